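"""Training-set construction for the two models.

Classification: putative iMs found genome-wide are labelled *folded* when
their region lies inside a high-confidence peak (the 3-way intersection of
replicate antibody peak tracks) and *unfolded* when it lies wholly in the
peak complement; regions straddling a peak edge are discarded and counted.
Peaks from CUT&Tag are strandless, so minus-strand formations are labelled
against the same intervals.

Regression: C-rich sequences with measured transitional pH (pH_T, the pH
at the folding midpoint) are reduced to their putative-iM sequence with
the greedy / non-overlapping / conformation-A search, deduplicated
(conflicting pH_T for one iM sequence removes the whole group), and pH_T
is rescaled to a [0,1] "folding strength".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, feature_table
from .search import SearchConfig, search_sequence, select_representative_conformation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping/adjacent intervals per chromosome."""
    out: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda v: (v.chrom, v.start, v.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def _intersect_two(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        if a[i].chrom != b[j].chrom:
            if a[i].chrom < b[j].chrom:
                i += 1
            else:
                j += 1
            continue
        lo = max(a[i].start, b[j].start)
        hi = min(a[i].end, b[j].end)
        if lo < hi:
            out.append(GenomicInterval(a[i].chrom, lo, hi))
        if a[i].end <= b[j].end:
            i += 1
        else:
            j += 1
    return out


def intersect_replicates(
    tracks: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Exact n-way intersection of replicate peak tracks (n >= 2).

    The result — regions supported by every replicate — is the
    high-confidence peak set used for folded/unfolded labelling.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 replicate tracks to intersect")
    acc = merge_intervals(tracks[0])
    for t in tracks[1:]:
        acc = _intersect_two(acc, merge_intervals(t))
    return acc


def label_formations(
    regions: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
) -> tuple[list[str], dict[str, int]]:
    """Label each region folded/unfolded by full containment.

    Returns per-region labels ("folded", "unfolded", or "discarded" for
    straddlers and unknown chromosomes) plus a tally.  Containment is the
    conservative reading of "in peak regions": a region half inside a peak
    is evidence for neither class.
    """
    peaks = merge_intervals(peaks)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    peak_chroms = set(by_chrom)

    labels = []
    counts = {"folded": 0, "unfolded": 0, "discarded": 0}
    for r in regions:
        if r.chrom not in peak_chroms:
            logger.warning("chromosome %s absent from peak track; discarding", r.chrom)
            lab = "discarded"
        else:
            chrom_peaks = by_chrom[r.chrom]
            starts = np.array([p.start for p in chrom_peaks])
            idx = int(np.searchsorted(starts, r.start, side="right")) - 1
            inside = idx >= 0 and r.end <= chrom_peaks[idx].end
            overlaps = any(
                p.start < r.end and r.start < p.end for p in chrom_peaks
            )
            lab = "folded" if inside else ("discarded" if overlaps else "unfolded")
        labels.append(lab)
        counts[lab] += 1
    logger.info("labelled formations: %s", counts)
    return labels, counts


def build_classification_dataset(
    genome: Mapping[str, str],
    tracks: Sequence[Sequence[GenomicInterval]],
    cfg: SearchConfig | None = None,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Search, label and featurise a genome against replicate peak tracks.

    Returns (X, y, metadata): the 33-column feature matrix, binary labels
    (1 = folded), and per-row region metadata.  The non-overlapping
    strategy is enforced to avoid double-counting overlapping candidates.
    """
    cfg = cfg or SearchConfig()
    if cfg.overlapping:
        raise ValueError("classification datasets require the non-overlapping strategy")
    if not genome:
        raise ValueError("empty genome")
    peaks = intersect_replicates(tracks)

    frames = []
    for chrom, seq in genome.items():
        formations = search_sequence(seq, cfg)
        if not formations:
            continue
        tab = feature_table(formations, seq, representative_only=True)
        tab.insert(0, "chrom", chrom)
        frames.append(tab)
    if not frames:
        raise ValueError("no putative iMs found in genome")
    table = pd.concat(frames, ignore_index=True)

    regions = [
        GenomicInterval(row.chrom, int(row.start), int(row.end))
        for row in table.itertuples()
    ]
    labels, counts = label_formations(regions, peaks)
    table["label"] = labels
    kept = table[table["label"] != "discarded"].reset_index(drop=True)
    X = kept[list(FEATURE_NAMES)].copy()
    y = (kept["label"] == "folded").to_numpy(dtype=int)
    meta = kept[["chrom", "start", "end", "strand", "label"]].copy()
    logger.info("classification dataset: %d rows (%s)", len(kept), counts)
    return X, y, meta


def extract_putative_im_sequence(seq: str, cfg: SearchConfig | None = None) -> str | None:
    """Reduce a C-rich input sequence to its putative-iM sequence.

    Uses the greedy, non-overlapping, conformation-A strategy on the plus
    strand and returns the first representative formation's region
    sequence, or None when no iM pattern is present.
    """
    cfg = cfg or SearchConfig(strands="plus")
    formations = search_sequence(seq, cfg)
    if not formations:
        return None
    f = formations[0]
    return seq.upper()[f.start : f.end]


def dedup_strength_records(records: pd.DataFrame) -> pd.DataFrame:
    """Deduplicate (sequence, pH_T) records by putative-iM sequence.

    Exact duplicates collapse to one row; groups where the same putative
    iM sequence carries more than one distinct pH_T are removed entirely
    (the measurements are irreconcilable).  Rows whose sequence yields no
    putative iM are dropped with a warning.  Expects columns
    ``sequence`` and ``ph_t``; idempotent.
    """
    recs = records.copy()
    if "im_sequence" not in recs.columns:
        recs["im_sequence"] = recs["sequence"].map(
            lambda s: extract_putative_im_sequence(s)
        )
    n_no_im = int(recs["im_sequence"].isna().sum())
    if n_no_im:
        logger.warning("%d records yield no putative iM; dropped", n_no_im)
    recs = recs.dropna(subset=["im_sequence"])
    recs = recs.drop_duplicates(subset=["im_sequence", "ph_t"])
    conflict = recs.groupby("im_sequence")["ph_t"].transform("nunique") > 1
    if conflict.any():
        logger.info(
            "removing %d records with conflicting pH_T", int(conflict.sum())
        )
    return recs[~conflict].reset_index(drop=True)


def scale_strength(ph_values: Sequence[float]) -> np.ndarray:
    """Map pH_T values to [0,1] folding strengths.

    Standardises (z-score) then min-max scales; the composition is
    numerically identical to plain min-max scaling because both maps are
    affine.  Constant input is rejected (scaling undefined).
    """
    ph = np.asarray(ph_values, dtype=float)
    if ph.size < 2 or np.ptp(ph) == 0:
        raise ValueError("need >= 2 distinct pH_T values to define strength")
    z = (ph - ph.mean()) / ph.std()
    return (z - z.min()) / (z.max() - z.min())


def build_regression_dataset(
    records: pd.DataFrame, cfg: SearchConfig | None = None
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Full regression-table pipeline: filter, dedup, scale, featurise.

    ``records`` needs columns sequence, ph_t and optionally
    high_confidence (rows flagged False are dropped first).  Returns
    (X, strength, metadata).
    """
    cfg = cfg or SearchConfig(strands="plus")
    recs = records.copy()
    if "high_confidence" in recs.columns:
        recs = recs[recs["high_confidence"].astype(bool)]
    recs = dedup_strength_records(recs)
    if len(recs) < 2:
        raise ValueError("fewer than 2 usable strength records")

    rows = []
    meta = []
    for row in recs.itertuples():
        formations = search_sequence(str(row.sequence), cfg)
        if not formations:
            continue
        f = formations[0]
        rep = f.representative or select_representative_conformation(f, "A")
        tab = feature_table([f], str(row.sequence), representative_only=True)
        rows.append(tab[list(FEATURE_NAMES)].iloc[0])
        meta.append({"im_sequence": row.im_sequence, "ph_t": row.ph_t})
    X = pd.DataFrame(rows).reset_index(drop=True)
    meta_df = pd.DataFrame(meta)
    strength = scale_strength(meta_df["ph_t"].to_numpy())
    meta_df["strength"] = strength
    return X, strength, meta_df
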