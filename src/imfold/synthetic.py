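"""Synthetic fixtures: planted-motif genomes, replicate peak tracks and
feature-driven transitional-pH tables.

The generators state a small, fixed world: a random background genome in
which (C>=3 N1-12)3 C>=3 motifs are planted at known positions, three
replicate "antibody peak" tracks that cover a chosen subset of the planted
motifs with bounded boundary jitter, and pH_T values produced from motif
features by a linear model with additive Gaussian noise.  Everything is a
pure function of the seed.

Background suppression replaces any accidental run of >= 3 C (or G, for
the minus strand) so that planted motifs are the only putative iMs — a
deliberate simplification that gives exact ground truth; real genomes of
course carry abundant C-rich background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import GenomicInterval
from .features import FEATURE_NAMES, feature_table
from .search import SearchConfig, search_sequence

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class StrengthModel:
    """Linear pH_T model: long C-tracts and C/T-rich loops stabilise,
    long loops and G/A-rich loops destabilise."""

    intercept: float = 6.0
    beta_core: float = 0.15      # pH units per core nt
    beta_loop: float = 0.05      # pH units per mean-loop nt (subtracted)
    beta_ct: float = 0.8         # weight of C+T density in loops
    beta_ga: float = 0.8         # weight of G+A density in loops (subtracted)
    sigma: float = 0.05          # additive noise, pH units


@dataclass(frozen=True)
class SyntheticSpec:
    genome_length: int = 50_000
    gc_content: float = 0.4
    n_motifs: int = 20
    tract_len_range: tuple[int, int] = (3, 6)
    loop_len_range: tuple[int, int] = (1, 8)
    peak_cover_fraction: float = 0.4
    peak_margin: int = 25        # peak flank beyond the motif, > jitter
    jitter: int = 20             # replicate boundary jitter, nt
    strength: StrengthModel = field(default_factory=StrengthModel)
    seed: int = 0


def _random_motif(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    """One planted (C>=3 N1-12)3 C>=3 motif.

    Loop bases next to a tract are never C, and loops never contain 3
    consecutive C, so the planted tracts stay the only graph nodes.
    """
    lo_t, hi_t = spec.tract_len_range
    lo_l, hi_l = spec.loop_len_range
    tracts = ["C" * int(rng.integers(lo_t, hi_t + 1)) for _ in range(4)]
    loops = []
    for _ in range(3):
        n = int(rng.integers(lo_l, hi_l + 1))
        loop = list(rng.choice(BASES, size=n))
        for i in (0, n - 1):
            if loop[i] == "C":
                loop[i] = str(rng.choice(["A", "T", "G"]))
        for i in range(2, n):
            if loop[i - 2] == loop[i - 1] == loop[i] == "C":
                loop[i] = "T"
        loops.append("".join(loop))
    return tracts[0] + loops[0] + tracts[1] + loops[1] + tracts[2] + loops[2] + tracts[3]


def _background(rng: np.random.Generator, n: int, gc: float, suppress: bool) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(BASES, size=n, p=p)
    if suppress:
        # break every C- or G-run of length >= 3 (both strands stay clean)
        for bad, sub in (("C", "A"), ("G", "T")):
            run = 0
            for i in range(n):
                run = run + 1 if arr[i] == bad else 0
                if run == 3:
                    arr[i] = sub
                    run = 0
    return "".join(arr)


def gen_genome(
    spec: SyntheticSpec, suppress_background: bool = True, chrom: str = "chrS"
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Background genome with planted motifs; returns (genome, truth).

    Motifs are spaced evenly with randomised offsets, planted on a random
    strand (minus-strand motifs are inserted as their reverse complement),
    and recorded as ground-truth intervals with strand.
    """
    rng = np.random.default_rng(spec.seed)
    motifs = [_random_motif(rng, spec) for _ in range(spec.n_motifs)]
    total_motif = sum(map(len, motifs))
    if total_motif + 10 * max(1, spec.n_motifs) > spec.genome_length:
        raise ValueError("motifs do not fit in the requested genome length")

    seq = list(
        _background(rng, spec.genome_length, spec.gc_content, suppress_background)
    )
    truth: list[GenomicInterval] = []
    if spec.n_motifs:
        slot = spec.genome_length // spec.n_motifs
        for k, motif in enumerate(motifs):
            strand = "+" if rng.random() < 0.5 else "-"
            ins = motif if strand == "+" else _revcomp(motif)
            margin = slot - len(ins)
            start = k * slot + int(rng.integers(2, max(3, margin - 2)))
            seq[start : start + len(ins)] = list(ins)
            # guard bases so background cannot extend the terminal runs
            seq[start - 1] = "A"
            if start + len(ins) < spec.genome_length:
                seq[start + len(ins)] = "A"
            truth.append(GenomicInterval(chrom, start, start + len(ins), strand))
    return {chrom: "".join(seq)}, truth


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def gen_peak_tracks(
    truth: list[GenomicInterval], spec: SyntheticSpec
) -> tuple[list[list[GenomicInterval]], list[int]]:
    """Three replicate peak tracks covering a subset of planted motifs.

    Exactly ``round(peak_cover_fraction * n)`` motifs (chosen by seeded
    draw) receive a peak in every replicate.  Each replicate's peak
    extends ``peak_margin`` nt beyond the motif, jittered by up to
    ``jitter`` nt; because margin > jitter, the 3-way intersection still
    contains each chosen motif.  Returns (tracks, covered indices).
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_cover = int(round(spec.peak_cover_fraction * len(truth)))
    covered = sorted(rng.choice(len(truth), size=n_cover, replace=False).tolist())
    tracks: list[list[GenomicInterval]] = []
    for _ in range(3):
        track = []
        for i in covered:
            m = truth[i]
            j1 = int(rng.integers(0, spec.jitter + 1)) if spec.jitter else 0
            j2 = int(rng.integers(0, spec.jitter + 1)) if spec.jitter else 0
            track.append(
                GenomicInterval(m.chrom, max(0, m.start - spec.peak_margin + j1),
                                m.end + spec.peak_margin - j2)
            )
        tracks.append(track)
    return tracks, covered


def gen_classification_features(
    n_minority: int = 50,
    imbalance: int = 80,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Imbalanced feature matrix with informative class structure.

    The folded (minority) class is drawn from a long-tract / short-loop
    motif regime and the unfolded majority from a short-tract / long-loop
    regime, both featurised through the real search pipeline, emulating
    the ~1:80 folded:unfolded ratio of genome-wide data.
    """
    folded_spec = SyntheticSpec(tract_len_range=(4, 6), loop_len_range=(1, 4), seed=seed)
    unfolded_spec = SyntheticSpec(tract_len_range=(3, 4), loop_len_range=(4, 10), seed=seed)
    rng = np.random.default_rng(seed)
    cfg = SearchConfig(strands="plus")

    def block(spec: SyntheticSpec, n: int) -> pd.DataFrame:
        rows = []
        while len(rows) < n:
            motif = _random_motif(rng, spec)
            forms = search_sequence(motif, cfg)
            if forms:
                rows.append(feature_table(forms[:1], motif).iloc[0])
        return pd.DataFrame(rows)

    folded = block(folded_spec, n_minority)
    unfolded = block(unfolded_spec, n_minority * imbalance)
    X = pd.concat([folded, unfolded], ignore_index=True)[list(FEATURE_NAMES)]
    y = np.r_[np.ones(len(folded), dtype=int), np.zeros(len(unfolded), dtype=int)]
    return X, y


def gen_strength_table(
    n: int,
    spec: SyntheticSpec | None = None,
    n_exact_duplicates: int = 0,
    n_conflicts: int = 0,
) -> pd.DataFrame:
    """Sequences with pH_T computed from their representative features.

    pH_T = b0 + b1*core_len - b2*mean_loop + b3*(C+T loop density)
           - b4*(G+A loop density) + N(0, sigma).

    Optionally appends exact-duplicate rows and conflicting-pH_T rows to
    exercise deduplication.  Columns: sequence, ph_t, high_confidence.
    """
    if n < 10:
        raise ValueError("need n >= 10 strength records")
    spec = spec or SyntheticSpec()
    sm = spec.strength
    rng = np.random.default_rng(spec.seed + 2)
    cfg = SearchConfig(strands="plus")

    rows = []
    seen: set[str] = set()
    while len(rows) < n:
        motif = _random_motif(rng, spec)
        if motif in seen:
            continue
        forms = search_sequence(motif, cfg)
        if not forms:
            continue
        seen.add(motif)
        feats = feature_table(forms[:1], motif).iloc[0]
        loops_ct = feats["C_density_loops"] + feats["T_density_loops"]
        loops_ga = feats["G_density_loops"] + feats["A_density_loops"]
        ph = (
            sm.intercept
            + sm.beta_core * feats["c_tract_length"]
            - sm.beta_loop * feats["loop_length"]
            + sm.beta_ct * loops_ct
            - sm.beta_ga * loops_ga
            + rng.normal(0.0, sm.sigma)
        )
        rows.append({"sequence": motif, "ph_t": round(float(ph), 3),
                     "high_confidence": True})
    table = pd.DataFrame(rows)

    extra = []
    for i in range(n_exact_duplicates):
        extra.append(dict(table.iloc[i % n]))
    for i in range(n_conflicts):
        row = dict(table.iloc[(n - 1 - i) % n])
        row["ph_t"] = row["ph_t"] + 0.5
        extra.append(row)
    if extra:
        table = pd.concat([table, pd.DataFrame(extra)], ignore_index=True)
    return table
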