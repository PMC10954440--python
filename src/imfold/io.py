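"""FASTA / BED / TSV input-output."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .datasets import GenomicInterval
from .features import feature_table
from .search import IMotifFormation


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record) FASTA into {name: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open; extra columns ignored)."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) > 5 else None
            ivs.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return ivs


def read_bedgraph(path, threshold: float = 0.0) -> list[GenomicInterval]:
    """Convert a bedGraph track to intervals with score > threshold."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, score = line.split("\t")[:4]
            if float(score) > threshold:
                ivs.append(GenomicInterval(chrom, int(start), int(end)))
    return ivs


def write_bed(
    path,
    chroms: Sequence[str],
    formations: Sequence[IMotifFormation],
    scores: Sequence[float] | None = None,
) -> None:
    """Write formations as BED6 (score column defaults to 0)."""
    with open(path, "w") as fh:
        for i, (chrom, f) in enumerate(zip(chroms, formations)):
            score = int(round(scores[i])) if scores is not None else 0
            fh.write(
                f"{chrom}\t{f.start}\t{f.end}\tiM_{i}\t{score}\t{f.strand}\n"
            )


def conformation_tsv(
    chroms: Sequence[str],
    formations: Sequence[IMotifFormation],
    seqs: dict[str, str],
    representative_only: bool,
) -> pd.DataFrame:
    """Per-conformation detail table including dash notation."""
    rows = []
    for i, (chrom, f) in enumerate(zip(chroms, formations)):
        confs = (
            [f.representative]
            if representative_only and f.representative is not None
            else f.conformations
        )
        for c in confs:
            seq = seqs[chrom]
            sub = seq[c.span[0] : c.span[1]]
            if c.strand == "-":
                from .search import reverse_complement

                sub = reverse_complement(sub)
            # dash notation in the C-rich (5'->3' folded) orientation
            from .features import _oriented_span

            oriented_seq, local = _oriented_span(c, seq)
            rows.append(
                {
                    "chrom": chrom,
                    "formation": f"iM_{i}",
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "core_starts": ",".join(map(str, c.core_starts)),
                    "core_len": c.core_len,
                    "loop_lengths": ",".join(map(str, c.loop_lengths)),
                    "dash_notation": local.dash_notation(oriented_seq),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "formation", "start", "end", "strand",
            "core_starts", "core_len", "loop_lengths", "dash_notation",
        ],
    )
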