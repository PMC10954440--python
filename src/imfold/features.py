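"""The 33-feature encoding of an i-motif conformation.

Both the folding-status classifier and the folding-strength regressor
consume the same fixed-order vector: nine length features (core/tract
length, overall iM length, and aggregates of the three loop lengths)
followed by A/C/G/T densities over six regions (whole iM span, all loops,
middle loop, longest side loop, shortest side loop, both side loops).

Loops are indexed 5'->3' as L1, L2, L3; L2 is the middle loop and L1/L3
are the side loops.  When the two side loops tie in length, the 5' loop L1
is deemed the "longest" — an arbitrary but fixed and documented rule.
The aggregate "loop_length" is the arithmetic mean of the three loops.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .search import IMotifConformation, IMotifFormation, reverse_complement

SCHEMA_VERSION = "imfold-features-1"

FEATURE_NAMES: tuple[str, ...] = (
    "c_tract_length",
    "im_length",
    "loop_length",
    "middle_loop_length",
    "longest_side_loop_length",
    "shortest_side_loop_length",
    "sum_side_loops",
    "longest_loop_length",
    "shortest_loop_length",
) + tuple(
    f"{base}_density_{region}"
    for region in (
        "im",
        "loops",
        "middle_loop",
        "longest_side_loop",
        "shortest_side_loop",
        "side_loops",
    )
    for base in "ACGT"
)

assert len(FEATURE_NAMES) == 33


def _densities(region: str) -> tuple[float, float, float, float]:
    if not region:
        # an empty region (cannot occur with loop_min >= 1) contributes zeros
        return (0.0, 0.0, 0.0, 0.0)
    bad = set(region) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT bases in feature region: {sorted(bad)}")
    n = len(region)
    return tuple(region.count(b) / n for b in "ACGT")  # type: ignore[return-value]


def _oriented_span(conf: IMotifConformation, seq: str) -> tuple[str, IMotifConformation]:
    """Return the 5'->3' C-rich span sequence and a span-local conformation.

    Minus-strand conformations carry forward-strand coordinates; their
    actual C-rich sequence is the reverse complement of the spanned
    region, with core positions mirrored accordingly.
    """
    a, b = conf.span
    sub = seq[a:b].upper()
    local = tuple(s - a for s in conf.core_starts)
    if conf.strand == "-":
        sub = reverse_complement(sub)
        n = len(sub)
        local = tuple(sorted(n - (s + conf.core_len) for s in local))
    return sub, IMotifConformation(core_starts=local, core_len=conf.core_len)  # type: ignore[arg-type]


def extract_features(conf: IMotifConformation, seq: str) -> np.ndarray:
    """Encode one conformation against its source sequence (33 floats)."""
    sub, local = _oriented_span(conf, seq)
    l1, l2, l3 = (sub[a:b] for a, b in local.loops)
    lens = local.loop_lengths
    # side-loop tie: the 5' loop counts as the longest
    longest_side, shortest_side = (l1, l3) if len(l1) >= len(l3) else (l3, l1)

    values = [
        float(local.core_len),
        float(len(sub)),
        float(sum(lens)) / 3.0,
        float(lens[1]),
        float(len(longest_side)),
        float(len(shortest_side)),
        float(len(l1) + len(l3)),
        float(max(lens)),
        float(min(lens)),
    ]
    for region in (sub, l1 + l2 + l3, l2, longest_side, shortest_side, l1 + l3):
        values.extend(_densities(region))
    return np.asarray(values, dtype=float)


def feature_table(
    formations: Sequence[IMotifFormation],
    seq: str,
    representative_only: bool = True,
) -> pd.DataFrame:
    """Featurise formations into a DataFrame (one row per conformation).

    Row metadata columns (formation id, region, strand, conformation core
    starts) precede the 33 feature columns.
    """
    rows = []
    meta = []
    for fi, f in enumerate(formations):
        confs = (
            [f.representative]
            if representative_only and f.representative is not None
            else f.conformations
        )
        for conf in confs:
            rows.append(extract_features(conf, seq))
            meta.append(
                {
                    "formation": fi,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "core_starts": ",".join(map(str, conf.core_starts)),
                    "core_len": conf.core_len,
                }
            )
    meta_df = pd.DataFrame(
        meta, columns=["formation", "start", "end", "strand", "core_starts", "core_len"]
    )
    feat_df = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, 33)), columns=list(FEATURE_NAMES)
    )
    return pd.concat([meta_df, feat_df], axis=1)
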