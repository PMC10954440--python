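"""Graph-based discovery of putative i-motif forming sequences.

An i-motif (iM) core is four equal-length tracts of consecutive cytosines
joined by three loops of 1-12 nt, the classic (C>=3 N1-12)3 C>=3 pattern.
Maximal C-runs are the nodes of a directed acyclic graph; an edge joins two
runs whenever the gap between them is an admissible loop length.  Every
4-node path of that graph yields candidate conformations by sliding an
equal-length core window inside each run; candidates sharing the same
(first run, last run) endpoints are grouped into one *formation*, from
which representative conformations and representative formations are
selected under the greedy/non-greedy x overlapping/non-overlapping
strategies.

Coordinates are 0-based half-open throughout; minus-strand hits report
forward-strand coordinates (BED convention).
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

logger = logging.getLogger(__name__)

_VALID_SEQ = re.compile(r"^[ACGTN]*$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SearchConfig:
    """Settings of the putative-iM search.

    Defaults reproduce the canonical pattern (C>=3 N1-12)3 C>=3 with the
    greedy, non-overlapping, conformation-A strategy used for model
    training.
    """

    min_tract_len: int = 3
    loop_min: int = 1
    loop_max: int = 12
    greedy: bool = True
    overlapping: bool = False
    representative_mode: Literal["A", "B", "all"] = "A"
    strands: Literal["plus", "minus", "both"] = "both"

    def __post_init__(self) -> None:
        if self.min_tract_len < 2:
            raise ValueError("min_tract_len must be >= 2")
        if not (1 <= self.loop_min <= self.loop_max):
            raise ValueError("need 1 <= loop_min <= loop_max")
        if self.representative_mode not in ("A", "B", "all"):
            raise ValueError(f"unknown representative_mode {self.representative_mode!r}")
        if self.strands not in ("plus", "minus", "both"):
            raise ValueError(f"unknown strands {self.strands!r}")


@dataclass(frozen=True, order=True)
class CTractRun:
    """A maximal run of consecutive cytosines (a graph node)."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TractGraph:
    """DAG over C-runs; an edge i->j exists iff the gap is a legal loop."""

    nodes: tuple[CTractRun, ...]
    edges: tuple[tuple[int, int], ...]

    def successors(self, i: int) -> list[int]:
        return [j for (a, j) in self.edges if a == i]


@dataclass(frozen=True)
class IMotifConformation:
    """One assignment of the four equal-length C-cores within a region.

    ``core_starts`` are 0-based offsets of the four cores (each of length
    ``core_len``); the three loops are the half-open gaps between
    consecutive cores.  The span runs from the first core start to the end
    of the fourth core.
    """

    core_starts: tuple[int, int, int, int]
    core_len: int
    strand: str = "+"

    @property
    def span(self) -> tuple[int, int]:
        return self.core_starts[0], self.core_starts[3] + self.core_len

    @property
    def loops(self) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
        s, L = self.core_starts, self.core_len
        return tuple((s[i] + L, s[i + 1]) for i in range(3))  # type: ignore[return-value]

    @property
    def loop_lengths(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in self.loops)  # type: ignore[return-value]

    def dash_notation(self, seq: str) -> str:
        """Render as cores and loops joined by dashes, e.g. CCC-CA-CCC-...-CCC."""
        parts = []
        for i in range(4):
            a = self.core_starts[i]
            parts.append(seq[a : a + self.core_len])
            if i < 3:
                la, lb = self.loops[i]
                parts.append(seq[la:lb])
        return "-".join(parts)


@dataclass
class IMotifFormation:
    """A candidate region with every conformation it supports.

    Keyed by the (first run, last run) endpoint pair; the region runs from
    the first run's start to the last run's end, so conformations may begin
    or end a few bases inside the endpoint runs (leftover cytosines join
    the loops or flanks).
    """

    first_run: int
    last_run: int
    region: tuple[int, int]
    conformations: list[IMotifConformation]
    strand: str = "+"
    representative: IMotifConformation | None = None

    @property
    def start(self) -> int:
        return self.region[0]

    @property
    def end(self) -> int:
        return self.region[1]


def find_c_runs(seq: str, min_len: int = 3) -> list[CTractRun]:
    """Locate maximal runs of >= ``min_len`` consecutive cytosines.

    Raises ``ValueError`` on characters outside {A,C,G,T,N}.
    """
    seq = seq.upper()
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    return [
        CTractRun(m.start(), m.end())
        for m in re.finditer("C{%d,}" % min_len, seq)
    ]


def build_tract_graph(runs: Sequence[CTractRun], cfg: SearchConfig) -> TractGraph:
    """Connect runs whose gap lies in [loop_min, loop_max].

    Edges are not restricted to adjacent runs: any downstream run within
    reach gets an edge, which is what makes tract-skipping conformations
    (e.g. 1-2-3-5) enumerable.
    """
    edges = [
        (i, j)
        for i in range(len(runs))
        for j in range(i + 1, len(runs))
        if cfg.loop_min <= runs[j].start - runs[i].end <= cfg.loop_max
    ]
    return TractGraph(nodes=tuple(runs), edges=tuple(edges))


def enumerate_paths(graph: TractGraph) -> list[tuple[int, int, int, int]]:
    """All 4-node directed paths a->b->c->d, in lexicographic node order."""
    succ: dict[int, list[int]] = {i: [] for i in range(len(graph.nodes))}
    for a, b in graph.edges:
        succ[a].append(b)
    for lst in succ.values():
        lst.sort()
    quads = []
    for a in range(len(graph.nodes)):
        for b in succ[a]:
            for c in succ[b]:
                for d in succ[c]:
                    quads.append((a, b, c, d))
    quads.sort()
    return quads


def enumerate_conformations(
    seq: str,
    runs: Sequence[CTractRun],
    quadruple: tuple[int, int, int, int],
    cfg: SearchConfig,
    strand: str = "+",
) -> list[IMotifConformation]:
    """Slide equal-length cores inside the four runs of one path.

    The core length is the minimum run length over the path's four runs;
    every placement of a core window inside each run is a candidate, and a
    placement survives only if all three resulting loops (which absorb the
    leftover run cytosines) stay within [loop_min, loop_max].
    """
    rs = [runs[i] for i in quadruple]
    core_len = min(r.length for r in rs)
    placements = [range(r.start, r.end - core_len + 1) for r in rs]
    out = []
    for starts in itertools.product(*placements):
        conf = IMotifConformation(core_starts=starts, core_len=core_len, strand=strand)
        if all(cfg.loop_min <= n <= cfg.loop_max for n in conf.loop_lengths):
            out.append(conf)
    out.sort(key=lambda c: c.core_starts)
    return out


def group_formations(
    seq: str,
    runs: Sequence[CTractRun],
    paths: Iterable[tuple[int, int, int, int]],
    cfg: SearchConfig,
    strand: str = "+",
) -> list[IMotifFormation]:
    """Group path conformations by their (first run, last run) endpoints."""
    by_ends: dict[tuple[int, int], list[IMotifConformation]] = {}
    for quad in paths:
        confs = enumerate_conformations(seq, runs, quad, cfg, strand=strand)
        if confs:
            by_ends.setdefault((quad[0], quad[3]), []).extend(confs)
    formations = []
    for (a, d), confs in by_ends.items():
        # distinct paths can in principle reproduce a placement; dedupe
        uniq = sorted(set(confs), key=lambda c: c.core_starts)
        formations.append(
            IMotifFormation(
                first_run=a,
                last_run=d,
                region=(runs[a].start, runs[d].end),
                conformations=uniq,
                strand=strand,
            )
        )
    formations.sort(key=lambda f: f.region)
    return formations


def _formation_sort_key(f: IMotifFormation) -> tuple:
    core = max(c.core_len for c in f.conformations)
    total_loop = min(sum(c.loop_lengths) for c in f.conformations)
    return (-core, total_loop, f.region)


def select_representative_formations(
    formations: Sequence[IMotifFormation], cfg: SearchConfig
) -> list[IMotifFormation]:
    """Apply the greedy/non-greedy x overlapping/non-overlapping strategy.

    Greedy keeps, per starting run, the formation with the maximal region
    end (the longest match); non-greedy the minimal end.  Overlapping mode
    emits one formation per starting run; non-overlapping mode scans left
    to right and drops any formation intersecting an already-emitted
    region.  Ties break by larger core length, then smaller total loop
    length, then lexicographic region.
    """
    by_start: dict[int, list[IMotifFormation]] = {}
    for f in formations:
        by_start.setdefault(f.first_run, []).append(f)

    per_start: list[IMotifFormation] = []
    for fr in sorted(by_start):
        group = by_start[fr]
        extreme = max(g.end for g in group) if cfg.greedy else min(g.end for g in group)
        cands = [g for g in group if g.end == extreme]
        cands.sort(key=_formation_sort_key)
        per_start.append(cands[0])

    if cfg.overlapping:
        return per_start

    kept: list[IMotifFormation] = []
    for f in per_start:  # already ordered by start
        if all(f.start >= k.end or f.end <= k.start for k in kept):
            kept.append(f)
    return kept


def select_representative_conformation(
    formation: IMotifFormation, mode: str
) -> IMotifConformation:
    """Pick conformation A (min loop-length spread) or B (min side loops).

    A minimises the population standard deviation of the three loop
    lengths; B minimises the summed length of the two side loops (first
    and third).  Ties break by lexicographically smallest core starts,
    which the sorted conformation list provides for free.
    """
    if not formation.conformations:
        raise ValueError("formation has no conformations")
    if mode == "A":
        def key(c: IMotifConformation) -> tuple:
            ls = c.loop_lengths
            mean = sum(ls) / 3.0
            return (sum((x - mean) ** 2 for x in ls), c.core_starts)
    elif mode == "B":
        def key(c: IMotifConformation) -> tuple:
            ls = c.loop_lengths
            return (ls[0] + ls[2], c.core_starts)
    else:
        raise ValueError(f"unknown representative mode {mode!r}")
    return min(formation.conformations, key=key)


def _search_one_strand(seq: str, cfg: SearchConfig, strand: str) -> list[IMotifFormation]:
    runs = find_c_runs(seq, cfg.min_tract_len)
    graph = build_tract_graph(runs, cfg)
    paths = enumerate_paths(graph)
    formations = group_formations(seq, runs, paths, cfg, strand=strand)

    # a candidate region containing N cannot fold; drop it
    def clean(f: IMotifFormation) -> bool:
        ok = "N" not in seq[f.start : f.end]
        if not ok:
            logger.info("dropping formation %s-%s: contains N", f.start, f.end)
        return ok

    formations = [f for f in formations if clean(f)]
    reps = select_representative_formations(formations, cfg)
    if cfg.representative_mode != "all":
        for f in reps:
            f.representative = select_representative_conformation(
                f, cfg.representative_mode
            )
    return reps


def _map_to_forward(f: IMotifFormation, seq_len: int) -> IMotifFormation:
    """Mirror a minus-strand formation's coordinates onto the forward strand."""
    L = f.conformations[0].core_len

    def flip_conf(c: IMotifConformation) -> IMotifConformation:
        starts = tuple(sorted(seq_len - (s + c.core_len) for s in c.core_starts))
        return IMotifConformation(core_starts=starts, core_len=c.core_len, strand="-")

    confs = sorted((flip_conf(c) for c in f.conformations), key=lambda c: c.core_starts)
    rep = flip_conf(f.representative) if f.representative is not None else None
    return IMotifFormation(
        first_run=f.last_run,
        last_run=f.first_run,
        region=(seq_len - f.end, seq_len - f.start),
        conformations=confs,
        strand="-",
        representative=rep,
    )


def search_sequence(seq: str, cfg: SearchConfig | None = None) -> list[IMotifFormation]:
    """Full putative-iM search on one sequence.

    Scans the forward strand and/or the reverse complement (C-rich regions
    on the minus strand are G-rich on the plus strand); minus-strand
    formations come back with forward-strand coordinates and strand "-".
    Output is sorted by (start, end, strand).
    """
    cfg = cfg or SearchConfig()
    seq = seq.upper()
    out: list[IMotifFormation] = []
    if cfg.strands in ("plus", "both"):
        out.extend(_search_one_strand(seq, cfg, "+"))
    if cfg.strands in ("minus", "both"):
        rc = reverse_complement(seq)
        out.extend(_map_to_forward(f, len(seq)) for f in _search_one_strand(rc, cfg, "-"))
    out.sort(key=lambda f: (f.start, f.end, f.strand))
    return out
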