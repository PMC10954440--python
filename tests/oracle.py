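"""Independent brute-force enumeration of i-motif conformations.

Enumerates quadruples of maximal C-runs with itertools and slides core
windows directly on the string, never touching the graph machinery, so it
can serve as an oracle for the graph pipeline.
"""

import itertools


def brute_force_conformations(seq, min_tract=3, loop_min=1, loop_max=12):
    """Set of (core_starts, core_len) tuples enumerable on the plus strand."""
    seq = seq.upper()
    # maximal C runs by direct scan
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "C":
            j = i
            while j < len(seq) and seq[j] == "C":
                j += 1
            if j - i >= min_tract:
                runs.append((i, j))
            i = j
        else:
            i += 1

    found = set()
    for quad in itertools.combinations(range(len(runs)), 4):
        rs = [runs[k] for k in quad]
        if any(
            not (loop_min <= rs[k + 1][0] - rs[k][1] <= loop_max) for k in range(3)
        ):
            continue
        core = min(b - a for a, b in rs)
        for starts in itertools.product(
            *[range(a, b - core + 1) for a, b in rs]
        ):
            gaps = [starts[k + 1] - (starts[k] + core) for k in range(3)]
            if all(loop_min <= g <= loop_max for g in gaps):
                assert all(seq[s : s + core] == "C" * core for s in starts)
                found.add((starts, core))
    return found
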