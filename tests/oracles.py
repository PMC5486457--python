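"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: a full-matrix Gotoh
local-alignment DP with traceback, a per-base sweep for masked-base
attribution, and a brute-force all-pairs single-linkage clustering.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DPAlignment(NamedTuple):
    score: int
    identity: float
    coverage_shorter: float
    strand: str


def _gotoh_local(x: str, y: str, match: int, mismatch: int, open_: int, ext: int):
    """Full-matrix local Gotoh DP; returns (score, H, E, F) integer matrices.

    Gap convention: a gap of length L scores open + (L-1)*ext (the opening
    column already costs ``open_``).
    """
    m, n = len(x), len(y)
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in x (moves in y)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in y (moves in x)
    xa = np.frombuffer(x.encode(), dtype=np.uint8)
    ya = np.frombuffer(y.encode(), dtype=np.uint8)
    jj = np.arange(1, n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        s = np.where(ya == xa[i - 1], match, mismatch)
        best_prev = np.maximum(np.maximum(H[i - 1], E[i - 1]), F[i - 1])
        H[i, 1:] = np.maximum(0, best_prev[:-1] + s)
        F[i, 1:] = np.maximum(H[i - 1, 1:] + open_, F[i - 1, 1:] + ext)
        # E[i,j] = max_{k<j} H[i,k] + open + (j-k-1)*ext, via a running max.
        run = np.maximum.accumulate(H[i, :-1] - ext * np.arange(n))
        E[i, 1:] = open_ - ext + ext * jj + run
    return int(H.max()), H, E, F


def _traceback(x, y, H, E, F, match, mismatch, open_, ext):
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    state = "H"
    matches = columns = 0
    end_x, end_y = i, j
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            s = match if x[i - 1] == y[j - 1] else mismatch
            columns += 1
            matches += x[i - 1] == y[j - 1]
            prev = H[i, j] - s
            i, j = i - 1, j - 1
            if H[i, j] == prev:
                state = "H"
            elif E[i, j] == prev:
                state = "E"
            else:
                assert F[i, j] == prev
                state = "F"
            if state == "H" and H[i, j] == 0:
                break
        elif state == "E":  # gap column consuming y
            columns += 1
            if E[i, j] == E[i, j - 1] + ext:
                j -= 1
            else:
                assert E[i, j] == H[i, j - 1] + open_
                j -= 1
                state = "H"
        else:  # F: gap column consuming x
            columns += 1
            if F[i, j] == F[i - 1, j] + ext:
                i -= 1
            else:
                assert F[i, j] == H[i - 1, j] + open_
                i -= 1
                state = "H"
    start_x, start_y = i, j
    return matches, columns, (start_x, end_x), (start_y, end_y)


def dp_local_similarity(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -5,
    gap_extend: int = -1,
    both_strands: bool = True,
) -> DPAlignment:
    """Best local alignment of a nucleotide pair, both strands.

    Identity is matches / alignment columns (gaps included); coverage is
    the aligned span of the shorter sequence over its length.
    """
    short, long_ = sorted((a.upper(), b.upper()), key=lambda s: (len(s), s))
    best = None
    for strand, target in (("+", long_), ("-", revcomp(long_))):
        score, H, E, F = _gotoh_local(target, short, match, mismatch, gap_open, gap_extend)
        if best is None or score > best[0]:
            best = (score, target, strand, H, E, F)
    score, target, strand, H, E, F = best
    if score <= 0:
        return DPAlignment(score, 0.0, 0.0, strand)
    matches, columns, _, span_short = _traceback(
        target, short, H, E, F, match, mismatch, gap_open, gap_extend
    )
    return DPAlignment(
        score,
        matches / columns,
        (span_short[1] - span_short[0]) / len(short),
        strand,
    )


def per_base_sweep(records, genome_lengths: dict[str, int]) -> dict[int, int]:
    """Per-base masked-base attribution: record index -> owned bp.

    Every base goes to the covering record with the highest
    (sw_score, earlier start, input order) priority.
    """
    owned = {i: 0 for i in range(len(records))}
    for name, length in genome_lengths.items():
        owner = np.full(length, -1, dtype=np.int64)
        prio = np.full(length, -1, dtype=np.int64)
        ranked = sorted(
            range(len(records)),
            key=lambda i: (-records[i].sw_score, records[i].query_begin, i),
        )
        for rank, i in enumerate(ranked):
            rec = records[i]
            if rec.query_name != name:
                continue
            sl = slice(rec.query_begin - 1, rec.query_end)
            free = owner[sl] == -1
            segment = owner[sl]
            segment[free] = i
            owner[sl] = segment
        for i in owner[owner >= 0]:
            owned[int(i)] += 1
    return owned


def brute_force_single_linkage(
    library: dict[str, str], min_identity: float = 0.80, min_coverage: float = 0.80
) -> set[frozenset[str]]:
    """All-pairs single-linkage under the 80-80 rule with the DP reference."""
    ids = sorted(library)
    adj = {i: set() for i in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            sim = dp_local_similarity(library[a], library[b])
            if sim.identity > min_identity and sim.coverage_shorter > min_coverage:
                adj[a].add(b)
                adj[b].add(a)
    seen: set[str] = set()
    components: set[frozenset[str]] = set()
    for start in ids:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        seen |= comp
        components.add(frozenset(comp))
    return components
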