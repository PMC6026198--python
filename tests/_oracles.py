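"""Independent brute-force oracles used by the test suite.

Deliberately naive re-implementations (enumeration, full-matrix dynamic
programming, direct simulation) kept separate from the package code paths
they check.
"""

from __future__ import annotations

import math

import numpy as np

NEG = -(10**9)


def mutual_information_oracle(p_xy) -> float:
    """Direct double-loop summation of sum p log2(p / px / py)."""
    n = len(p_xy)
    p_x = [sum(p_xy[i][j] for j in range(n)) for i in range(n)]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if p_xy[i][j] > 0:
                total += p_xy[i][j] * math.log2(p_xy[i][j] / p_x[i] / p_x[j])
    return total


def best_segment_oracle(a, b, scores) -> int:
    """Exhaustive enumeration of all contiguous segments (floor 0)."""
    n = len(a)
    per_pos = [int(scores[a[i], b[i]]) for i in range(n)]
    best = 0
    for i in range(n):
        run = 0
        for j in range(i, n):
            run += per_pos[j]
            best = max(best, run)
    return best


def local_align_score_oracle(q, t, scores, gap_open=11, gap_extend=1) -> int:
    """Textbook full-matrix affine-gap Smith-Waterman score.

    Gap of length g costs gap_open + g * gap_extend.
    """
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - first, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - first, F[i - 1, j] - gap_extend)
            diag = H[i - 1, j - 1] + int(scores[q[i - 1], t[j - 1]])
            H[i, j] = max(0, diag, E[i, j], F[i, j])
    return int(H.max())


def greedy_cluster_oracle(lengths, edge_pairs):
    """Step-through simulation of greedy incremental clustering."""
    n = len(lengths)
    adj = {i: set() for i in range(n)}
    for a, b in edge_pairs:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    remaining = sorted(range(n), key=lambda i: (-lengths[i], i))
    assigned = {}
    while remaining:
        rep = remaining.pop(0)
        if rep in assigned:
            continue
        assigned[rep] = rep
        for nb in adj[rep]:
            if nb not in assigned:
                assigned[nb] = rep
    return assigned


def fnv1a_16_oracle(codes) -> int:
    """Independent 5-line restatement of the reference k-mer hash."""
    h = 0xCBF29CE484222325
    for c in codes:
        h = ((h ^ int(c)) * 0x100000001B3) % 2**64
    h = (h >> 32) ^ (h % 2**32)
    return (h >> 16) ^ (h % 2**16)
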