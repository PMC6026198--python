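"""Numerical kernels shared by the prefilter and alignment stages.

All kernels operate on full-alphabet integer codes (0..20, 20 = wildcard)
and an integer 21x21 Blosum62 score matrix.  They are compiled with numba
when it is available; otherwise the pure-Python definitions run as-is
(correct but slow).  The batched entry points call the same per-pair
kernels as the public per-pair API, so there is a single implementation of
each primitive.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap

WILDCARD = 20

# Traceback move codes for the gapped aligner.
_STOP, _DIAG, _FROM_E, _FROM_F = 0, 1, 2, 3


@njit(cache=True)
def hamming_identical(a, b):
    """Number of identical positions between equal-length code arrays.

    The wildcard (code 20) never counts as identical, even against itself.
    """
    n = 0
    for i in range(a.shape[0]):
        if a[i] == b[i] and a[i] != WILDCARD:
            n += 1
    return n


@njit(cache=True)
def best_ungapped_segment(a, b, scores):
    """Maximum-scoring contiguous segment of the gapless comparison of a, b.

    One-pass dynamic programming (run = max(0, run + S(x, y))).  Returns
    (score, start, length) relative to the overlap; an empty segment
    (score 0, length 0) is allowed when every extension scores negatively.
    Ties go to the earliest-ending, then shortest, segment.
    """
    best = 0
    best_start = 0
    best_len = 0
    run = 0
    run_start = 0
    for i in range(a.shape[0]):
        s = scores[a[i], b[i]]
        if run <= 0:
            run = 0
            run_start = i
        run += s
        if run <= 0:
            run = 0
            run_start = i + 1
        elif run > best:
            best = run
            best_start = run_start
            best_len = i + 1 - run_start
    return best, best_start, best_len


@njit(cache=True)
def prefilter_batch(
    concat, offsets, lengths, centers, members, diagonals, scores
):
    """Hamming identity and ungapped best-segment score for candidate pairs.

    ``concat`` holds all sequences back to back; ``offsets``/``lengths``
    index into it by sequence id.  For each pair the overlap of the two
    sequences along the stored diagonal is compared.  Returns per-pair
    arrays (overlap_length, n_identical, ungapped_score).
    """
    n = centers.shape[0]
    overlap_len = np.zeros(n, dtype=np.int64)
    n_ident = np.zeros(n, dtype=np.int64)
    ungapped = np.zeros(n, dtype=np.int64)
    for p in range(n):
        ci = centers[p]
        mi = members[p]
        d = diagonals[p]
        clen = lengths[ci]
        mlen = lengths[mi]
        x_start = max(0, d)
        length = min(clen, mlen + d) - x_start
        if length <= 0:
            continue
        y_start = x_start - d
        a = concat[offsets[ci] + x_start : offsets[ci] + x_start + length]
        b = concat[offsets[mi] + y_start : offsets[mi] + y_start + length]
        overlap_len[p] = length
        n_ident[p] = hamming_identical(a, b)
        score, _, _ = best_ungapped_segment(a, b, scores)
        ungapped[p] = score
    return overlap_len, n_ident, ungapped


@njit(cache=True)
def hamming_preaccept_any_diagonal(q, t, min_seq_id, c, cov_mode):
    """Whether any diagonal pre-accepts the pair by Hamming identity.

    Mirrors the Hamming pre-clustering criterion: identity >= min_seq_id
    over the entire diagonal overlap and overlap coverage >= c under the
    given cov_mode, tested over every diagonal.  Used by cluster
    verification, where the k-mer-seeded diagonal is no longer known.
    """
    n = q.shape[0]
    m = t.shape[0]
    for d in range(-(m - 1), n):
        x_start = max(0, d)
        length = min(n, m + d) - x_start
        if length <= 0:
            continue
        if cov_mode == 0:
            cov = length / max(n, m)
        elif cov_mode == 1:
            cov = length / m
        else:
            cov = length / n
        if cov < c:
            continue
        ident = hamming_identical(
            q[x_start : x_start + length],
            t[x_start - d : x_start - d + length],
        )
        if ident / length >= min_seq_id:
            return True
    return False


@njit(cache=True)
def smith_waterman(q, t, scores, gap_open, gap_extend):
    """Affine-gap Smith-Waterman local alignment with traceback.

    Gap cost convention: a gap of length g costs gap_open + g * gap_extend
    (the first gap residue costs gap_open + gap_extend).  Returns
    (score, q_start, q_end, t_start, t_end, n_columns, n_identical,
    n_pairs) with 0-based inclusive segment bounds.  An all-negative
    comparison returns score 0 and an empty segment (-1 bounds).

    Tie-breaking is deterministic: the best cell is the first one reached
    in row-major scan order (smallest q_end, then t_end), and the traceback
    prefers a diagonal move over gap moves.
    """
    n = q.shape[0]
    m = t.shape[0]
    first_gap = gap_open + gap_extend

    h_prev = np.zeros(m + 1, dtype=np.int64)
    h_cur = np.zeros(m + 1, dtype=np.int64)
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = extend
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    f_col = np.full(m + 1, -10**9, dtype=np.int64)

    # F is recomputed per column inside the row loop via f_col.
    best = 0
    best_i = -1
    best_j = -1
    for i in range(1, n + 1):
        h_cur[0] = 0
        e_val = -10**9
        for j in range(1, m + 1):
            # E: gap in target (consumes q? by convention: gap along t,
            # i.e. horizontal move consuming t[j-1] with a gap in q).
            open_e = h_cur[j - 1] - first_gap
            ext_e = e_val - gap_extend
            if ext_e > open_e:
                e_val = ext_e
                ptr_e[i, j] = 1
            else:
                e_val = open_e
                ptr_e[i, j] = 0
            # F: vertical move consuming q[i-1] with a gap in t.
            open_f = h_prev[j] - first_gap
            ext_f = f_col[j] - gap_extend
            if ext_f > open_f:
                f_col[j] = ext_f
                ptr_f[i, j] = 1
            else:
                f_col[j] = open_f
                ptr_f[i, j] = 0
            diag = h_prev[j - 1] + scores[q[i - 1], t[j - 1]]
            # Prefer diagonal over E over F on ties.
            val = diag
            move = _DIAG
            if e_val > val:
                val = e_val
                move = _FROM_E
            if f_col[j] > val:
                val = f_col[j]
                move = _FROM_F
            if val <= 0:
                val = 0
                move = _STOP
            h_cur[j] = val
            ptr_h[i, j] = move
            if val > best:
                best = val
                best_i = i
                best_j = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp

    if best_i < 0:
        return 0, -1, -1, -1, -1, 0, 0, 0

    # Traceback from the best cell.
    i = best_i
    j = best_j
    n_columns = 0
    n_pairs = 0
    n_identical = 0
    state = 0  # 0 = in H, 1 = in E, 2 = in F
    while i > 0 and j > 0:
        if state == 0:
            move = ptr_h[i, j]
            if move == _STOP:
                break
            if move == _DIAG:
                n_columns += 1
                n_pairs += 1
                if q[i - 1] == t[j - 1] and q[i - 1] != WILDCARD:
                    n_identical += 1
                i -= 1
                j -= 1
            elif move == _FROM_E:
                state = 1
            else:
                state = 2
        elif state == 1:
            n_columns += 1
            ext = ptr_e[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            n_columns += 1
            ext = ptr_f[i, j]
            i -= 1
            if ext == 0:
                state = 0
    q_start = i
    t_start = j
    return (
        best,
        q_start,
        best_i - 1,
        t_start,
        best_j - 1,
        n_columns,
        n_identical,
        n_pairs,
    )
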