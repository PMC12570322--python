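"""Affine-gap local alignment kernel (Gotoh) used by the read mapper.

The mapper only needs exact local alignment on short read-vs-window problems
(~250 x ~1000), so a dense DP with full traceback is adequate.  Scoring is
integral; a gap of length L costs ``gap_open + L * gap_extend``.  Tie-breaking
is fixed (diagonal, then target-gap, then query-gap; best cell = first maximum
in row-major order) so alignments are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# cigar op codes used in the packed traceback output
OP_M, OP_I, OP_D, OP_S = 0, 1, 2, 3


@njit(cache=False)
def _gotoh_local(q, t, match, mismatch, gap_open, gap_extend):
    n = q.shape[0]
    m = t.shape[0]
    NEG = -(1 << 30)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] - gap_open - gap_extend
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            E[i, j] = e
            f = H[i - 1, j] - gap_open - gap_extend
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            F[i, j] = f
            if qi == t[j - 1] and qi < 4:
                sub = H[i - 1, j - 1] + match
            else:
                sub = H[i - 1, j - 1] + mismatch
            h = sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback from (bi, bj); states: 0=H, 1=E (gap in query, consumes t),
    # 2=F (gap in target, consumes q)
    max_ops = n + m + 2
    ops = np.empty(max_ops, dtype=np.uint8)
    lens = np.empty(max_ops, dtype=np.int32)
    n_ops = 0
    i, j = bi, bj
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if i > 0 and j > 0:
                if (q[i - 1] == t[j - 1] and q[i - 1] < 4):
                    sub = H[i - 1, j - 1] + match
                else:
                    sub = H[i - 1, j - 1] + mismatch
            else:
                sub = NEG
            if h == sub:
                op = OP_M
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
                continue
            else:
                state = 2
                continue
        elif state == 1:
            op = OP_D
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = 0
            j -= 1
        else:
            op = OP_I
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = 0
            i -= 1
        if n_ops > 0 and ops[n_ops - 1] == op:
            lens[n_ops - 1] += 1
        else:
            ops[n_ops] = op
            lens[n_ops] = 1
            n_ops += 1
    # ops were emitted backwards
    ops = ops[:n_ops][::-1].copy()
    lens = lens[:n_ops][::-1].copy()
    return best, i, bi, j, bj, ops, lens


def local_align(q: np.ndarray, t: np.ndarray, match: int, mismatch: int,
                gap_open: int, gap_extend: int):
    """Best local alignment of query codes ``q`` against target codes ``t``.

    Returns ``(score, q_start, q_end, t_start, t_end, [(op, length), ...])``
    with half-open coordinates and ops in {'M','I','D'} ('I' consumes query,
    'D' consumes target).  Score 0 means no positive-scoring alignment.
    """
    score, qb, qe, tb, te, ops, lens = _gotoh_local(
        np.ascontiguousarray(q), np.ascontiguousarray(t),
        match, mismatch, gap_open, gap_extend)
    names = "MID S"
    cigar = [(names[o], int(l)) for o, l in zip(ops, lens)]
    return int(score), int(qb), int(qe), int(tb), int(te), cigar
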