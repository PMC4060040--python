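"""Affine-gap dynamic-programming kernels (numba-compiled).

One scoring scheme is used everywhere (aligner, mate rescue, realigner):
match +1, mismatch -4, gap open -6, gap extend -1, where a gap of length L
costs 6 + L in total.  Alignments are local in the Smith-Waterman sense:
the read may start anywhere in the supplied reference window and read ends
are soft-clipped whenever clipping improves the score.  An N base (code 4)
on either side scores as a mismatch, never as a match.

Op codes used in tracebacks: 0=M (match run), 1=X (single mismatch),
2=I (insertion in read), 3=D (deletion from reference), 4=S (soft clip).
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -4
GAP_OPEN = -6   # charged once per gap, on top of the per-base extend
GAP_EXTEND = -1

OP_M, OP_X, OP_I, OP_D, OP_S = 0, 1, 2, 3, 4
OP_CHARS = "MXIDS"

NEG = -10 ** 6


@njit(cache=True)
def sw_score(read: np.ndarray, window: np.ndarray) -> int:
    """Best local (soft-clip tolerant) affine-gap score of read vs window."""
    n, m = len(read), len(window)
    open_cost = -(GAP_OPEN + GAP_EXTEND)  # 7: a length-L gap costs 6 + L
    ext = -GAP_EXTEND
    h = np.zeros(m + 1, dtype=np.int32)
    e = np.full(m + 1, NEG, dtype=np.int32)
    best = 0
    for i in range(1, n + 1):
        rb = read[i - 1]
        h_diag = h[0]
        h_left = 0
        f = NEG
        for j in range(1, m + 1):
            wb = window[j - 1]
            s = MATCH if (rb == wb and rb != 4) else MISMATCH
            up = h[j]  # H[i-1][j]
            e[j] = max(up - open_cost, e[j] - ext)   # gap in ref (read insertion)
            f = max(h_left - open_cost, f - ext)     # gap in read (ref deletion)
            v = h_diag + s
            if e[j] > v:
                v = e[j]
            if f > v:
                v = f
            if v < 0:
                v = 0
            h[j] = v
            h_diag = up
            h_left = v
            if v > best:
                best = v
    return best


@njit(cache=True)
def sw_align(read: np.ndarray, window: np.ndarray):
    """Local affine-gap alignment with traceback.

    Returns (score, win_start, win_end, op_codes, op_lens) where win_start /
    win_end delimit the aligned window span (half-open) and the ops cover the
    whole read (soft clips included).  An empty/negative alignment returns
    score 0 and no ops.
    """
    n, m = len(read), len(window)
    open_cost = -(GAP_OPEN + GAP_EXTEND)
    ext = -GAP_EXTEND
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in ref (read insertion)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in read (ref deletion)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        rb = read[i - 1]
        for j in range(1, m + 1):
            wb = window[j - 1]
            s = MATCH if (rb == wb and rb != 4) else MISMATCH
            e = max(H[i - 1, j] - open_cost, E[i - 1, j] - ext)
            f = max(H[i, j - 1] - open_cost, F[i, j - 1] - ext)
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:  # first maximal cell in row-major order: deterministic
                best = h
                bi = i
                bj = j
    op_codes = np.empty(2 * n + 4, dtype=np.int32)
    op_lens = np.empty(2 * n + 4, dtype=np.int32)
    nops = 0
    if best <= 0:
        return 0, 0, 0, op_codes[:0], op_lens[:0]
    i, j = bi, bj
    state = 0  # 0=H, 1=E(ins), 2=F(del)
    # collect reversed ops
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            rb = read[i - 1]
            wb = window[j - 1]
            s = MATCH if (rb == wb and rb != 4) else MISMATCH
            if H[i, j] == H[i - 1, j - 1] + s:
                code = OP_M if s == MATCH else OP_X
                if nops > 0 and op_codes[nops - 1] == code:
                    op_lens[nops - 1] += 1
                else:
                    op_codes[nops] = code
                    op_lens[nops] = 1
                    nops += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:  # insertion: consumes read
            if nops > 0 and op_codes[nops - 1] == OP_I:
                op_lens[nops - 1] += 1
            else:
                op_codes[nops] = OP_I
                op_lens[nops] = 1
                nops += 1
            if E[i, j] == H[i - 1, j] - open_cost:
                state = 0
            i -= 1
        else:  # deletion: consumes window
            if nops > 0 and op_codes[nops - 1] == OP_D:
                op_lens[nops - 1] += 1
            else:
                op_codes[nops] = OP_D
                op_lens[nops] = 1
                nops += 1
            if F[i, j] == H[i, j - 1] - open_cost:
                state = 0
            j -= 1
    win_start = j
    win_end = bj
    # reverse ops
    rev_codes = np.empty(nops + 2, dtype=np.int32)
    rev_lens = np.empty(nops + 2, dtype=np.int32)
    k = 0
    if i > 0:  # leading soft clip
        rev_codes[k] = OP_S
        rev_lens[k] = i
        k += 1
    for t in range(nops - 1, -1, -1):
        rev_codes[k] = op_codes[t]
        rev_lens[k] = op_lens[t]
        k += 1
    if bi < n:  # trailing soft clip
        rev_codes[k] = OP_S
        rev_lens[k] = n - bi
        k += 1
    return best, win_start, win_end, rev_codes[:k], rev_lens[:k]


def hamming_ops(read: np.ndarray, refseg: np.ndarray):
    """Gapless edit script and score of read vs an equal-length ref segment.

    Returns (score, ops, n_mismatch); N on either side counts as a mismatch.
    """
    mism = (read != refseg) | (read == 4) | (refseg == 4)
    nmis = int(mism.sum())
    score = (len(read) - nmis) * MATCH + nmis * MISMATCH
    ops: list[tuple[str, int]] = []
    if nmis == 0:
        return score, [("M", len(read))], 0
    idx = np.flatnonzero(mism)
    prev = 0
    for p in idx:
        if p > prev:
            ops.append(("M", int(p - prev)))
        ops.append(("X", 1))
        prev = int(p) + 1
    if prev < len(read):
        ops.append(("M", len(read) - prev))
    return score, ops, nmis


def ops_from_arrays(op_codes: np.ndarray, op_lens: np.ndarray) -> list[tuple[str, int]]:
    """Convert kernel traceback arrays to [('M', n), ('X', 1), ...] form."""
    out = []
    for c, l in zip(op_codes, op_lens):
        ch = OP_CHARS[c]
        if ch == "X":
            out.extend([("X", 1)] * int(l))
        else:
            out.append((ch, int(l)))
    return out


def warm_up() -> None:
    """Trigger numba compilation of the kernels on tiny inputs."""
    r = np.array([0, 1, 2, 3], dtype=np.uint8)
    sw_score(r, r)
    sw_align(r, r)
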