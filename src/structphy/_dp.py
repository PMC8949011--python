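"""Numba kernel: global alignment DP with an opening-only gap cost.

Three-state affine Needleman-Wunsch maximising the sum of per-pair
similarity scores minus a gap-open penalty (gap extension is free), as
used by the iterative structural aligner.  Ties are broken with a fixed
state preference (match > gap-in-B > gap-in-A) so the traceback is
deterministic.
"""

import numpy as np
from numba import njit

NEG = -1e18


@njit(cache=True)
def nw_open_only(S, gap_open):
    """Align the rows of A (i) to the rows of B (j) given score matrix S.

    Returns an (k, 2) int64 array of aligned (i, j) index pairs, both
    columns strictly increasing.
    """
    la, lb = S.shape
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B: i consumed
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A: j consumed
    # traceback: which state each cell came from (0=M, 1=X, 2=Y)
    tM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tY = np.zeros((la + 1, lb + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open
        tX[i, 0] = 1 if i > 1 else 0
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open
        tY[0, j] = 2 if j > 1 else 0

    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            # M: consume (i, j)
            best = M[i - 1, j - 1]
            src = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                src = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                src = 2
            M[i, j] = best + S[i - 1, j - 1]
            tM[i, j] = src
            # X: consume i only
            best = M[i - 1, j] - gap_open
            src = 0
            if X[i - 1, j] > best:
                best = X[i - 1, j]
                src = 1
            if Y[i - 1, j] - gap_open > best:
                best = Y[i - 1, j] - gap_open
                src = 2
            X[i, j] = best
            tX[i, j] = src
            # Y: consume j only
            best = M[i, j - 1] - gap_open
            src = 0
            if X[i, j - 1] - gap_open > best:
                best = X[i, j - 1] - gap_open
                src = 1
            if Y[i, j - 1] > best:
                best = Y[i, j - 1]
                src = 2
            Y[i, j] = best
            tY[i, j] = src

    # terminal state, fixed preference M > X > Y
    state = 0
    best = M[la, lb]
    if X[la, lb] > best:
        best = X[la, lb]
        state = 1
    if Y[la, lb] > best:
        best = Y[la, lb]
        state = 2

    pairs = np.empty((min(la, lb), 2), dtype=np.int64)
    k = 0
    i, j = la, lb
    while i > 0 or j > 0:
        if state == 0:
            prev = tM[i, j]
            i -= 1
            j -= 1
            pairs[k, 0] = i
            pairs[k, 1] = j
            k += 1
            state = prev
        elif state == 1:
            prev = tX[i, j]
            i -= 1
            state = prev
        else:
            prev = tY[i, j]
            j -= 1
            state = prev
    return pairs[:k][::-1].copy()
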