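"""Numba-accelerated dynamic-programming kernel for local profile alignment.

The fill routine is the only O(L1*L2) inner loop in the package; everything
around it (column scoring, traceback, island labelling) is vectorized numpy
or negligible Python.  A pure-Python fallback keeps the package importable
if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


# move codes in the traceback matrix
NONE, DIAG, UP, LEFT = 0, 1, 2, 3


@njit(cache=False)
def fill(S, gx, gy):
    """Fill the local-alignment matrix.

    Parameters
    ----------
    S : (L1, L2) float array of column-vector similarity scores.
    gx : (L1,) gap penalties for aligning a column of X to a gap.
    gy : (L2,) gap penalties for aligning a column of Y to a gap.

    Returns
    -------
    H : (L1+1, L2+1) score matrix with zero borders.
    moves : (L1+1, L2+1) uint8 matrix of move codes (0 none, 1 diag,
        2 up = consume X column, 3 left = consume Y column).  Ties break
        diagonal > up > left for a deterministic traceback.
    """
    n1, n2 = S.shape
    H = np.zeros((n1 + 1, n2 + 1), dtype=np.float64)
    moves = np.zeros((n1 + 1, n2 + 1), dtype=np.uint8)
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            best = 0.0
            move = 0
            d = H[i - 1, j - 1] + S[i - 1, j - 1]
            if d > best:
                best = d
                move = 1
            u = H[i - 1, j] - gx[i - 1]
            if u > best:
                best = u
                move = 2
            l = H[i, j - 1] - gy[j - 1]
            if l > best:
                best = l
                move = 3
            H[i, j] = best
            moves[i, j] = move
    return H, moves
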