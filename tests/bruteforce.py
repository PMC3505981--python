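"""Exhaustive enumeration oracle for gapped local profile alignment.

Independent of the dynamic-programming implementation: every candidate
local alignment is a monotone path of diagonal (match), up (gap a column of
X) and left (gap a column of Y) moves; its score is the sum of move scores.
The oracle enumerates every path starting with a match at every cell by
depth-first search and records the running maximum over all prefixes.
Feasible only for tiny matrices.
"""

import numpy as np

from chromalign.alignment import AlignParams, column_score_matrix, gap_vector


def brute_local_score(X, Y, params: AlignParams) -> float:
    """Maximum score over all local alignment paths (0 if nothing positive)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    S = column_score_matrix(X, Y, params)
    gx = gap_vector(X, params)
    gy = gap_vector(Y, params)
    l1, l2 = S.shape
    best = 0.0
    # stack entries: (last consumed X col, last consumed Y col, running score)
    for i0 in range(l1):
        for j0 in range(l2):
            stack = [(i0, j0, S[i0, j0])]
            while stack:
                i, j, acc = stack.pop()
                if acc > best:
                    best = acc
                if i + 1 < l1 and j + 1 < l2:
                    stack.append((i + 1, j + 1, acc + S[i + 1, j + 1]))
                if i + 1 < l1:
                    stack.append((i + 1, j, acc - gx[i + 1]))
                if j + 1 < l2:
                    stack.append((i, j + 1, acc - gy[j + 1]))
    return best
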