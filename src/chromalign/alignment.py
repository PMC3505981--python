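"""Gapped local alignment of multi-mark score-profile matrices.

A region's profile matrix is treated as a string of per-bin column vectors.
Two columns are compared by an angle-amplified cosine similarity damped by a
norm-dependent weight: the amplification factor ``gamma`` sharpens the
distinction between similar and dissimilar mark combinations (the score of
a pair of columns turns negative once the amplified angle passes pi/2), and
the weight sends near-empty bins toward zero so background cannot build up
alignment score.  Gaps cost in proportion to the norm of the skipped
column, so empty stretches act as nearly free spacers — this is what lets
one signature span alternating conserved and variant segments — while
skipping a strongly marked bin is expensive.

The best local alignment is found with a Smith-Waterman-style recurrence
with zero floor; every pair of regions is compared in both orientations
because a signature can recur on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, NamedTuple, Optional, Tuple

import numpy as np

from . import _dp
from .regions import ProfileMatrix

__all__ = [
    "AlignParams",
    "PathStep",
    "AlignmentResult",
    "Island",
    "column_score",
    "column_score_matrix",
    "gap_penalty",
    "gap_vector",
    "local_align",
    "align_pair",
    "extract_islands",
    "island_peaks",
]


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for profile alignment.

    gamma : angle amplification (>= 1); 2 for small-region comparisons,
        1.5 for medium/large — small regions demand tighter similarity.
    beta : weight stringency (> 0); larger beta shrinks the weight of
        low-coverage columns.
    delta : gap stringency (> 0); larger for small-region comparisons.
    epsilon : columns with norm below this floor score 0 and cost no gap.
    """

    gamma: float = 2.0
    beta: float = 0.3
    delta: float = 0.5
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.beta <= 0 or self.delta <= 0:
            raise ValueError("beta and delta must be positive")

    @classmethod
    def for_size_class(cls, size_class: str, **overrides) -> "AlignParams":
        """Defaults per region size class: stricter for small regions."""
        if size_class == "small":
            base = cls(gamma=2.0, delta=0.5)
        elif size_class in ("medium", "large"):
            base = cls(gamma=1.5, delta=0.3)
        else:
            raise ValueError(f"unknown size class {size_class!r}")
        return replace(base, **overrides) if overrides else base


class PathStep(NamedTuple):
    """One traceback move; the unconsumed side of a gap move is None."""

    move: str  # "diag" | "up" | "left"
    x_col: Optional[int]
    y_col: Optional[int]


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment between two profile matrices.

    ``path`` runs from the first to the last aligned pair of columns;
    ``x_interval``/``y_interval`` are the half-open column ranges the path
    projects onto (both in forward-frame coordinates; for ``opposite``
    orientation the y columns along the path therefore decrease).
    """

    score: float
    path: Tuple[PathStep, ...]
    x_interval: Tuple[int, int]
    y_interval: Tuple[int, int]
    orientation: str = "same"


@dataclass(frozen=True)
class Island:
    """A connected set of positive alignment cells sharing traceback ancestry."""

    peak_score: float
    anchor: Tuple[int, int]  # (x_col, y_col) of the peak cell

    def __post_init__(self) -> None:
        if self.peak_score <= 0:
            raise ValueError("island peak score must be positive")


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, ProfileMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def column_score(u, v, params: AlignParams = AlignParams()) -> float:
    """Weighted angle-amplified cosine similarity of two bin column vectors.

    Raw score s = cos(min(gamma * theta, pi)) with theta the angle between
    u and v; weight w = nbar / (nbar + beta) with nbar the smaller of the
    two norms scaled by 1/sqrt(M).  Columns with norm below epsilon score 0.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"column length mismatch: {u.shape} vs {v.shape}")
    return float(column_score_matrix(u[:, None], v[:, None], params)[0, 0])


def column_score_matrix(X, Y, params: AlignParams = AlignParams()) -> np.ndarray:
    """All-pairs column scores between the columns of X (M x L1) and Y (M x L2)."""
    X = _as_matrix(X)
    Y = _as_matrix(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"mark-dimension mismatch: {X.shape[0]} vs {Y.shape[0]}")
    m = X.shape[0]
    nx = np.linalg.norm(X, axis=0)
    ny = np.linalg.norm(Y, axis=0)
    ok = (nx[:, None] >= params.epsilon) & (ny[None, :] >= params.epsilon)
    denom = np.where(ok, nx[:, None] * ny[None, :], 1.0)
    cosines = np.clip((X.T @ Y) / denom, -1.0, 1.0)
    theta = np.arccos(cosines)
    raw = np.cos(np.minimum(params.gamma * theta, np.pi))
    nbar = np.minimum(nx[:, None], ny[None, :]) / np.sqrt(m)
    weight = nbar / (nbar + params.beta)
    return np.where(ok, raw * weight, 0.0)


def gap_penalty(u, params: AlignParams = AlignParams()) -> float:
    """Penalty for aligning column u to a gap: delta * ||u|| / sqrt(M)."""
    u = np.asarray(u, dtype=float)
    return float(params.delta * np.linalg.norm(u) / np.sqrt(u.shape[0]))


def gap_vector(X, params: AlignParams = AlignParams()) -> np.ndarray:
    """Per-column gap penalties for a profile matrix."""
    X = _as_matrix(X)
    norms = np.linalg.norm(X, axis=0)
    pen = params.delta * norms / np.sqrt(X.shape[0])
    pen[norms < params.epsilon] = 0.0
    return pen


def _fill(X: np.ndarray, Y: np.ndarray, params: AlignParams):
    S = column_score_matrix(X, Y, params)
    return _dp.fill(S, gap_vector(X, params), gap_vector(Y, params))


def _traceback(H: np.ndarray, moves: np.ndarray) -> Tuple[float, List[PathStep]]:
    if H.size == 0 or H.max() <= 0.0:
        return 0.0, []
    flat = int(np.argmax(H))  # first maximum in row-major order
    i, j = divmod(flat, H.shape[1])
    score = float(H[i, j])
    steps: List[PathStep] = []
    while moves[i, j] != _dp.NONE:
        m = moves[i, j]
        if m == _dp.DIAG:
            steps.append(PathStep("diag", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif m == _dp.UP:
            steps.append(PathStep("up", i - 1, None))
            i -= 1
        else:
            steps.append(PathStep("left", None, j - 1))
            j -= 1
    steps.reverse()
    return score, steps


def _projections(steps: List[PathStep]) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    xs = [s.x_col for s in steps if s.x_col is not None]
    ys = [s.y_col for s in steps if s.y_col is not None]
    xi = (min(xs), max(xs) + 1) if xs else (0, 0)
    yi = (min(ys), max(ys) + 1) if ys else (0, 0)
    return xi, yi


def local_align(X, Y, params: AlignParams = AlignParams()) -> AlignmentResult:
    """Best gapped local alignment of two profile matrices (same orientation).

    The recurrence is H(i,j) = max(0, diag + score, up - gap, left - gap)
    with zero borders; the result is the global maximum cell traced back to
    the first zero.  Ties break diagonal > up > left, and the first maximal
    cell in row-major order wins, making the path deterministic.
    """
    Xm, Ym = _as_matrix(X), _as_matrix(Y)
    if Xm.shape[1] == 0 or Ym.shape[1] == 0:
        return AlignmentResult(0.0, (), (0, 0), (0, 0), "same")
    H, moves = _fill(Xm, Ym, params)
    score, steps = _traceback(H, moves)
    xi, yi = _projections(steps)
    return AlignmentResult(score, tuple(steps), xi, yi, "same")


def _reverse_result(res: AlignmentResult, ly: int) -> AlignmentResult:
    """Map a result computed against column-reversed Y back to Y's forward frame."""
    steps = tuple(
        PathStep(s.move, s.x_col, None if s.y_col is None else ly - 1 - s.y_col)
        for s in res.path
    )
    a, b = res.y_interval
    y_interval = (ly - b, ly - a) if b > a else (0, 0)
    return AlignmentResult(res.score, steps, res.x_interval, y_interval, "opposite")


def align_pair(X, Y, params: AlignParams = AlignParams()) -> AlignmentResult:
    """Align X and Y in both orientations; return the better result.

    The opposite-orientation alignment runs against column-reversed Y and
    its coordinates are mapped back to Y's forward frame.  On an exact tie
    the same orientation is preferred.
    """
    Ym = _as_matrix(Y)
    fwd = local_align(X, Ym, params)
    rev = local_align(X, Ym[:, ::-1], params)
    if rev.score > fwd.score:
        return _reverse_result(rev, Ym.shape[1])
    return fwd


def extract_islands(
    X, Y, params: AlignParams = AlignParams(), threshold: float = 0.0
) -> List[Island]:
    """All traceback-connected islands of positive cells with peak >= threshold.

    Two positive cells belong to the same island when the traceback parent
    of one is the other (transitively); each island contributes its peak
    score, the statistic the extreme-value null is fitted on.
    """
    Xm, Ym = _as_matrix(X), _as_matrix(Y)
    if Xm.shape[1] == 0 or Ym.shape[1] == 0:
        return []
    H, moves = _fill(Xm, Ym, params)
    peaks: dict[int, Tuple[float, int]] = {}
    n2 = H.shape[1]
    root = np.full(H.shape, -1, dtype=np.int64)
    pos = np.argwhere(H > 0.0)
    for i, j in pos:
        m = moves[i, j]
        if m == _dp.DIAG:
            pi, pj = i - 1, j - 1
        elif m == _dp.UP:
            pi, pj = i - 1, j
        else:
            pi, pj = i, j - 1
        r = root[pi, pj] if H[pi, pj] > 0.0 else i * n2 + j
        root[i, j] = r
        h = float(H[i, j])
        cur = peaks.get(r)
        if cur is None or h > cur[0]:
            peaks[r] = (h, i * n2 + j)
    islands = []
    for r in sorted(peaks):
        h, cell = peaks[r]
        if h >= threshold:
            i, j = divmod(cell, n2)
            islands.append(Island(peak_score=h, anchor=(i - 1, j - 1)))
    return islands


def island_peaks(
    X, Y, params: AlignParams = AlignParams(), threshold: float = 0.0
) -> np.ndarray:
    """Island peak scores from both orientations, pooled (for null sampling)."""
    Ym = _as_matrix(Y)
    out = [isl.peak_score for isl in extract_islands(X, Ym, params, threshold)]
    out += [isl.peak_score for isl in extract_islands(X, Ym[:, ::-1], params, threshold)]
    return np.asarray(out, dtype=float)
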