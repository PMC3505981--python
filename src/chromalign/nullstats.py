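"""Island-method extreme-value calibration of alignment scores.

Randomly sampled pairs of regions from a group serve as the null: their
alignments produce "islands" of positive score whose peak heights, above a
threshold T in the tail, are approximately exponential with rate lambda.
With K the island density per unit of search area, the best score S of a
pair searched over an L1 x L2 area is then Gumbel-tailed and

    P(best >= S) = 1 - exp(-K * L1 * L2 * exp(-lambda * S)).

lambda is fitted by maximum likelihood on the exponential excesses over T
and K from the island count per unit area.  Two practical points shape the
default policy.  First, a random sample of pairs inevitably catches some
*truly related* pairs, and a single related pair floods the pool with
dozens of high islands; the unit of decontamination is therefore the pair:
pairs whose best island is a far outlier (Tukey fence, > Q3 + 3 IQR of the
per-pair maxima) are discarded wholesale before fitting.  On genuinely
unrelated data this removes almost nothing.  Second, the island-height
distribution decays faster than exponential at low heights (bounded
per-column scores; most islands are one- or two-cell fragments), so an
excess rate fitted from a low threshold badly misstates the far tail.  T is
therefore placed at the median of the positive per-pair *maximum* island
scores — the scale at which best-score P-values are actually evaluated, and
a robust statistic under residual contamination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .alignment import AlignParams, island_peaks

__all__ = [
    "EVDParams",
    "sample_null_islands",
    "trim_related_pairs",
    "choose_island_threshold",
    "fit_evd",
    "alignment_pvalue",
    "MIN_ISLANDS",
]

#: minimum number of islands required for a stable fit
MIN_ISLANDS = 50


@dataclass(frozen=True)
class EVDParams:
    """Extreme-value parameters converting alignment scores to P-values."""

    lam: float
    k: float
    threshold: float
    n_islands: int
    group_key: object = None

    def __post_init__(self) -> None:
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ValueError(f"lambda must be positive and finite, got {self.lam}")
        if not (self.k > 0 and np.isfinite(self.k)):
            raise ValueError(f"K must be positive and finite, got {self.k}")


def _sample_pairs(n: int, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct unordered index pairs (i < j), sampled without replacement."""
    total = n * (n - 1) // 2
    take = min(n_pairs, total)
    flat = rng.choice(total, size=take, replace=False) if take < total else np.arange(total)
    # invert the row-major upper-triangle enumeration
    pairs = np.empty((take, 2), dtype=np.int64)
    for out, f in zip(pairs, np.sort(flat)):
        i = int((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * f)) // 2)
        first = i * (2 * n - i - 1) // 2
        out[0] = i
        out[1] = f - first + i + 1
    return pairs


def sample_null_islands(
    group: Sequence,
    n_pairs: int,
    params: AlignParams,
    threshold: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> Tuple[np.ndarray, float, List[Tuple[int, int]]]:
    """Pool island peaks from randomly sampled region pairs of one group.

    Pairs are drawn without replacement among the distinct unordered pairs;
    islands are pooled from both orientations of each pair and filtered at
    ``threshold``.  Returns ``(scores, total_area, pairs)`` where
    ``total_area`` is the summed L1*L2 search area (one orientation; the
    two-orientation search is absorbed into K, matching its use on the
    two-orientation best score downstream).

    ``group`` may hold ProfileMatrix objects or plain M x L arrays.
    """
    if len(group) < 2:
        raise ValueError("null sampling needs a group of at least 2 regions")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = _sample_pairs(len(group), n_pairs, rng)
    scores: List[np.ndarray] = []
    area = 0.0
    out_pairs: List[Tuple[int, int]] = []
    for i, j in pairs:
        X, Y = group[i], group[j]
        peaks = island_peaks(X, Y, params, threshold)
        scores.append(peaks)
        lx = X.values.shape[1] if hasattr(X, "values") else np.asarray(X).shape[1]
        ly = Y.values.shape[1] if hasattr(Y, "values") else np.asarray(Y).shape[1]
        area += float(lx * ly)
        out_pairs.append((int(i), int(j)))
    pooled = np.concatenate(scores) if scores else np.empty(0)
    return pooled, area, out_pairs


def trim_related_pairs(
    per_pair_scores: Sequence[np.ndarray], fence: float = 3.0
) -> List[int]:
    """Indices of pairs retained after discarding best-score outliers.

    A pair whose maximum island score exceeds Q3 + ``fence`` * IQR of the
    per-pair maxima (zeros included) is treated as a genuinely related pair
    that slipped into the random sample and is excluded from the null.
    """
    maxima = np.array([s.max() if s.size else 0.0 for s in per_pair_scores])
    if maxima.size == 0:
        return []
    q1, q3 = np.quantile(maxima, [0.25, 0.75])
    cut = q3 + fence * (q3 - q1)
    return [i for i, m in enumerate(maxima) if m <= cut]


def choose_island_threshold(
    per_pair_scores: Sequence[np.ndarray], quantile: float = 0.5
) -> float:
    """Island threshold T = quantile of the positive per-pair best scores.

    ``per_pair_scores`` holds each (retained) pair's island peaks collected
    with threshold 0.  The per-pair maximum is the statistic P-values are
    computed for, and the excess distribution is exponential only at that
    scale; pairs without any positive island are ignored.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    if not per_pair_scores:
        raise ValueError("no pairs to choose a threshold from")
    maxima = np.array(
        [s.max() for s in map(np.asarray, per_pair_scores) if s.size and s.max() > 0]
    )
    if maxima.size == 0:
        raise ValueError("island threshold is not positive; group has no signal")
    return float(np.quantile(maxima, quantile))


def fit_evd(
    island_scores: Sequence[float],
    threshold: float,
    total_area: float,
    min_islands: int = MIN_ISLANDS,
    group_key: object = None,
) -> EVDParams:
    """Fit (lambda, K) from island peaks at or above the threshold.

    lambda-hat = 1 / mean(S_i - T), the exponential maximum-likelihood
    estimate of the excess rate; K-hat = (n / total_area) * exp(lambda * T),
    the island density extrapolated back to score zero.
    """
    scores = np.asarray(island_scores, dtype=float)
    scores = scores[scores >= threshold]
    if scores.size < min_islands:
        raise ValueError(
            f"only {scores.size} islands >= threshold; need {min_islands} "
            "(increase n_pairs or lower the threshold)"
        )
    if total_area <= 0:
        raise ValueError("total search area must be positive")
    mean_excess = float(np.mean(scores - threshold))
    if mean_excess <= 0:
        raise ValueError("all island scores equal the threshold; cannot fit lambda")
    lam = 1.0 / mean_excess
    k = scores.size / total_area * float(np.exp(lam * threshold))
    return EVDParams(lam=lam, k=k, threshold=threshold,
                     n_islands=int(scores.size), group_key=group_key)


def alignment_pvalue(score: float, evd: EVDParams, l1: int, l2: int) -> float:
    """P-value of a best alignment score over an L1 x L2 search.

    P = 1 - exp(-K * L1 * L2 * exp(-lambda * S)); decreasing in S,
    increasing in the search area.  A non-positive score gets P = 1.
    """
    if l1 < 0 or l2 < 0:
        raise ValueError("region lengths must be non-negative")
    if score <= 0.0 or l1 == 0 or l2 == 0:
        return 1.0
    e = evd.k * l1 * l2 * np.exp(-evd.lam * score)
    return float(min(1.0, max(0.0, -np.expm1(-e))))
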