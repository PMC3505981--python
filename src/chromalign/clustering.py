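"""Tree clustering of regions by pairwise alignment P-values.

Pairwise P-values act directly as distances: an average-linkage (UPGMA)
dendrogram built on them has merge heights that read as approximate
P-values among sub-groups, so cutting the tree at a chosen significance
level (0.05 by default) yields clusters of regions whose members are all
mutually similar at that confidence.  Each cluster's signature is
summarized by projecting every member onto the cluster medoid through its
pairwise alignment path and averaging the projected scores per column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .alignment import AlignmentResult
from .regions import ProfileMatrix

__all__ = [
    "DistanceMatrix",
    "SignatureCluster",
    "build_distance_matrix",
    "cluster_tree",
    "cut_tree",
    "consensus_profile",
    "member_footprints",
    "linkage_to_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise P-values with a zero diagonal."""

    ids: Tuple[object, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if m.size and (m.min() < 0.0 or m.max() > 1.0):
            raise ValueError("P-value distances must lie in [0, 1]")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class SignatureCluster:
    """A recurrent chromatin signature: members, footprints and consensus.

    ``footprints`` gives, per member, the half-open column interval of that
    member's aligned sub-region (union of its aligned intervals with the
    other cluster members, in the member's forward frame).  ``consensus``
    is the M x Lc mean score profile in the medoid's frame.
    """

    cluster_id: int
    members: List[object]
    medoid: object
    footprints: Dict[object, Tuple[int, int]]
    consensus: np.ndarray
    size_class: Optional[str] = None


def build_distance_matrix(
    ids: Sequence[object], pvalues: Mapping[Tuple[object, object], float]
) -> DistanceMatrix:
    """Arrange pairwise P-values into a symmetric distance matrix.

    Missing pairs default to distance 1 (no detectable similarity).  A pair
    supplied in both orders with conflicting values is rejected.
    """
    ids = tuple(ids)
    index = {rid: i for i, rid in enumerate(ids)}
    n = len(ids)
    m = np.ones((n, n))
    np.fill_diagonal(m, 0.0)
    seen: Dict[Tuple[int, int], float] = {}
    for (a, b), p in pvalues.items():
        i, j = index[a], index[b]
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen and not np.isclose(seen[key], p):
            raise ValueError(f"asymmetric P-values for pair {(a, b)!r}")
        seen[key] = float(p)
        m[i, j] = m[j, i] = float(p)
    return DistanceMatrix(ids=ids, matrix=m)


def cluster_tree(d: DistanceMatrix) -> np.ndarray:
    """Average-linkage dendrogram (scipy linkage matrix) on P-value distances."""
    if d.n < 2:
        return np.empty((0, 4))
    return average(squareform(d.matrix, checks=False))


def cut_tree(
    linkage: np.ndarray,
    p_threshold: float,
    n_leaves: int,
    min_cluster_size: int = 3,
) -> Tuple[List[List[int]], List[int]]:
    """Cut the dendrogram at a P-value threshold.

    Clusters are the maximal subtrees whose internal merge heights are all
    strictly below ``p_threshold``.  Groups smaller than
    ``min_cluster_size`` are returned as unclustered: a recurrent signature
    needs at least that many instances.

    Returns ``(clusters, unclustered)`` as lists of leaf indices.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    if n_leaves == 1:
        labels = np.array([1])
    else:
        # fcluster merges at height <= t; back off one ulp for a strict cut
        t = np.nextafter(p_threshold, 0.0)
        labels = fcluster(linkage, t=t, criterion="distance")
    groups: Dict[int, List[int]] = {}
    for leaf, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(leaf)
    clusters = [g for _, g in sorted(groups.items()) if len(g) >= min_cluster_size]
    clusters.sort(key=lambda g: g[0])
    unclustered = sorted(
        leaf for _, g in groups.items() if len(g) < min_cluster_size for leaf in g
    )
    return clusters, unclustered


def _union_interval(
    intervals: List[Tuple[int, int]], fallback: Tuple[int, int]
) -> Tuple[int, int]:
    spans = [(a, b) for a, b in intervals if b > a]
    if not spans:
        return fallback
    return (min(a for a, _ in spans), max(b for _, b in spans))


def _pair_alignment(
    alignments: Mapping[Tuple[object, object], AlignmentResult], a: object, b: object
):
    """Return (result, a_is_x) for the stored alignment of the pair {a, b}."""
    if (a, b) in alignments:
        return alignments[(a, b)], True
    if (b, a) in alignments:
        return alignments[(b, a)], False
    raise KeyError(f"no alignment stored for pair {(a, b)!r}")


def member_footprints(
    members: Sequence[object],
    alignments: Mapping[Tuple[object, object], AlignmentResult],
    lengths: Mapping[object, int],
) -> Dict[object, Tuple[int, int]]:
    """Each member's footprint: union of its aligned intervals with co-members."""
    out: Dict[object, Tuple[int, int]] = {}
    for a in members:
        spans = []
        for b in members:
            if b == a:
                continue
            res, a_is_x = _pair_alignment(alignments, a, b)
            spans.append(res.x_interval if a_is_x else res.y_interval)
        out[a] = _union_interval(spans, (0, lengths[a]))
    return out


def consensus_profile(
    members: Sequence[object],
    profiles: Mapping[object, ProfileMatrix],
    dist: DistanceMatrix,
    alignments: Mapping[Tuple[object, object], AlignmentResult],
) -> Tuple[object, Tuple[int, int], np.ndarray]:
    """Consensus signature of a cluster in its medoid's frame.

    The medoid is the member with the smallest summed P-value distance to
    the other members (ties break on matrix order).  Every other member's
    aligned columns are projected onto the medoid through the diagonal
    steps of its pairwise alignment path — orientation normalization is
    inherent in the stored forward-frame paths — and the consensus is the
    per-column, per-mark mean over all projected observations (gap columns
    simply contribute nothing).

    Returns ``(medoid_id, medoid_footprint, consensus)`` with consensus of
    shape M x footprint-length.
    """
    idx = {rid: i for i, rid in enumerate(dist.ids)}
    rows = [idx[m] for m in members]
    sub = dist.matrix[np.ix_(rows, rows)]
    medoid = members[int(np.argmin(sub.sum(axis=1)))]
    med_prof = profiles[medoid].values

    # medoid footprint: union of its aligned intervals with other members
    spans = []
    proj: List[Tuple[np.ndarray, np.ndarray]] = []  # (medoid cols, member values)
    for b in members:
        if b == medoid:
            continue
        res, med_is_x = _pair_alignment(alignments, medoid, b)
        spans.append(res.x_interval if med_is_x else res.y_interval)
        mcols, bcols = [], []
        for step in res.path:
            if step.move != "diag":
                continue
            mc = step.x_col if med_is_x else step.y_col
            bc = step.y_col if med_is_x else step.x_col
            mcols.append(mc)
            bcols.append(bc)
        if mcols:
            proj.append(
                (np.asarray(mcols), profiles[b].values[:, np.asarray(bcols)])
            )
    f0, f1 = _union_interval(spans, (0, med_prof.shape[1]))
    lc = f1 - f0
    m = med_prof.shape[0]
    sums = med_prof[:, f0:f1].copy()
    counts = np.ones((m, lc))
    for mcols, values in proj:
        inside = (mcols >= f0) & (mcols < f1)
        cols = mcols[inside] - f0
        np.add.at(sums, (slice(None), cols), values[:, inside])
        counts[:, cols] += 1.0
    return medoid, (f0, f1), sums / counts


def linkage_to_newick(linkage: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string.

    Branch lengths are differences of merge heights, so root-to-leaf path
    lengths reproduce the cophenetic (P-value) heights.
    """
    n = len(leaf_names)
    if n == 1:
        return f"{leaf_names[0]}:0;"
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: str(leaf_names[i]) for i in range(n)}
    for k, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + k] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
        heights[n + k] = h
    return nodes[n + len(linkage) - 1] + ";"
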