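"""Distance matrices, tree building, threshold cuts and consensus profiles."""

import numpy as np
import pytest

from chromalign import (
    AlignParams,
    align_pair,
    build_distance_matrix,
    cluster_tree,
    consensus_profile,
    cut_tree,
)
from chromalign.clustering import linkage_to_newick, member_footprints

PARAMS = AlignParams(gamma=2.0, beta=0.3, delta=0.5)


class FakeProfile:
    """Minimal stand-in exposing ``.values`` like a ProfileMatrix."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)


class TestDistanceMatrix:
    def test_single_region(self):
        d = build_distance_matrix(["a"], {})
        assert d.matrix.shape == (1, 1) and d.matrix[0, 0] == 0.0

    def test_symmetric_entries(self):
        d = build_distance_matrix(["a", "b"], {("a", "b"): 0.3})
        assert d.matrix[0, 1] == d.matrix[1, 0] == 0.3

    def test_missing_pair_defaults_to_one(self):
        d = build_distance_matrix(["a", "b", "c"], {("a", "b"): 0.2})
        assert d.matrix[0, 2] == 1.0 and d.matrix[1, 2] == 1.0

    def test_conflicting_duplicates_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            build_distance_matrix(["a", "b"], {("a", "b"): 0.3, ("b", "a"): 0.4})


class TestTree:
    def test_two_leaves_merge_at_their_distance(self):
        d = build_distance_matrix(["a", "b"], {("a", "b"): 0.2})
        linkage = cluster_tree(d)
        assert linkage.shape == (1, 4)
        assert linkage[0, 2] == pytest.approx(0.2)

    def test_ultrametric_heights_reproduced_exactly(self):
        # 4-leaf ultrametric: (a,b) at 0.1, (c,d) at 0.2, root at 0.8
        ids = ["a", "b", "c", "d"]
        pv = {("a", "b"): 0.1, ("c", "d"): 0.2}
        for x in ("a", "b"):
            for y in ("c", "d"):
                pv[(x, y)] = 0.8
        linkage = cluster_tree(build_distance_matrix(ids, pv))
        assert sorted(np.round(linkage[:, 2], 12)) == [0.1, 0.2, 0.8]

    def test_partition_invariant_under_leaf_permutation(self, rng):
        n = 12
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        ids = list(range(n))
        pv = {(i, j): m[i, j] for i in range(n) for j in range(i + 1, n)}
        base, _ = cut_tree(cluster_tree(build_distance_matrix(ids, pv)), 0.5, n, 1)
        base_sets = {frozenset(c) for c in base}
        perm = list(rng.permutation(n))
        pv_p = {
            (perm[i], perm[j]): m[i, j] for i in range(n) for j in range(i + 1, n)
        }
        ids_p = [perm[i] for i in range(n)]
        clusters_p, _ = cut_tree(
            cluster_tree(build_distance_matrix(ids_p, pv_p)), 0.5, n, 1
        )
        perm_sets = {frozenset(ids_p[l] for l in c) for c in clusters_p}
        base_sets_named = {frozenset(perm[i] for i in c) for c in base_sets}
        assert perm_sets == base_sets_named


class TestCut:
    def _two_block_matrix(self):
        ids = list(range(6))
        pv = {}
        for i in range(6):
            for j in range(i + 1, 6):
                same = (i < 3) == (j < 3)
                pv[(i, j)] = 0.001 if same else 0.9
        return build_distance_matrix(ids, pv)

    def test_two_well_separated_blocks(self):
        d = self._two_block_matrix()
        clusters, unclustered = cut_tree(cluster_tree(d), 0.05, 6, 3)
        assert sorted(sorted(c) for c in clusters) == [[0, 1, 2], [3, 4, 5]]
        assert unclustered == []

    def test_all_distances_one_yields_no_clusters(self):
        d = build_distance_matrix(list(range(5)), {})
        clusters, unclustered = cut_tree(cluster_tree(d), 0.05, 5, 3)
        assert clusters == [] and unclustered == [0, 1, 2, 3, 4]

    def test_all_distances_zero_yields_one_cluster(self):
        ids = list(range(5))
        pv = {(i, j): 0.0 for i in range(5) for j in range(i + 1, 5)}
        clusters, _ = cut_tree(cluster_tree(build_distance_matrix(ids, pv)), 0.05, 5, 3)
        assert clusters == [[0, 1, 2, 3, 4]]

    def test_cut_is_strict_at_threshold(self):
        ids = ["a", "b"]
        d = build_distance_matrix(ids, {("a", "b"): 0.05})
        clusters, _ = cut_tree(cluster_tree(d), 0.05, 2, 1)
        assert len(clusters) == 2  # merge height == threshold does not join

    def test_raising_threshold_never_increases_cluster_count(self, rng):
        n = 15
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        pv = {(i, j): m[i, j] for i in range(n) for j in range(i + 1, n)}
        linkage = cluster_tree(build_distance_matrix(list(range(n)), pv))
        counts = [
            len(cut_tree(linkage, t, n, 1)[0])
            for t in (0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 0.95)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        n = 20
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        pv = {(i, j): m[i, j] for i in range(n) for j in range(i + 1, n)}
        clusters, unclustered = cut_tree(
            cluster_tree(build_distance_matrix(list(range(n)), pv)), 0.3, n, 3
        )
        seen = [l for c in clusters for l in c] + unclustered
        assert sorted(seen) == list(range(n))


class TestConsensus:
    def _aligned_cluster(self, profiles):
        ids = list(range(len(profiles)))
        aligns = {
            (i, j): align_pair(profiles[i], profiles[j], PARAMS)
            for i in ids
            for j in ids
            if i < j
        }
        pv = {k: 0.001 for k in aligns}
        dist = build_distance_matrix(ids, pv)
        pmap = {i: FakeProfile(profiles[i]) for i in ids}
        return ids, pmap, dist, aligns

    def test_identical_profiles_reproduce_common_profile(self, rng):
        base = rng.uniform(0.3, 0.9, size=(3, 8))
        ids, pmap, dist, aligns = self._aligned_cluster([base] * 4)
        medoid, (f0, f1), consensus = consensus_profile(ids, pmap, dist, aligns)
        np.testing.assert_allclose(consensus, base[:, f0:f1], atol=1e-12)
        assert (f0, f1) == (0, 8)

    def test_reversed_member_normalized_to_medoid_frame(self):
        base = np.linspace(0.1, 0.9, 9)[None, :].repeat(2, axis=0)
        base[1] = base[1, ::-1]  # asymmetric two-mark profile
        members = [base, base[:, ::-1]]
        ids, pmap, dist, aligns = self._aligned_cluster(members)
        medoid, (f0, f1), consensus = consensus_profile(ids, pmap, dist, aligns)
        np.testing.assert_allclose(consensus, pmap[medoid].values[:, f0:f1], atol=1e-12)

    def test_noisy_members_average_toward_medoid(self, rng):
        base = rng.uniform(0.3, 0.7, size=(4, 10))
        n = 9
        members = [base] + [
            np.clip(base + rng.normal(0, 0.05, size=base.shape), 0, 1)
            for _ in range(n - 1)
        ]
        ids, pmap, dist, aligns = self._aligned_cluster(members)
        medoid, (f0, f1), consensus = consensus_profile(ids, pmap, dist, aligns)
        med = pmap[medoid].values[:, f0:f1]
        assert np.max(np.abs(consensus - med)) < 2 * 0.05 / np.sqrt(n) + 0.05


class TestFootprintsAndNewick:
    def test_footprints_cover_aligned_intervals(self, rng):
        base = rng.uniform(0.5, 0.9, size=(3, 6))
        profiles = [
            np.hstack([np.zeros((3, k)), base, np.zeros((3, 4 - k))])
            for k in (0, 2, 4)
        ]
        ids = [0, 1, 2]
        aligns = {
            (i, j): align_pair(profiles[i], profiles[j], PARAMS)
            for i in ids
            for j in ids
            if i < j
        }
        fps = member_footprints(ids, aligns, {i: 10 for i in ids})
        for i, k in zip(ids, (0, 2, 4)):
            a, b = fps[i]
            assert a >= k - 1 and b <= k + 7  # tight around the planted block

    def test_newick_heights_sum_to_root(self):
        ids = ["a", "b", "c"]
        pv = {("a", "b"): 0.1, ("a", "c"): 0.6, ("b", "c"): 0.6}
        linkage = cluster_tree(build_distance_matrix(ids, pv))
        nwk = linkage_to_newick(linkage, ids)
        assert nwk.endswith(";") and "a" in nwk and "(" in nwk
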