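"""Column scoring, gap penalties, local DP alignment and island extraction."""

import numpy as np
import pytest

from chromalign import (
    AlignParams,
    align_pair,
    column_score,
    extract_islands,
    gap_penalty,
    local_align,
)

from bruteforce import brute_local_score
from conftest import noise_profile

PARAMS = AlignParams(gamma=2.0, beta=0.3, delta=0.5)


class TestColumnScore:
    def test_identical_nonzero_columns_score_positive_weight(self):
        u = np.array([0.5, 0.5, 0.2])
        s = column_score(u, u, PARAMS)
        nbar = np.linalg.norm(u) / np.sqrt(3)
        assert s == pytest.approx(nbar / (nbar + 0.3), rel=1e-12)

    def test_orthogonal_unit_columns_hand_value(self):
        # theta = pi/2, amplified to pi -> raw -1; nbar = 1/sqrt(2)
        s = column_score([1.0, 0.0], [0.0, 1.0], PARAMS)
        nbar = 1.0 / np.sqrt(2.0)
        assert s == pytest.approx(-(nbar / (nbar + 0.3)), rel=1e-9)
        assert s == pytest.approx(-0.702117, abs=1e-6)

    def test_zero_column_scores_zero(self):
        assert column_score([0.0, 0.0], [0.3, 0.9], PARAMS) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            column_score([1.0, 0.0], [1.0, 0.0, 0.0], PARAMS)

    def test_score_bounded_by_one(self, rng):
        for _ in range(200):
            u = rng.random(4)
            v = rng.random(4)
            assert -1.0 <= column_score(u, v, PARAMS) <= 1.0

    def test_raising_gamma_never_increases_small_angle_scores(self, rng):
        for _ in range(50):
            u = rng.random(3) + 0.5
            v = u + rng.normal(0, 0.05, size=3)  # small angle
            v = np.clip(v, 0, 1)
            s2 = column_score(u, v, AlignParams(gamma=2.0))
            s3 = column_score(u, v, AlignParams(gamma=3.0))
            assert s3 <= s2 + 1e-12

    def test_raising_beta_never_increases_score(self, rng):
        for _ in range(50):
            u, v = rng.random(3), rng.random(3)
            s_lo = column_score(u, v, AlignParams(beta=0.3))
            s_hi = column_score(u, v, AlignParams(beta=0.6))
            if s_lo >= 0:
                assert s_hi <= s_lo + 1e-12
            else:  # weight shrinks the magnitude of negative scores too
                assert s_hi >= s_lo - 1e-12


class TestGapPenalty:
    def test_zero_vector_free(self):
        assert gap_penalty([0.0, 0.0, 0.0], PARAMS) == 0.0

    def test_unit_normalized_norm_costs_delta(self):
        u = np.ones(4)  # ||u|| = 2 = sqrt(M)
        assert gap_penalty(u, PARAMS) == pytest.approx(0.5, rel=1e-12)

    def test_homogeneous_in_scale(self, rng):
        u = rng.random(5) * 0.5
        assert gap_penalty(2 * u, PARAMS) == pytest.approx(
            2 * gap_penalty(u, PARAMS), rel=1e-12
        )


class TestLocalAlign:
    def test_single_identical_column(self):
        u = np.array([[0.8], [0.6]])
        res = local_align(u, u, PARAMS)
        assert res.score == pytest.approx(column_score(u[:, 0], u[:, 0], PARAMS))
        assert len(res.path) == 1 and res.path[0].move == "diag"
        assert res.x_interval == (0, 1) and res.y_interval == (0, 1)

    def test_all_zero_matrix_empty_alignment(self):
        z = np.zeros((3, 5))
        res = local_align(z, z, PARAMS)
        assert res.score == 0.0 and res.path == ()

    def test_empty_matrix(self):
        res = local_align(np.zeros((3, 0)), np.zeros((3, 4)), PARAMS)
        assert res.score == 0.0 and res.path == ()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            m = int(rng.integers(1, 5))
            l1 = int(rng.integers(1, 7))
            l2 = int(rng.integers(1, 7))
            X = rng.random((m, l1))
            Y = rng.random((m, l2))
            res = local_align(X, Y, PARAMS)
            assert res.score == pytest.approx(
                brute_local_score(X, Y, PARAMS), abs=1e-10
            )

    def test_path_projections_match_intervals(self, rng):
        X = noise_profile(rng)
        Y = noise_profile(rng)
        res = local_align(X, Y, PARAMS)
        xs = [s.x_col for s in res.path if s.x_col is not None]
        ys = [s.y_col for s in res.path if s.y_col is not None]
        assert res.x_interval == (min(xs), max(xs) + 1)
        assert res.y_interval == (min(ys), max(ys) + 1)

    def test_padding_with_zero_columns_leaves_score_unchanged(self, rng):
        X = noise_profile(rng)
        Y = noise_profile(rng)
        base = local_align(X, Y, PARAMS).score
        Xp = np.hstack([np.zeros((6, 3)), X, np.zeros((6, 2))])
        Yp = np.hstack([Y, np.zeros((6, 4))])
        assert local_align(Xp, Yp, PARAMS).score == pytest.approx(base, rel=1e-9)


class TestAlignPair:
    def test_mirror_symmetry(self, rng):
        X = noise_profile(rng)
        fwd = align_pair(X, X, PARAMS)
        rev = align_pair(X, X[:, ::-1], PARAMS)
        assert rev.score == pytest.approx(fwd.score, rel=1e-9)

    def test_score_symmetric_in_arguments(self, rng):
        for _ in range(20):
            X = noise_profile(rng)
            Y = noise_profile(rng)
            assert align_pair(X, Y, PARAMS).score == pytest.approx(
                align_pair(Y, X, PARAMS).score, rel=1e-9
            )

    def test_self_alignment_dominates_random_pairs(self, rng):
        X = noise_profile(rng)
        self_score = align_pair(X, X, PARAMS).score
        for _ in range(100):
            Y = noise_profile(rng)
            assert align_pair(X, Y, PARAMS).score <= self_score + 1e-9

    def test_reversed_motif_found_in_opposite_orientation(self, rng):
        # asymmetric motif planted forward in X, reversed in Y
        motif = np.zeros((4, 6))
        motif[0] = [0.9, 0.8, 0.6, 0.3, 0.1, 0.05]
        motif[1] = [0.05, 0.1, 0.4, 0.7, 0.9, 0.95]
        X = np.full((4, 14), 0.05)
        X[:, 4:10] = motif
        Y = np.full((4, 14), 0.05)
        Y[:, 6:12] = motif[:, ::-1]
        res = align_pair(X, Y, PARAMS)
        assert res.orientation == "opposite"
        # footprint covers the planted motif in both forward frames
        xa, xb = res.x_interval
        ya, yb = res.y_interval
        x_overlap = max(0, min(xb, 10) - max(xa, 4)) / 6
        y_overlap = max(0, min(yb, 12) - max(ya, 6)) / 6
        assert x_overlap >= 0.9 and y_overlap >= 0.9

    def test_raising_delta_never_increases_score(self, rng):
        for _ in range(20):
            X, Y = noise_profile(rng), noise_profile(rng)
            lo = align_pair(X, Y, AlignParams(delta=0.3)).score
            hi = align_pair(X, Y, AlignParams(delta=0.6)).score
            assert hi <= lo + 1e-12


class TestIslands:
    def test_no_islands_for_zero_matrices(self):
        z = np.zeros((3, 4))
        assert extract_islands(z, z, PARAMS) == []

    def test_single_shared_motif_single_island(self):
        X = np.full((2, 8), 0.02)
        X[:, 2:5] = 0.9
        islands = extract_islands(X, X, PARAMS, threshold=2.0)
        # one dominant island from the motif self-match (threshold excludes
        # the short off-diagonal matches between motif columns)
        assert len(islands) == 1
        assert islands[0].peak_score == pytest.approx(
            local_align(X, X, PARAMS).score
        )

    def test_free_spacer_connects_motifs_into_one_island(self):
        # empty (zero-norm) bins score 0 and cost no gap, so two shared
        # motifs joined by empty bins form ONE island spanning both --
        # this is what lets signatures span conserved and variant segments
        X = np.zeros((2, 8))
        X[0, 0:3] = 0.9
        X[1, 5:8] = 0.9
        islands = extract_islands(X, X, PARAMS, threshold=1.5)
        assert len(islands) == 1
        single = local_align(X[:, 0:3], X[:, 0:3], PARAMS).score
        assert islands[0].peak_score == pytest.approx(2 * single, rel=1e-9)

    def test_two_motifs_split_by_mismatched_barrier_give_two_islands(self):
        # a barrier of mismatching (orthogonal-mark) columns costs more to
        # cross than either motif is worth, so traceback ancestry splits
        X = np.zeros((4, 13))
        Y = np.zeros((4, 13))
        X[0, 0:3] = Y[0, 0:3] = 0.9      # shared motif A (mark 0)
        X[2, 3:8] = 0.9                  # barrier: mark 2 in X ...
        Y[3, 3:8] = 0.9                  # ... vs mark 3 in Y
        X[1, 8:11] = Y[1, 8:11] = 0.9    # shared motif B (mark 1)
        islands = extract_islands(X, Y, PARAMS, threshold=1.5)
        assert len(islands) == 2

    def test_island_peak_equals_best_local_score(self, rng):
        X, Y = noise_profile(rng), noise_profile(rng)
        islands = extract_islands(X, Y, PARAMS)
        if islands:
            best = max(i.peak_score for i in islands)
            assert best == pytest.approx(local_align(X, Y, PARAMS).score)
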