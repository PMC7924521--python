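import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import intervalscore as ics
from intervalscore.binning import MIN_POINTS_PER_INTERVAL


class TestThresholds:
    def test_equal_count_quantile_split(self, rng):
        x = rng.uniform(size=100)
        vb = ics.compute_thresholds(x, "continuous", 4)
        assert vb.n_intervals == 4 and len(vb.thresholds) == 3
        idx = vb.interval_index(x)
        assert np.bincount(idx).tolist() == [25, 25, 25, 25]

    def test_occupancy_rule_reduces_interval_count(self, rng):
        # 12 points cannot give 4 intervals of >= 5 points; 2 intervals can
        x = rng.uniform(size=12)
        vb = ics.compute_thresholds(x, "continuous", 4)
        assert vb.n_intervals == 2
        assert np.bincount(vb.interval_index(x)).min() >= MIN_POINTS_PER_INTERVAL

    def test_constant_variable_single_interval(self):
        with pytest.warns(UserWarning):
            vb = ics.compute_thresholds(np.ones(30), "continuous", 5)
        assert vb.n_intervals == 1 and len(vb.thresholds) == 0

    def test_ordinal_thresholds_are_integers(self, rng):
        x = rng.integers(0, 6, size=200).astype(float)
        vb = ics.compute_thresholds(x, "ordinal", 5)
        assert np.allclose(vb.thresholds, np.round(vb.thresholds))
        assert len(np.unique(vb.thresholds)) == len(vb.thresholds)

    def test_heavy_ties_collapse_thresholds(self):
        x = np.concatenate([np.zeros(50), np.ones(50)])
        vb = ics.compute_thresholds(x, "continuous", 5)
        assert vb.n_intervals <= 2
        assert len(np.unique(vb.thresholds)) == len(vb.thresholds)

    def test_binary_and_categorical_counts(self):
        vb = ics.compute_thresholds(np.array([0.0, 1, 0, 1, 1]), "binary", 10)
        assert vb.n_intervals == 2 and vb.levels.tolist() == [0.0, 1.0]
        vc = ics.compute_thresholds(np.array([3.0, 1, 3, 2, 1]), "categorical", 10)
        # first-appearance order
        assert vc.levels.tolist() == [3.0, 1.0, 2.0] and vc.n_intervals == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ics.compute_thresholds(np.array([]), "continuous", 3)


class TestEncodings:
    def test_binary_one_hot(self):
        X = np.array([[1.0], [0.0]])
        scheme = ics.build_scheme(X, ["binary"], [(0,)], 10)
        Z = ics.lp_encode(X, scheme).Z
        assert Z.tolist() == [[0, 1], [1, 0]]

    def test_first_interval_indicator(self, rng):
        x = np.sort(rng.uniform(size=40))
        scheme = ics.build_scheme(x[:, None], ["continuous"], [(0,)], 4)
        lo = scheme.variables[0].thresholds[0]
        Z = ics.lp_encode(np.array([[lo - 0.01]]), scheme).Z
        assert Z.tolist() == [[1, 0, 0, 0]]

    def test_lp_rows_one_hot_per_effect(self, small_expansion):
        _, _, scheme, Z_lp, *_ = small_expansion
        for blk in Z_lp.block_slices:
            assert np.all(Z_lp.Z[:, blk].sum(axis=1) == 1.0)
        # row sums equal the number of effects
        assert np.all(Z_lp.Z.sum(axis=1) == len(scheme.effects))

    def test_en_blocks_are_prefixes_of_ones(self, small_expansion):
        _, _, scheme, _, Z_en, *_ = small_expansion
        for blk in Z_en.block_slices:
            B = Z_en.Z[:, blk]
            assert np.all(B[:, 0] == 1.0)
            assert np.all(np.diff(B, axis=1) <= 0)  # monotone non-increasing

    def test_en_all_ones_in_top_interval(self, rng):
        x = rng.uniform(size=60)
        scheme = ics.build_scheme(x[:, None], ["continuous"], [(0,)], 4)
        top = scheme.variables[0].thresholds[-1] + 1.0
        Z = ics.en_encode(np.array([[top]]), scheme).Z
        assert Z.tolist() == [[1, 1, 1, 1]]

    def test_lp_is_first_difference_of_en(self, small_expansion):
        X, _, scheme, Z_lp, Z_en, *_ = small_expansion
        for blk in Z_lp.block_slices:
            lp = Z_lp.Z[:, blk]
            en = Z_en.Z[:, blk]
            en_ext = np.hstack([en, np.zeros((en.shape[0], 1))])
            assert np.array_equal(lp, en_ext[:, :-1] - en_ext[:, 1:])

    def test_en_rejects_interactions(self, rng):
        X = rng.uniform(size=(50, 2))
        scheme = ics.build_scheme(X, ["continuous"] * 2, [(0, 1)], 3)
        with pytest.raises(ValueError, match="main effects"):
            ics.en_encode(X, scheme)

    def test_interaction_single_cell_fires(self, rng):
        X = rng.uniform(size=(100, 2))
        scheme = ics.build_scheme(X, ["continuous"] * 2, [(0,), (1,), (0, 1)], 4)
        n1 = scheme.variables[0].n_intervals
        n2 = scheme.variables[1].n_intervals
        Z = ics.lp_encode(X, scheme)
        blk = Z.Z[:, Z.block_slices[2]]
        assert blk.shape[1] == n1 * n2
        assert np.all(blk.sum(axis=1) == 1.0)
        # vectorization: cell (k, l) maps to column k + l * n1
        i1 = scheme.variables[0].interval_index(X[:, 0])
        i2 = scheme.variables[1].interval_index(X[:, 1])
        assert np.array_equal(np.argmax(blk, axis=1), i1 + i2 * n1)

    def test_unseen_categorical_level_zero_block(self):
        X = np.array([[1.0], [2.0], [1.0]])
        scheme = ics.build_scheme(X, ["categorical"], [(0,)], 10)
        with pytest.warns(UserWarning, match="unseen"):
            Z = ics.lp_encode(np.array([[9.0]]), scheme).Z
        assert Z.tolist() == [[0, 0]]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(2, 30))
    def test_categorical_encoding_permutation_equivariant(self, n):
        rng = np.random.default_rng(n)
        x = rng.integers(0, 4, size=n).astype(float)
        scheme = ics.build_scheme(x[:, None], ["categorical"], [(0,)], 10)
        Z = ics.lp_encode(x[:, None], scheme).Z
        # relabel levels by an order-scrambling injection; with the same
        # catalogued order the encoding is identical
        relabel = {0.0: 7.0, 1.0: -1.0, 2.0: 4.0, 3.0: 0.5}
        x2 = np.array([relabel[v] for v in x])
        scheme2 = ics.build_scheme(x2[:, None], ["categorical"], [(0,)], 10)
        Z2 = ics.lp_encode(x2[:, None], scheme2).Z
        assert np.array_equal(Z, Z2)


class TestDifferenceStructure:
    def test_main_effect_row_count(self, rng):
        x = rng.uniform(size=100)
        scheme = ics.build_scheme(x[:, None], ["continuous"], [(0,)], 4)
        diff = ics.build_difference_structure(scheme)
        assert diff.D.shape == (3, 4)

    def test_each_row_one_plus_one_minus_within_block(self, small_expansion):
        *_, diff_lp, _ = small_expansion
        for row in diff_lp.D:
            assert sorted(row[row != 0].tolist()) == [-1.0, 1.0]

    def test_interaction_grid_row_count(self):
        # 3 x 4 grid: 3 * 3 horizontal + 4 * 2 vertical = 17 rows,
        # counted independently by enumerating adjacent cell pairs
        v1 = ics.VariableBinning("continuous", np.array([1.0, 2.0]), None, 3)
        v2 = ics.VariableBinning("continuous", np.array([1.0, 2.0, 3.0]), None, 4)
        scheme = ics.BinningScheme({0: v1, 1: v2}, [(0, 1)])
        diff = ics.build_difference_structure(scheme)
        n1, n2 = 3, 4
        expected = sum(1 for k in range(n1) for l in range(n2 - 1)) + sum(
            1 for k in range(n1 - 1) for l in range(n2)
        )
        assert expected == 17
        assert diff.D.shape[0] == expected
        # every row couples two grid-adjacent cells (vec index k + l * n1)
        for row in diff.D:
            i, j = np.nonzero(row)[0]
            k1, l1 = i % n1, i // n1
            k2, l2 = j % n1, j // n1
            assert abs(k1 - k2) + abs(l1 - l2) == 1

    def test_reconstruction_inverts_differences(self, rng):
        x = rng.uniform(size=60)
        scheme = ics.build_scheme(x[:, None], ["continuous"], [(0,)], 3)
        diff = ics.build_difference_structure(scheme, "en")
        assert np.array_equal(diff.R, np.tril(np.ones((3, 3))))
        assert np.allclose(diff.R @ diff.D_full, np.eye(3))

    def test_interval_scores_agree_between_encodings(self, small_expansion, rng):
        # w_tilde = R w_hat implies Z_lp w_tilde = Z_en w_hat for all rows
        _, _, _, Z_lp, Z_en, _, diff_en = small_expansion
        for _ in range(5):
            w_hat = rng.normal(size=Z_en.Z.shape[1])
            w_tilde = diff_en.R @ w_hat
            assert np.allclose(Z_lp.Z @ w_tilde, Z_en.Z @ w_hat, atol=1e-12)

    def test_single_interval_effect_contributes_no_rows(self):
        X = np.column_stack([np.ones(30), np.linspace(0, 1, 30)])
        with pytest.warns(UserWarning):
            scheme = ics.build_scheme(X, ["continuous"] * 2, [(0,), (1,)], 3)
        diff = ics.build_difference_structure(scheme)
        assert diff.D.shape[0] == scheme.variables[1].n_intervals - 1
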