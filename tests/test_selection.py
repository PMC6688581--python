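"""Metrics, LOOCV protocol and greedy forward selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rnaffinity.selection import (ConstantInputError, greedy_select, loocv,
                                  mae, pearson_r, r2, rank_features)

vectors = st.lists(st.floats(-100, 100), min_size=3, max_size=30)


def constant_trainer(X, y):
    mean = float(np.mean(y))
    return lambda Q: np.full(len(np.atleast_2d(Q)), mean)


class TestPearson:
    def test_hand_evaluated_example(self):
        # sum((x-x̄)(y-ȳ)) = 3; sum(x-x̄)² = 2; sum(y-ȳ)² = 42/9
        assert pearson_r([1, 2, 3], [1, 2, 4]) == \
            pytest.approx(3 / np.sqrt(2 * 42 / 9), abs=1e-12)
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9820,
                                                                abs=1e-4)

    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(20)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_constant_vector_is_error(self):
        with pytest.raises(ConstantInputError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_matches_scipy(self, rng):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        assert pearson_r(a, b) == pytest.approx(stats.pearsonr(a, b)[0],
                                                abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    def test_invariant_under_positive_affine_maps(self, scale, shift):
        a = np.arange(10.0)
        b = np.array([3, 1, 4, 1, 5, 9, 2, 6, 5, 3.0])
        assert pearson_r(scale * a + shift, b) == \
            pytest.approx(pearson_r(a, b), abs=1e-9)
        assert pearson_r(-a, b) == pytest.approx(-pearson_r(a, b), abs=1e-12)


class TestMaeR2:
    def test_perfect_prediction(self):
        y = [1.0, 2.0, 3.0]
        assert mae(y, y) == 0.0
        assert r2(y, y) == 1.0

    def test_forced_arithmetic(self):
        assert mae([1, 2], [2, 4]) == pytest.approx(1.5)

    def test_shift_invariance_of_mae(self, rng):
        p = rng.standard_normal(10)
        a = rng.standard_normal(10)
        assert mae(p + 3.0, a + 3.0) == pytest.approx(mae(p, a))

    def test_mean_predictor_has_zero_r2(self):
        actual = np.array([1.0, 2.0, 3.0, 6.0])
        assert r2(np.full(4, actual.mean()), actual) == pytest.approx(0.0)

    def test_r2_matches_two_pass_oracle(self, rng):
        pred = rng.standard_normal(25)
        actual = rng.standard_normal(25)
        ss_res = sum((a - p) ** 2 for p, a in zip(pred, actual))
        mean = sum(actual) / len(actual)
        ss_tot = sum((a - mean) ** 2 for a in actual)
        assert r2(pred, actual) == pytest.approx(1 - ss_res / ss_tot,
                                                 abs=1e-12)

    def test_constant_actual_is_error(self):
        with pytest.raises(ConstantInputError):
            r2([1.0, 2.0], [3.0, 3.0])

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])


class TestLoocv:
    def test_constant_trainer_fold_means(self):
        X = np.zeros((3, 1))
        y = np.array([0.0, 1.0, 2.0])
        preds = loocv(X, y, constant_trainer)
        assert preds == pytest.approx([1.5, 1.0, 0.5])

    def test_n_outputs_for_n_inputs(self, rng):
        X = rng.standard_normal((7, 2))
        y = rng.standard_normal(7)
        assert len(loocv(X, y, constant_trainer)) == 7

    def test_no_leakage_with_memorizing_trainer(self):
        """A trainer that memorizes its training targets can never return
        the held-out value on a distinct-target fixture."""
        X = np.arange(5.0).reshape(-1, 1)
        y = np.array([10.0, 20.0, 30.0, 40.0, 50.0])

        def memorizer(Xtr, ytr):
            lookup = {float(x): t for x, t in zip(Xtr[:, 0], ytr)}
            return lambda Q: np.array(
                [lookup.get(float(q), -999.0)
                 for q in np.atleast_2d(Q)[:, 0]])

        preds = loocv(X, y, memorizer)
        assert np.all(preds == -999.0)

    def test_order_invariance(self, rng):
        X = rng.standard_normal((8, 2))
        y = rng.standard_normal(8)
        perm = rng.permutation(8)
        direct = loocv(X, y, constant_trainer)
        permuted = loocv(X[perm], y[perm], constant_trainer)
        assert direct[perm] == pytest.approx(permuted)

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError):
            loocv(np.zeros((2, 1)), np.zeros(2), constant_trainer)

    def test_trainer_failure_names_fold(self):
        def flaky(Xtr, ytr):
            if len(ytr) != 4:
                raise RuntimeError("nope")
            raise ValueError("bad fold")

        with pytest.raises(RuntimeError, match="fold 0"):
            loocv(np.zeros((5, 1)), np.arange(5.0), flaky)


def _nearest_neighbor_trainer(Xtr, ytr):
    Xtr = np.atleast_2d(Xtr)

    def predict(Q):
        Q = np.atleast_2d(Q)
        d = np.linalg.norm(Q[:, None, :] - Xtr[None, :, :], axis=2)
        return ytr[np.argmin(d, axis=1)]

    return predict


class TestRanking:
    def test_exact_copy_of_target_ranked_first(self, rng):
        y = rng.standard_normal(30)
        X = np.column_stack([rng.standard_normal(30), y,
                             rng.standard_normal(30)])
        ranked = rank_features(X, y, _nearest_neighbor_trainer)
        assert ranked[0][0] == 1

    def test_fewer_than_top_k_all_kept(self, rng):
        X = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        assert len(rank_features(X, y, constant_trainer)) == 4

    def test_top_k_cap(self, rng):
        X = rng.standard_normal((15, 14))
        y = rng.standard_normal(15)
        assert len(rank_features(X, y, _nearest_neighbor_trainer)) == 10

    def test_deterministic_under_fixed_data(self, rng):
        X = rng.standard_normal((15, 6))
        y = rng.standard_normal(15)
        assert rank_features(X, y, _nearest_neighbor_trainer) == \
            rank_features(X, y, _nearest_neighbor_trainer)

    def test_undefined_scores_ranked_last(self, rng):
        X = np.column_stack([rng.standard_normal(10),
                             rng.standard_normal(10)])
        y = rng.standard_normal(10)

        def zero_trainer(Xtr, ytr):
            return lambda Q: np.zeros(len(np.atleast_2d(Q)))

        ranked = rank_features(X, y, zero_trainer)  # constant predictions
        assert all(score == float("-inf") for _, score in ranked)


class TestGreedySelect:
    def test_perfect_feature_alone_suffices(self, rng):
        y = rng.standard_normal(30)
        X = np.column_stack([y, rng.standard_normal(30)])
        ranked = rank_features(X, y, _nearest_neighbor_trainer)
        sel = greedy_select(X, y, ranked, _nearest_neighbor_trainer)
        assert sel.selected == [0]

    def test_all_noise_pool_selects_single_feature(self):
        rng = np.random.default_rng(2024)
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        ranked = rank_features(X, y, _nearest_neighbor_trainer)
        sel = greedy_select(X, y, ranked, _nearest_neighbor_trainer)
        assert len(sel.selected) <= 2  # stops almost immediately

    def test_selected_bounded_by_pool(self, rng):
        X = rng.standard_normal((20, 15))
        y = X[:, 0] + rng.standard_normal(20)
        ranked = rank_features(X, y, _nearest_neighbor_trainer)
        sel = greedy_select(X, y, ranked, _nearest_neighbor_trainer)
        assert len(sel.selected) <= 10
        assert len(sel.trajectory) == len(sel.selected)

    def test_empty_pool_is_error(self, rng):
        with pytest.raises(ValueError):
            greedy_select(rng.standard_normal((5, 1)),
                          rng.standard_normal(5), [],
                          _nearest_neighbor_trainer)
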