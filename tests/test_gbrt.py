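"""The boosted-tree learner against independent oracles.

Two oracles keep the fast implementation honest: a naive double-loop greedy
tree builder (exhaustive enumeration of every split candidate at every node)
and scikit-learn's gradient boosting configured identically.
"""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from sklearn.ensemble import GradientBoostingRegressor

from rnaffinity import (GBRTConfig, GBRTModel, fit_gbrt, fit_tree,
                        line_search_weight, predict, pseudo_residuals)
from rnaffinity.fixtures import make_regression_dataset
from rnaffinity.selection import loocv, pearson_r


# --- naive oracle: brute-force split enumeration at every node -------------

def _oracle_best_split(X, y, min_leaf):
    n, p = X.shape
    best = None
    for f in range(p):
        values = sorted(set(X[:, f]))
        for a, b in zip(values[:-1], values[1:]):
            t = (a + b) / 2.0
            left = y[X[:, f] <= t]
            right = y[X[:, f] > t]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            sse = (np.sum((left - left.mean()) ** 2)
                   + np.sum((right - right.mean()) ** 2))
            if best is None or sse < best[2]:
                best = (f, t, sse)
    return best


def _oracle_tree_predict(X, y, Xq, max_depth, min_leaf):
    """Recursive greedy tree via the brute-force splitter."""
    if (max_depth == 0 or len(y) < 2 * min_leaf
            or np.all(y == y[0])):
        return np.full(len(Xq), y.mean())
    split = _oracle_best_split(X, y, min_leaf)
    if split is None:
        return np.full(len(Xq), y.mean())
    f, t, _ = split
    out = np.empty(len(Xq))
    mask, qmask = X[:, f] <= t, Xq[:, f] <= t
    out[qmask] = _oracle_tree_predict(X[mask], y[mask], Xq[qmask],
                                      max_depth - 1, min_leaf)
    out[~qmask] = _oracle_tree_predict(X[~mask], y[~mask], Xq[~qmask],
                                       max_depth - 1, min_leaf)
    return out


class TestPseudoResiduals:
    def test_residual_identity(self):
        out = pseudo_residuals(np.array([1.0, 2.0]), np.array([0.0, 0.0]))
        assert out.tolist() == [1.0, 2.0]

    def test_zero_at_optimum(self):
        y = np.array([3.0, -1.0, 2.0])
        assert pseudo_residuals(y, y).tolist() == [0.0, 0.0, 0.0]

    def test_matches_finite_difference_gradient(self, rng):
        y = rng.standard_normal(20)
        f = rng.standard_normal(20)
        eps = 1e-6

        def loss(fi, yi):
            return 0.5 * (yi - fi) ** 2

        grad = np.array([(loss(fi + eps, yi) - loss(fi - eps, yi)) / (2 * eps)
                         for fi, yi in zip(f, y)])
        assert pseudo_residuals(y, f) == pytest.approx(-grad, abs=1e-6)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            pseudo_residuals(np.zeros(3), np.zeros(2))


class TestFitTree:
    def test_step_function_split_at_midpoint(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        tree = fit_tree(X, y, GBRTConfig(max_depth=1))
        assert tree.n_leaves == 2
        root = tree.root
        assert root.threshold == pytest.approx(1.5)
        assert root.left.value == pytest.approx(0.0)
        assert root.right.value == pytest.approx(1.0)

    def test_constant_targets_single_leaf(self):
        X = np.arange(6.0).reshape(-1, 1)
        tree = fit_tree(X, np.full(6, 3.5), GBRTConfig(max_depth=3))
        assert tree.n_leaves == 1
        assert tree.predict(X) == pytest.approx(np.full(6, 3.5))

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError):
            fit_tree(np.array([[1.0]]), np.array([1.0]),
                     GBRTConfig(min_samples_leaf=1))

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_naive_enumeration_oracle(self, trial):
        """Every split equals brute-force enumeration: training SSE of the
        fast tree and the naive recursive oracle agree exactly."""
        rng = np.random.default_rng(9000 + trial)
        n = int(rng.integers(4, 13))
        p = int(rng.integers(1, 4))
        depth = int(rng.integers(1, 3))
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        tree = fit_tree(X, y, GBRTConfig(max_depth=depth))
        fast_sse = float(np.sum((y - tree.predict(X)) ** 2))
        oracle_sse = float(np.sum(
            (y - _oracle_tree_predict(X, y, X, depth, 1)) ** 2))
        assert fast_sse == pytest.approx(oracle_sse, abs=1e-9)

    def test_min_samples_leaf_respected(self, rng):
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        tree = fit_tree(X, y, GBRTConfig(max_depth=4, min_samples_leaf=5))
        leaves = tree.predict(X)
        _, counts = np.unique(leaves, return_counts=True)
        assert counts.min() >= 5


class TestLineSearch:
    def test_unit_weight_when_tree_equals_residuals(self, rng):
        y = rng.standard_normal(15)
        f = rng.standard_normal(15)
        assert line_search_weight(y, f, y - f) == pytest.approx(1.0)

    def test_zero_predictions_give_zero_weight(self):
        assert line_search_weight(np.ones(4), np.zeros(4), np.zeros(4)) == 0.0

    def test_matches_numeric_minimizer(self, rng):
        y = rng.standard_normal(30)
        f = rng.standard_normal(30)
        h = rng.standard_normal(30)
        beta = line_search_weight(y, f, h)
        res = minimize_scalar(
            lambda b: 0.5 * np.sum((y - (f + b * h)) ** 2),
            bounds=(-100, 100), method="bounded",
            options={"xatol": 1e-10})
        assert beta == pytest.approx(res.x, abs=1e-6)


class TestFitGbrt:
    def test_zero_trees_predicts_mean(self, rng):
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        model = fit_gbrt(X, y, GBRTConfig(n_trees=0))
        assert model.predict(X) == pytest.approx(np.full(10, y.mean()))

    def test_hand_executed_single_iteration(self):
        # beta0 = 0.5; tree splits at 0.5 with leaves -0.5 / +0.5;
        # beta = 1, nu = 1 -> exact fit
        X = np.array([[0.0], [1.0]])
        y = np.array([0.0, 1.0])
        model = fit_gbrt(X, y, GBRTConfig(n_trees=1, shrinkage=1.0,
                                          max_depth=1))
        assert model.beta0 == pytest.approx(0.5)
        assert model.weights == [pytest.approx(1.0)]
        assert model.predict(X) == pytest.approx([0.0, 1.0])

    def test_training_loss_non_increasing(self, rng):
        X = rng.standard_normal((60, 3))
        y = rng.standard_normal(60)
        model = fit_gbrt(X, y, GBRTConfig(n_trees=50, shrinkage=0.3,
                                          max_depth=2))
        losses = np.array(model.train_loss_path)
        assert np.all(np.diff(losses) <= 1e-9)

    def test_matches_sklearn_reference_per_iteration(self, rng):
        X = rng.standard_normal((200, 5))
        y = 2 * X[:, 0] + np.sin(3 * X[:, 1]) + 0.3 * rng.standard_normal(200)
        cfg = GBRTConfig(n_trees=5, shrinkage=0.1, max_depth=3)
        mine = fit_gbrt(X, y, cfg)
        ref = GradientBoostingRegressor(
            loss="squared_error", learning_rate=0.1, n_estimators=5,
            max_depth=3, min_samples_leaf=1, random_state=0)
        ref.fit(X, y)
        staged = list(mine.staged_predict(X))[1:]
        for ours, theirs in zip(staged, ref.staged_predict(X)):
            rel = np.max(np.abs(ours - theirs) / (np.abs(theirs) + 1e-12))
            assert rel < 1e-6

    def test_shrinkage_limit_smoke(self, rng):
        """Shrinking nu with the boosting horizon M*nu held fixed converges:
        on a linear target the small-nu runs land within 5% (of the initial
        loss) of the aggressive nu=1 run, and within a much tighter band of
        each other."""
        X = rng.standard_normal((80, 1))
        y = 2.0 * X[:, 0]
        initial = 0.5 * np.sum((y - y.mean()) ** 2)
        losses = {}
        for n_trees, nu in [(5, 1.0), (50, 0.1), (100, 0.05)]:
            model = fit_gbrt(X, y, GBRTConfig(n_trees=n_trees, shrinkage=nu,
                                              max_depth=2))
            losses[nu] = model.train_loss_path[-1]
        assert abs(losses[0.05] - losses[1.0]) <= 0.05 * initial
        assert abs(losses[0.05] - losses[0.1]) <= 0.005 * initial

    def test_missing_values_rejected(self):
        X = np.array([[0.0], [np.nan]])
        with pytest.raises(ValueError, match="missing"):
            fit_gbrt(X, np.array([0.0, 1.0]), GBRTConfig(n_trees=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GBRTConfig(n_trees=-1)
        with pytest.raises(ValueError):
            GBRTConfig(shrinkage=0.0)
        with pytest.raises(ValueError):
            GBRTConfig(shrinkage=1.5)


class TestPredictAndSerialization:
    def test_empty_model_predicts_constant(self, rng):
        model = fit_gbrt(rng.standard_normal((5, 2)), np.full(5, 2.0),
                         GBRTConfig(n_trees=0))
        assert predict(model, np.zeros(2)) == pytest.approx(2.0)

    def test_one_tree_arithmetic(self):
        # nu = 0.5, beta = 1, leaf value 2 at x -> beta0 + 1
        X = np.array([[0.0], [1.0]])
        y = np.array([1.0, 5.0])  # beta0 = 3, residuals [-2, 2]
        model = fit_gbrt(X, y, GBRTConfig(n_trees=1, shrinkage=0.5,
                                          max_depth=1))
        assert predict(model, np.array([1.0])) == pytest.approx(3.0 + 1.0)

    def test_batch_equals_per_sample(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        model = fit_gbrt(X, y, GBRTConfig(n_trees=10, max_depth=2))
        batch = model.predict(X)
        singles = [predict(model, x) for x in X]
        assert batch == pytest.approx(singles)

    def test_arity_mismatch_is_error(self, rng):
        model = fit_gbrt(rng.standard_normal((6, 2)),
                         rng.standard_normal(6), GBRTConfig(n_trees=1))
        with pytest.raises(ValueError):
            model.predict(np.zeros((1, 3)))

    def test_fixed_input_byte_identical_model(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        cfg = GBRTConfig(n_trees=15, max_depth=3, seed=7)
        assert fit_gbrt(X, y, cfg).to_json() == fit_gbrt(X, y, cfg).to_json()

    def test_json_round_trip_preserves_predictions(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        model = fit_gbrt(X, y, GBRTConfig(n_trees=12, max_depth=3))
        clone = GBRTModel.from_json(model.to_json())
        assert clone.predict(X).tolist() == model.predict(X).tolist()

    def test_split_gain_importance_finds_signal(self, rng):
        X = rng.standard_normal((100, 3))
        y = 3.0 * X[:, 1] + 0.1 * rng.standard_normal(100)
        model = fit_gbrt(X, y, GBRTConfig(n_trees=20, max_depth=2),
                         feature_names=["a", "b", "c"])
        imp = model.feature_importances()
        assert imp["b"] > imp["a"] and imp["b"] > imp["c"]


def test_noiseless_piecewise_target_recovered_in_loocv(small_gbrt):
    """On a noiseless piecewise-constant target the learner generalizes
    almost perfectly under LOOCV."""
    X, y, _ = make_regression_dataset(
        200, 3, {"kind": "piecewise", "informative": [0]}, noise_sd=0.0,
        seed=3)
    cfg = GBRTConfig(n_trees=100, shrinkage=0.1, max_depth=2)
    preds = loocv(X, y, lambda A, b: fit_gbrt(A, b, cfg).predict)
    assert pearson_r(preds, y) >= 0.99
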