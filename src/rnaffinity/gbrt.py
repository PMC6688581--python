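"""Gradient boosted regression trees, written out as the stagewise additive
model it is.

The learner builds

    F_M(x) = beta_0 + sum_{m=1}^{M} nu * beta_m * h_m(x)

where each weak learner h_m is a fixed-size least-squares regression tree fit
to the pseudo-residuals (negative loss gradients) of the current model, its
leaf values are the means of the pseudo-residuals falling in the leaf, beta_m
is chosen by exact line search, and nu in (0, 1] is the shrinkage (learning
rate).  The loss is fixed to the half squared error Psi(y, F) = (y - F)^2 / 2,
for which the pseudo-residuals are the ordinary residuals, beta_0 is the
target mean, and the line search has the closed form
beta_m = <h, y - F_{m-1}> / <h, h>.  (With mean leaf values this beta_m is
identically 1; it is still computed and stored so that alternative leaf-value
rules keep working.)

Trees are grown by exact greedy CART: every split minimizes the within-node
sum of squared deviations over all (feature, threshold) candidates, with
thresholds at midpoints between consecutive distinct sorted values and ties
broken toward the lowest feature index, then the lowest threshold -- the
learner is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import _speedups

__all__ = [
    "GBRTConfig",
    "TreeNode",
    "RegressionTree",
    "GBRTModel",
    "pseudo_residuals",
    "fit_tree",
    "line_search_weight",
    "fit_gbrt",
    "predict",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class GBRTConfig:
    """Hyperparameters of the boosted ensemble.

    Defaults (M=500 trees, nu=0.1, depth 3, min_samples_leaf=1) are common
    gradient-boosting choices sized for the tens-of-samples regime this tool
    targets; all are surfaced in configs and logs.
    """

    n_trees: int = 500
    shrinkage: float = 0.1
    max_depth: int = 3
    min_samples_leaf: int = 1
    loss: str = "half_squared_error"
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 0:
            raise ValueError(f"n_trees must be >= 0, got {self.n_trees}")
        if not 0.0 < self.shrinkage <= 1.0:
            raise ValueError(
                f"shrinkage must be in (0, 1], got {self.shrinkage}")
        if self.max_depth < 1:
            raise ValueError(f"max_depth must be >= 1, got {self.max_depth}")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if self.loss != "half_squared_error":
            raise ValueError(f"unsupported loss {self.loss!r}")


def pseudo_residuals(y: np.ndarray, f: np.ndarray,
                     loss: str = "half_squared_error") -> np.ndarray:
    """Negative gradient of the loss at the current predictions.

    For the half squared error this is simply ``y - f``.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {f.shape}")
    if loss != "half_squared_error":
        raise ValueError(f"unsupported loss {loss!r}")
    return y - f


@dataclass
class TreeNode:
    """Split node (feature, threshold, children) or leaf (value)."""

    value: float = float("nan")
    feature: int = -1
    threshold: float = float("nan")
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"value": self.value}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "feature" not in d:
            return cls(value=float(d["value"]))
        return cls(
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class RegressionTree:
    """A fitted CART regression tree; leaves partition the feature space, so
    every input lands in exactly one leaf.

    Nodes live in flat parallel arrays (``feature[i] < 0`` marks a leaf);
    :attr:`root` exposes the equivalent nested :class:`TreeNode` view used by
    the JSON schema.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    n_features: int
    #: per-node SSE reduction (split-gain importance source)
    gain: np.ndarray = None

    @property
    def root(self) -> TreeNode:
        def build(i: int) -> TreeNode:
            if self.feature[i] < 0:
                return TreeNode(value=float(self.value[i]))
            return TreeNode(feature=int(self.feature[i]),
                            threshold=float(self.threshold[i]),
                            left=build(int(self.left[i])),
                            right=build(int(self.right[i])))
        return build(0)

    @classmethod
    def from_root(cls, root: TreeNode, n_features: int) -> "RegressionTree":
        feature, threshold, left, right, value = [], [], [], [], []

        def add(node: TreeNode) -> int:
            i = len(feature)
            feature.append(-1 if node.is_leaf else node.feature)
            threshold.append(float("nan") if node.is_leaf
                             else node.threshold)
            left.append(-1)
            right.append(-1)
            value.append(node.value if node.is_leaf else float("nan"))
            if not node.is_leaf:
                left[i] = add(node.left)
                right[i] = add(node.right)
            return i

        add(root)
        return cls(feature=np.asarray(feature, dtype=np.int64),
                   threshold=np.asarray(threshold, dtype=float),
                   left=np.asarray(left, dtype=np.int64),
                   right=np.asarray(right, dtype=np.int64),
                   value=np.asarray(value, dtype=float),
                   n_features=n_features,
                   gain=np.zeros(len(feature)))

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.feature < 0))

    @property
    def split_gain(self) -> dict[int, float]:
        """Total SSE reduction attributed to each split feature."""
        out: dict[int, float] = {}
        for f, g in zip(self.feature, self.gain):
            if f >= 0:
                out[int(f)] = out.get(int(f), 0.0) + float(g)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}")
        return _speedups.predict_tree_arrays(
            self.feature, self.threshold, self.left, self.right, self.value,
            np.ascontiguousarray(X))


def fit_tree(X: np.ndarray, targets: np.ndarray,
             config: GBRTConfig) -> RegressionTree:
    """Grow one least-squares CART tree on (pseudo-residual) targets.

    Constant targets yield a single-leaf tree; fewer than
    ``2 * min_samples_leaf`` samples is an error.
    """
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
    targets = np.ascontiguousarray(np.asarray(targets, dtype=float))
    n, p = X.shape
    if targets.shape != (n,):
        raise ValueError(f"targets shape {targets.shape} does not match n={n}")
    if n < 2 * config.min_samples_leaf:
        raise ValueError(
            f"need >= {2 * config.min_samples_leaf} samples to split, got {n}")
    feature, threshold, left, right, value, gain = \
        _speedups.build_tree_arrays(X, targets, config.max_depth,
                                    config.min_samples_leaf)
    return RegressionTree(feature=feature, threshold=threshold, left=left,
                          right=right, value=value, n_features=p, gain=gain)


def line_search_weight(y: np.ndarray, f_prev: np.ndarray,
                       tree_predictions: np.ndarray,
                       loss: str = "half_squared_error") -> float:
    """Exact minimizer of sum_i Psi(y_i, f_prev_i + beta * h_i).

    Closed form for the half squared error:
    beta = <h, y - f_prev> / <h, h>, with beta = 0 when h is identically
    zero (nothing to scale).
    """
    y = np.asarray(y, dtype=float)
    f_prev = np.asarray(f_prev, dtype=float)
    h = np.asarray(tree_predictions, dtype=float)
    if not (y.shape == f_prev.shape == h.shape):
        raise ValueError("y, f_prev and tree_predictions must match in length")
    if loss != "half_squared_error":
        raise ValueError(f"unsupported loss {loss!r}")
    denom = float(h @ h)
    if denom == 0.0:
        return 0.0
    return float(h @ (y - f_prev)) / denom


@dataclass
class GBRTModel:
    """Fitted ensemble: initial constant, trees, per-tree weights, shrinkage."""

    beta0: float
    trees: list[RegressionTree]
    weights: list[float]
    config: GBRTConfig
    feature_names: list[str]
    #: training loss sum_i Psi(y_i, F_m(x_i)) after each stage (m = 0..M)
    train_loss_path: list[float] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model expects {self.n_features} features "
                f"({self.feature_names}), got {X.shape[1]}")
        out = np.full(X.shape[0], self.beta0, dtype=float)
        nu = self.config.shrinkage
        for tree, beta in zip(self.trees, self.weights):
            out += nu * beta * tree.predict(X)
        return out

    def staged_predict(self, X: np.ndarray):
        """Predictions after each boosting stage (stage 0 = beta0 alone)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(X.shape[0], self.beta0, dtype=float)
        yield out.copy()
        nu = self.config.shrinkage
        for tree, beta in zip(self.trees, self.weights):
            out += nu * beta * tree.predict(X)
            yield out.copy()

    def feature_importances(self) -> dict[str, float]:
        """Total split-gain (SSE reduction) credited to each feature."""
        totals = {name: 0.0 for name in self.feature_names}
        for tree in self.trees:
            for feat, g in tree.split_gain.items():
                totals[self.feature_names[feat]] += g
        return totals

    def to_json(self) -> str:
        payload = {
            "format_version": _FORMAT_VERSION,
            "beta0": self.beta0,
            "config": asdict(self.config),
            "feature_names": list(self.feature_names),
            "weights": list(self.weights),
            "trees": [t.root.to_dict() for t in self.trees],
            "train_loss_path": list(self.train_loss_path),
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GBRTModel":
        payload = json.loads(text)
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {payload.get('format_version')}")
        config = GBRTConfig(**payload["config"])
        feature_names = list(payload["feature_names"])
        trees = [
            RegressionTree.from_root(TreeNode.from_dict(d),
                                     n_features=len(feature_names))
            for d in payload["trees"]
        ]
        return cls(
            beta0=float(payload["beta0"]),
            trees=trees,
            weights=[float(w) for w in payload["weights"]],
            config=config,
            feature_names=feature_names,
            train_loss_path=[float(v) for v in payload["train_loss_path"]],
        )


def fit_gbrt(X: np.ndarray, y: np.ndarray, config: GBRTConfig,
             feature_names: Optional[Sequence[str]] = None) -> GBRTModel:
    """Fit the boosted ensemble by stagewise gradient descent.

    beta_0 is the loss-minimizing constant (the target mean); each of the M
    stages fits a tree to the pseudo-residuals, line-searches its weight, and
    updates F_m = F_{m-1} + nu * beta_m * h_m.  Missing values are rejected:
    imputation is the caller's job.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y shape {y.shape} does not match n={n}")
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in training data; impute upstream")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    elif len(feature_names) != p:
        raise ValueError("feature_names arity does not match X")

    beta0 = float(y.mean())
    f = np.full(n, beta0, dtype=float)
    trees: list[RegressionTree] = []
    weights: list[float] = []
    losses = [float(0.5 * np.sum((y - f) ** 2))]
    for _ in range(config.n_trees):
        residuals = pseudo_residuals(y, f, config.loss)
        tree = fit_tree(X, residuals, config)
        h = tree.predict(X)
        beta = line_search_weight(y, f, h, config.loss)
        f = f + config.shrinkage * beta * h
        trees.append(tree)
        weights.append(beta)
        losses.append(float(0.5 * np.sum((y - f) ** 2)))
    return GBRTModel(beta0=beta0, trees=trees, weights=weights, config=config,
                     feature_names=list(feature_names),
                     train_loss_path=losses)


def predict(model: GBRTModel, x: np.ndarray) -> np.ndarray:
    """Predict affinities for one vector or a batch of feature vectors."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    out = model.predict(np.atleast_2d(x))
    return float(out[0]) if single else out
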