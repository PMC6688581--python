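"""Evaluation metrics, leave-one-out cross-validation and greedy forward
feature selection.

Model quality is judged by the Pearson correlation between held-out
predictions and measured dissociation free energies, with the mean absolute
error (kcal/mol) and the coefficient of determination reported alongside.
Feature selection is a wrapper method: every feature is first scored by the
LOOCV correlation of a model trained on it alone, the ten best-scoring
features form a candidate pool, and features are then added greedily -- each
step admits the candidate that most improves the LOOCV correlation of the
refit model, stopping as soon as the best improvement falls below a small
tolerance.  The correlation alone drives ranking and greedy steps; MAE and R2
are reported, never optimized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConstantInputError",
    "pearson_r",
    "mae",
    "r2",
    "loocv",
    "rank_features",
    "greedy_select",
    "SelectionResult",
    "EvaluationReport",
    "evaluate_predictions",
    "Trainer",
]

#: A trainer maps (X, y) to a prediction callable over feature matrices.
Trainer = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]

#: Minimum LOOCV correlation gain for a greedy step to count as an
#: improvement ("stops to increase" tolerance).
IMPROVEMENT_TOL = 1e-4


class ConstantInputError(ValueError):
    """Correlation is undefined for a constant vector."""


def _pair(a, b, min_n: int):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {a.size}")
    return a, b


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson correlation r = sum((a-ā)(b-b̄)) / sqrt(sum(a-ā)² sum(b-b̄)²)."""
    a, b = _pair(a, b, 2)
    da = a - a.mean()
    db = b - b.mean()
    ssa = float(da @ da)
    ssb = float(db @ db)
    if ssa == 0.0 or ssb == 0.0:
        raise ConstantInputError("correlation undefined for a constant vector")
    return float((da @ db) / math.sqrt(ssa * ssb))


def mae(pred: Sequence[float], actual: Sequence[float]) -> float:
    """Mean absolute prediction error, kcal/mol."""
    pred, actual = _pair(pred, actual, 1)
    return float(np.mean(np.abs(pred - actual)))


def r2(pred: Sequence[float], actual: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (1 is perfect)."""
    pred, actual = _pair(pred, actual, 2)
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConstantInputError("R2 undefined for constant actual values")
    ss_res = float(np.sum((actual - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def loocv(X: np.ndarray, y: np.ndarray, trainer: Trainer) -> np.ndarray:
    """Leave-one-out held-out predictions, one per sample, order preserved."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"LOOCV needs at least 3 samples, got {n}")
    preds = np.empty(n, dtype=float)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            predict_fn = trainer(X[keep], y[keep])
        except Exception as exc:
            raise RuntimeError(f"trainer failed on fold {i}: {exc}") from exc
        preds[i] = float(np.asarray(predict_fn(X[i:i + 1]))[0])
    return preds


def _loocv_r(X: np.ndarray, y: np.ndarray, trainer: Trainer,
             use_loocv: bool) -> float:
    if use_loocv:
        preds = loocv(X, y, trainer)
    else:
        preds = np.asarray(trainer(X, y)(X), dtype=float)
    return pearson_r(preds, y)


def rank_features(
    X: np.ndarray,
    y: np.ndarray,
    trainer: Trainer,
    feature_names: Optional[Sequence[str]] = None,
    top_k: int = 10,
    use_loocv: bool = True,
) -> list[tuple[int, float]]:
    """Score each feature by single-feature model correlation; keep the best.

    Returns ``(feature_index, score)`` pairs sorted descending; the sort is
    stable, so ties keep registry order.  Features whose correlation is
    undefined score -inf and are logged.  Fewer than ``top_k`` features are
    all retained.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if p < 1:
        raise ValueError("need at least one feature")
    names = list(feature_names) if feature_names is not None \
        else [f"x{j}" for j in range(p)]
    scored: list[tuple[int, float]] = []
    for j in range(p):
        try:
            score = _loocv_r(X[:, [j]], y, trainer, use_loocv)
        except (ConstantInputError, ValueError, RuntimeError) as exc:
            logger.warning("feature %s: correlation undefined (%s); "
                           "ranked last", names[j], exc)
            score = float("-inf")
        scored.append((j, score))
    ranked = sorted(scored, key=lambda t: -t[1])
    return ranked[:top_k]


@dataclass
class SelectionResult:
    """Outcome of greedy forward selection."""

    selected: list[int]                    # feature indices, in added order
    trajectory: list[tuple[int, float]]    # (feature added, LOOCV r after)
    final_r: float


def greedy_select(
    X: np.ndarray,
    y: np.ndarray,
    ranked: Sequence[tuple[int, float]],
    trainer: Trainer,
    tol: float = IMPROVEMENT_TOL,
    use_loocv: bool = True,
) -> SelectionResult:
    """Greedy forward selection from the ranked candidate pool.

    Starts from the best single feature; each step refits with one more
    candidate and keeps the one maximizing the LOOCV correlation, stopping
    when the best gain is <= ``tol``.  Deterministic: candidate ties keep the
    earlier-ranked feature.
    """
    if not ranked:
        raise ValueError("ranked candidate pool is empty")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    pool = [j for j, _ in ranked]
    selected = [pool[0]]
    current_r = _safe_r(X, y, selected, trainer, use_loocv)
    trajectory = [(pool[0], current_r)]
    remaining = pool[1:]
    while remaining:
        best_j, best_r = None, float("-inf")
        for j in remaining:
            r = _safe_r(X, y, selected + [j], trainer, use_loocv)
            if r > best_r:
                best_j, best_r = j, r
        if best_j is None or best_r - current_r <= tol:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        current_r = best_r
        trajectory.append((best_j, best_r))
    return SelectionResult(selected=selected, trajectory=trajectory,
                           final_r=current_r)


def _safe_r(X, y, cols, trainer, use_loocv) -> float:
    try:
        return _loocv_r(X[:, cols], y, trainer, use_loocv)
    except (ConstantInputError, RuntimeError):
        return float("-inf")


@dataclass
class EvaluationReport:
    """LOOCV predictions and summary metrics for one complex class."""

    class_label: str
    predictions: list[float]
    actual: list[float]
    pearson_r: float
    mae: float
    r2: float
    n_complexes: int
    selected_features: list[str] = field(default_factory=list)
    complex_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "class": self.class_label,
            "n_complexes": self.n_complexes,
            "pearson_r": self.pearson_r,
            "mae": self.mae,
            "r2": self.r2,
            "selected_features": list(self.selected_features),
            "predictions": list(self.predictions),
            "actual": list(self.actual),
            "complex_ids": list(self.complex_ids),
        }


def evaluate_predictions(
    pred: Sequence[float],
    actual: Sequence[float],
    class_label: str = "all",
    selected_features: Optional[Sequence[str]] = None,
    complex_ids: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Bundle held-out predictions into an :class:`EvaluationReport`."""
    pred = list(map(float, pred))
    actual = list(map(float, actual))
    return EvaluationReport(
        class_label=class_label,
        predictions=pred,
        actual=actual,
        pearson_r=pearson_r(pred, actual),
        mae=mae(pred, actual),
        r2=r2(pred, actual),
        n_complexes=len(pred),
        selected_features=list(selected_features or []),
        complex_ids=list(complex_ids or []),
    )
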