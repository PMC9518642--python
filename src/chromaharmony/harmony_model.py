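"""Linear color-harmony modeling: normalization, prediction, fitting, evaluation.

The bundled reference model is the fitted linear regression over seven
normalized features::

    harmony = 1.499 f1 + 0.408 f4 - 0.594 f5 - 0.52 f11 - 0.47 f13
              - 1.386 f14 + 0.862 f15 + 0.249

Its inputs are min-max normalized features; because the normalization bounds
of the original dataset are unpublished, the model refuses to score raw
features unless a :class:`NormParams` is attached (or batch normalization is
requested explicitly at the CLI).

Also here: OLS fitting with optional greedy backward elimination, k-fold
cross-validation, MAE/RMSE/Pearson/accuracy metrics, Cronbach's alpha for
rating matrices, and the pleasure/arousal → harmony linear map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)

#: Coefficients of the bundled reference regression model.
REFERENCE_COEFFICIENTS: dict[str, float] = {
    "f1": 1.499,
    "f4": 0.408,
    "f5": -0.594,
    "f11": -0.52,
    "f13": -0.47,
    "f14": -1.386,
    "f15": 0.862,
}
REFERENCE_INTERCEPT: float = 0.249

#: Pleasure/arousal → harmony linear map coefficients.
PAD_PLEASURE_COEF = 0.813
PAD_AROUSAL_COEF = -0.616
PAD_INTERCEPT = 0.374

DEFAULT_THRESHOLD = 0.0


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormParams:
    """Per-feature min/max bounds for min-max normalization."""

    minimum: dict[str, float]
    maximum: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.minimum) != set(self.maximum):
            raise ValueError("minimum and maximum must cover the same features")
        for name in self.minimum:
            if self.maximum[name] < self.minimum[name]:
                raise ValueError(f"max < min for feature {name!r}")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.minimum)

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "NormParams":
        """Record per-column min/max of a feature table."""
        if len(table) < 2:
            raise ValueError("need at least 2 rows to fit normalization bounds")
        return cls(
            minimum={c: float(table[c].min()) for c in table.columns},
            maximum={c: float(table[c].max()) for c in table.columns},
        )

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Apply ``(x - min) / (max - min)`` per feature.

        Values falling outside the fitted bounds are clamped to [0, 1] with a
        warning; constant features map to 0.
        """
        out = {}
        clamped = False
        for name in table.columns:
            if name not in self.minimum:
                raise KeyError(f"feature {name!r} has no fitted normalization bounds")
            lo, hi = self.minimum[name], self.maximum[name]
            col = table[name].to_numpy(dtype=np.float64)
            if hi == lo:
                out[name] = np.zeros_like(col)
                continue
            scaled = (col - lo) / (hi - lo)
            clip = np.clip(scaled, 0.0, 1.0)
            if np.any(clip != scaled):
                clamped = True
            out[name] = clip
        if clamped:
            logger.warning("normalization clamped values outside the fitted [min, max] range")
        return pd.DataFrame(out, index=table.index)

    def to_dict(self) -> dict:
        return {"min": dict(self.minimum), "max": dict(self.maximum)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormParams":
        return cls(minimum=dict(d["min"]), maximum=dict(d["max"]))


def normalize(table: pd.DataFrame, norm: NormParams) -> pd.DataFrame:
    if norm is None:
        raise ValueError("normalization parameters are required (unfitted norm)")
    return norm.transform(table)


# ---------------------------------------------------------------------------
# the linear model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonyModel:
    """Affine harmony predictor over a named feature subset."""

    intercept: float
    coefficients: dict[str, float]
    norm: NormParams | None = None
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        vals = [self.intercept, self.threshold, *self.coefficients.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("model parameters must be finite")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def predict(self, features) -> np.ndarray | float:
        return predict_harmony(self, features)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "norm": self.norm.to_dict() if self.norm is not None else None,
            "threshold": self.threshold,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "HarmonyModel":
        norm = NormParams.from_dict(d["norm"]) if d.get("norm") else None
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            norm=norm,
            threshold=float(d.get("threshold", DEFAULT_THRESHOLD)),
        )

    @classmethod
    def load(cls, path) -> "HarmonyModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def reference_model(norm: NormParams | None = None) -> HarmonyModel:
    """The bundled fitted regression model (expects normalized inputs)."""
    return HarmonyModel(
        intercept=REFERENCE_INTERCEPT,
        coefficients=dict(REFERENCE_COEFFICIENTS),
        norm=norm,
    )


def _features_to_matrix(model: HarmonyModel, features) -> tuple[np.ndarray, bool]:
    """Extract the model's feature columns; returns (matrix, was_single_row)."""
    names = model.feature_names
    if isinstance(features, pd.DataFrame):
        missing = [n for n in names if n not in features.columns]
        if missing:
            raise KeyError(f"missing required feature(s): {', '.join(missing)}")
        return features[list(names)].to_numpy(dtype=np.float64), False
    if isinstance(features, Mapping):
        missing = [n for n in names if n not in features]
        if missing:
            raise KeyError(f"missing required feature(s): {', '.join(missing)}")
        return np.array([[float(features[n]) for n in names]]), True
    arr = np.asarray(features, dtype=np.float64)
    if arr.ndim == 1:
        if arr.size != len(names):
            raise ValueError(f"expected {len(names)} feature values, got {arr.size}")
        return arr[None, :], True
    if arr.ndim == 2:
        if arr.shape[1] != len(names):
            raise ValueError(f"expected {len(names)} feature columns, got {arr.shape[1]}")
        return arr, False
    raise ValueError("features must be a mapping, DataFrame, or 1-D/2-D array")


def predict_harmony(model: HarmonyModel, features) -> np.ndarray | float:
    """Intercept plus dot product over the model's feature subset.

    ``features`` must already be on the model's normalized scale.
    """
    X, single = _features_to_matrix(model, features)
    beta = np.array([model.coefficients[n] for n in model.feature_names])
    scores = model.intercept + X @ beta
    return float(scores[0]) if single else scores


def pad_to_harmony(pleasure, arousal):
    """Linear map from pleasure/arousal coordinates to a harmony score."""
    p = np.asarray(pleasure, dtype=np.float64)
    a = np.asarray(arousal, dtype=np.float64)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(a))):
        raise ValueError("pleasure and arousal must be finite")
    out = PAD_PLEASURE_COEF * p + PAD_AROUSAL_COEF * a + PAD_INTERCEPT
    return float(out) if out.ndim == 0 else out


def classify(model: HarmonyModel, features, threshold: float | None = None) -> np.ndarray | bool:
    """True (harmonious) iff the predicted score strictly exceeds the threshold.

    A score exactly at the threshold counts as disharmonious.
    """
    t = model.threshold if threshold is None else threshold
    scores = predict_harmony(model, features)
    out = np.asarray(scores) > t
    return bool(out) if np.isscalar(scores) else out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_ols(
    features: pd.DataFrame,
    targets,
    *,
    norm: NormParams | None = None,
    eliminate: bool = False,
    cv_k: int = 10,
    seed: int = 0,
    ridge_fallback: bool = False,
    ridge_alpha: float = 1e-8,
) -> HarmonyModel:
    """Least-squares fit of the affine harmony model.

    Parameters
    ----------
    features
        Feature table (already normalized if a ``norm`` is supplied for
        bookkeeping); columns become the model's feature subset.
    targets
        Harmony scores, one per row.
    eliminate
        If True, greedily drop the feature whose removal most improves the
        cross-validated RMSE, until no removal helps.
    ridge_fallback
        Permit a tiny ridge penalty when the design matrix is column-rank
        deficient; otherwise rank deficiency raises.
    """
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features, dtype=np.float64))
        features.columns = [f"x{i}" for i in range(features.shape[1])]
    y = np.asarray(targets, dtype=np.float64)
    if y.ndim != 1 or len(y) != len(features):
        raise ValueError("targets must be a 1-D vector matching the feature rows")
    if len(features) < features.shape[1] + 1:
        raise ValueError("need at least as many rows as coefficients (incl. intercept)")

    names = list(features.columns)
    if eliminate and len(names) > 1:
        names = _backward_eliminate(features, y, names, cv_k=cv_k, seed=seed)

    X = features[names].to_numpy(dtype=np.float64)
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        if not ridge_fallback:
            raise ValueError(
                "design matrix is rank deficient; enable ridge_fallback to fit anyway"
            )
        logger.warning("rank-deficient design: falling back to ridge (alpha=%g)", ridge_alpha)
        beta = np.linalg.solve(
            design.T @ design + ridge_alpha * np.eye(design.shape[1]), design.T @ y
        )
    else:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return HarmonyModel(
        intercept=float(beta[0]),
        coefficients={n: float(b) for n, b in zip(names, beta[1:])},
        norm=norm,
    )


def _cv_rmse(features: pd.DataFrame, y: np.ndarray, names: list[str], cv_k: int, seed: int) -> float:
    k = min(cv_k, len(y))
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    sq = 0.0
    for train_idx, test_idx in splitter.split(features):
        model = fit_ols(features.iloc[train_idx][names], y[train_idx], ridge_fallback=True)
        pred = predict_harmony(model, features.iloc[test_idx][names])
        sq += float(((pred - y[test_idx]) ** 2).sum())
    return float(np.sqrt(sq / len(y)))


def _backward_eliminate(
    features: pd.DataFrame, y: np.ndarray, names: list[str], cv_k: int, seed: int
) -> list[str]:
    current = list(names)
    best = _cv_rmse(features, y, current, cv_k, seed)
    while len(current) > 1:
        trials = [
            (_cv_rmse(features, y, [n for n in current if n != drop], cv_k, seed), drop)
            for drop in current
        ]
        trial_rmse, drop = min(trials)
        if trial_rmse >= best:
            break
        best = trial_rmse
        current.remove(drop)
        logger.info("backward elimination dropped %s (cv RMSE %.4f)", drop, best)
    return current


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def mae(pred, truth) -> float:
    p, t = np.asarray(pred, dtype=np.float64), np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred and truth must be equal-length non-empty vectors")
    return float(np.abs(p - t).mean())


def rmse(pred, truth) -> float:
    p, t = np.asarray(pred, dtype=np.float64), np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred and truth must be equal-length non-empty vectors")
    return float(np.sqrt(((p - t) ** 2).mean()))


def correct_classification_rate(pred_labels, truth_labels) -> float:
    """(TP + TN) / (P + N): overall binary accuracy."""
    p = np.asarray(pred_labels, dtype=bool)
    t = np.asarray(truth_labels, dtype=bool)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    return float((p == t).mean())


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalReport:
    """Pooled and per-fold evaluation of a cross-validated model."""

    task: str
    mae: float
    rmse: float
    pearson_r: float | None = None
    cc: float | None = None
    folds: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mae > self.rmse + 1e-12:
            raise ValueError("MAE cannot exceed RMSE")

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "mae": self.mae,
            "rmse": self.rmse,
            "pearson_r": self.pearson_r,
            "cc": self.cc,
            "folds": list(self.folds),
        }


def kfold_cv(
    features: pd.DataFrame,
    targets,
    *,
    k: int = 10,
    seed: int = 0,
    task: str = "regression",
    threshold: float = DEFAULT_THRESHOLD,
    fit_fn: Callable[..., HarmonyModel] | None = None,
) -> EvalReport:
    """Shuffled k-fold cross-validation of the harmony model.

    For ``task="classification"`` the continuous targets are binarized at
    ``threshold`` (strictly greater = harmonious), folds are stratified on
    the labels, and pooled accuracy (CC) is reported alongside MAE/RMSE of
    the underlying scores.
    """
    if task not in ("regression", "classification"):
        raise ValueError(f"unknown task {task!r}")
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features, dtype=np.float64))
        features.columns = [f"x{i}" for i in range(features.shape[1])]
    y = np.asarray(targets, dtype=np.float64)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    fit = fit_fn or (lambda Xtr, ytr: fit_ols(Xtr, ytr, ridge_fallback=True))

    if task == "classification":
        labels = y > threshold
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(features, labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(features)

    pred = np.empty(n)
    folds = []
    for fold_id, (train_idx, test_idx) in enumerate(splits):
        model = fit(features.iloc[train_idx], y[train_idx])
        fold_pred = np.atleast_1d(predict_harmony(model, features.iloc[test_idx]))
        pred[test_idx] = fold_pred
        entry = {
            "fold": fold_id,
            "n_test": int(len(test_idx)),
            "mae": mae(fold_pred, y[test_idx]),
            "rmse": rmse(fold_pred, y[test_idx]),
        }
        if task == "classification":
            entry["cc"] = correct_classification_rate(
                fold_pred > threshold, y[test_idx] > threshold
            )
        folds.append(entry)

    pooled_mae, pooled_rmse = mae(pred, y), rmse(pred, y)
    if task == "classification":
        cc = correct_classification_rate(pred > threshold, y > threshold)
        return EvalReport(task=task, mae=pooled_mae, rmse=pooled_rmse, cc=cc, folds=tuple(folds))
    if np.ptp(y) == 0 or np.ptp(pred) == 0:
        r = None
    else:
        r, _ = pearson_r(pred, y)
    return EvalReport(task=task, mae=pooled_mae, rmse=pooled_rmse, pearson_r=r, folds=tuple(folds))


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

RATING_SCALE = (-2, -1, 0, 1, 2)


def validate_rating_matrix(ratings: pd.DataFrame) -> pd.DataFrame:
    """Check a materials × raters score grid: complete, integer, 5-level scale."""
    if ratings.isna().any().any():
        raise ValueError("rating matrix must have no missing cells")
    vals = ratings.to_numpy()
    if not np.isin(vals, RATING_SCALE).all():
        raise ValueError(f"ratings must lie on the 5-level scale {RATING_SCALE}")
    return ratings


def cronbach_alpha(ratings, *, raters: str = "columns") -> float:
    """Internal-consistency coefficient of a materials × raters score grid.

    ``alpha = K/(K-1) * (1 - sum_i var(rater_i) / var(total score))`` with
    population (1/n) variances; the K components are the raters and the
    observations are the materials.  Set ``raters="rows"`` for the transposed
    orientation.
    """
    arr = ratings.to_numpy(dtype=np.float64) if isinstance(ratings, pd.DataFrame) else np.asarray(
        ratings, dtype=np.float64
    )
    if arr.ndim != 2:
        raise ValueError("rating matrix must be 2-D")
    if raters == "rows":
        arr = arr.T
    elif raters != "columns":
        raise ValueError("raters must be 'columns' or 'rows'")
    n_materials, k = arr.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    if n_materials < 2:
        raise ValueError("need at least 2 materials")
    rater_vars = arr.var(axis=0)  # population variance across materials
    total_var = arr.sum(axis=1).var()
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha is undefined")
    return float(k / (k - 1) * (1.0 - rater_vars.sum() / total_var))
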