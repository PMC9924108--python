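"""GPR regression: target rescaling, models, evaluation, statistics.

Measured gamma passing rates concentrate in the (90, 100)% band, which
sits in the flat tail of the logit curve.  A linear SVR fitted to the
raw percentages can predict values above 100%; the remedy used here is
a bespoke rescaling before the logit:

    x = clip((g/100 - offset) * scale, eps, 1 - eps),   t = ln(x/(1-x))

with offset 0.9 and scale 10, so the 90-100% band maps onto (0, 1) and
then onto the whole real line.  Predictions are mapped back with the
inverse logit, which bounds them to (90, 100) — no prediction can
exceed 100%.  Negative rescaled values are floored at zero and the
epsilon clip (default 1e-3) keeps the logit finite there.

Models are the scikit-learn RandomForestRegressor (150 trees,
min_samples_leaf 6, min_samples_split 3, max_features sqrt, max_depth
80) and linear-kernel SVR (C = 1, epsilon = 0.5).  The SVR sees
z-scored features (C is scale sensitive); the forest sees raw
features and, by default, raw targets (trees cannot extrapolate past
their training range, so they need no rescaling).

Evaluation is repeated random hold-out: 30 shuffled 70/30 splits, MAE /
RMSE / R^2 per split summarized as mean +/- SD, plus the overall
maximum absolute error and the fraction of test predictions within a
3-percentage-point error threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "TransformConfig",
    "ModelConfig",
    "EvalConfig",
    "EvalSummary",
    "FittedGPRModel",
    "gpr_forward_transform",
    "gpr_inverse_transform",
    "fit_model",
    "predict_gpr",
    "repeated_holdout_eval",
    "permutation_importance",
    "correlation_report",
    "correlation_category",
    "site_anova",
    "tune_hyperparameters",
]

ModelKind = Literal["rfr", "svr"]


@dataclass(frozen=True)
class TransformConfig:
    """Parameters of the GPR rescaled-logit transform.

    ``apply_to`` selects which models see transformed targets: ``"svr"``
    (default — forests cannot extrapolate past their training range and
    need no bounding), ``"both"``, or ``"none"`` (raw percentages; used
    e.g. when assessing linear recovery on the untransformed scale).
    """

    offset: float = 0.9
    scale: float = 10.0
    epsilon: float = 1e-3
    apply_to: Literal["svr", "both", "none"] = "svr"

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")
        if self.offset + 1.0 / self.scale > 1.0 + 1e-12:
            raise ValueError("offset + 1/scale must be <= 1")

    def applies_to(self, kind: ModelKind) -> bool:
        if self.apply_to == "none":
            return False
        return kind == "svr" or self.apply_to == "both"


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the two regressors (packaged defaults)."""

    rfr: Mapping[str, object] = field(
        default_factory=lambda: dict(
            n_estimators=150,
            min_samples_leaf=6,
            min_samples_split=3,
            max_features="sqrt",
            max_depth=80,
        )
    )
    svr: Mapping[str, object] = field(
        default_factory=lambda: dict(kernel="linear", C=1.0, epsilon=0.5)
    )
    standardize_features: bool = True


@dataclass(frozen=True)
class EvalConfig:
    """Repeated hold-out protocol parameters."""

    n_repeats: int = 30
    test_fraction: float = 0.3
    cv_folds: int = 10  # used only by the optional tuning routine
    error_threshold: float = 3.0  # percentage points of GPR
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


# ---------------------------------------------------------------------------
# transforms


def gpr_forward_transform(gpr_percent, cfg: TransformConfig = TransformConfig()):
    """Map GPR (percent) onto the real line via the rescaled logit.

    Values whose rescaled argument would be non-positive (GPR at or
    below 100*offset) are floored, then epsilon-clipped so the logit
    stays finite.  Accepts scalars or arrays.
    """
    g = np.asarray(gpr_percent, dtype=float)
    x = (g / 100.0 - cfg.offset) * cfg.scale
    x = np.clip(np.maximum(x, 0.0), cfg.epsilon, 1.0 - cfg.epsilon)
    out = np.log(x / (1.0 - x))
    return float(out) if np.isscalar(gpr_percent) else out


def gpr_inverse_transform(t, cfg: TransformConfig = TransformConfig()):
    """Inverse of :func:`gpr_forward_transform` (without the clipping).

    The sigmoid bounds the output to (100*offset, 100*(offset+1/scale)),
    so with the defaults no prediction can exceed 100%.
    """
    t = np.asarray(t, dtype=float)
    out = 100.0 * (cfg.offset + expit(t) / cfg.scale)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# models


@dataclass
class FittedGPRModel:
    """A fitted regressor plus its feature scaler and target transform."""

    kind: ModelKind
    estimator: object
    scaler: StandardScaler | None
    transform: TransformConfig | None
    feature_names: list[str]

    def fit(self, X, y=None):  # scikit-learn estimator-protocol shim; already fitted
        return self

    def predict(self, features) -> np.ndarray:
        """Predict GPR (percent) for a feature matrix or DataFrame."""
        X = _as_matrix(features, self.feature_names)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        pred = self.estimator.predict(X)
        if self.transform is not None:
            pred = gpr_inverse_transform(pred, self.transform)
        return np.asarray(pred, dtype=float)


def _as_matrix(features, feature_names: Sequence[str] | None = None) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        if feature_names:
            missing = [c for c in feature_names if c not in features.columns]
            if missing:
                raise ValueError(f"feature columns missing: {missing}")
            features = features[list(feature_names)]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if feature_names and X.shape[1] != len(feature_names):
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns, model expects {len(feature_names)}"
        )
    return X


def fit_model(
    train_features,
    train_gpr,
    model_kind: ModelKind,
    model_cfg: ModelConfig = ModelConfig(),
    transform_cfg: TransformConfig = TransformConfig(),
    random_state: int | None = 0,
) -> FittedGPRModel:
    """Fit an RFR or linear-SVR GPR regressor.

    Targets are transformed per ``transform_cfg.apply_to``; SVR features
    are z-scored by training statistics when
    ``model_cfg.standardize_features``.  Deterministic given
    ``random_state``.
    """
    names = (
        list(train_features.columns)
        if isinstance(train_features, pd.DataFrame)
        else [f"x{j}" for j in range(np.asarray(train_features).shape[1])]
    )
    X = _as_matrix(train_features)
    y = np.asarray(train_gpr, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 training rows")

    scaler = None
    if model_kind == "svr" and model_cfg.standardize_features:
        if np.any(np.var(X, axis=0) == 0):
            warnings.warn("zero-variance feature: centered only, not scaled")
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)

    transform = transform_cfg if transform_cfg.applies_to(model_kind) else None
    if transform is not None:
        y = gpr_forward_transform(y, transform)

    if model_kind == "rfr":
        est = RandomForestRegressor(random_state=random_state, **dict(model_cfg.rfr))
    elif model_kind == "svr":
        est = SVR(**dict(model_cfg.svr))
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    est.fit(X, y)
    return FittedGPRModel(
        kind=model_kind,
        estimator=est,
        scaler=scaler,
        transform=transform,
        feature_names=names,
    )


def predict_gpr(model: FittedGPRModel, features) -> np.ndarray:
    """Predict GPR (percent) per row; convenience alias for ``model.predict``."""
    return model.predict(features)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalSummary:
    """Repeated hold-out statistics for one model."""

    model_kind: str
    mae_mean: float
    mae_sd: float
    rmse_mean: float
    rmse_sd: float
    r2_mean: float
    r2_sd: float
    max_abs_error: float
    fraction_within_threshold: float
    error_threshold: float
    per_repeat: pd.DataFrame  # columns: repeat, mae, rmse, r2

    def as_dict(self) -> dict[str, float]:
        return {
            "model": self.model_kind,
            "mae_mean": self.mae_mean,
            "mae_sd": self.mae_sd,
            "rmse_mean": self.rmse_mean,
            "rmse_sd": self.rmse_sd,
            "r2_mean": self.r2_mean,
            "r2_sd": self.r2_sd,
            "max_abs_error": self.max_abs_error,
            "fraction_within_threshold": self.fraction_within_threshold,
            "error_threshold": self.error_threshold,
        }


def repeated_holdout_eval(
    features,
    gpr,
    model_kind: ModelKind,
    model_cfg: ModelConfig = ModelConfig(),
    eval_cfg: EvalConfig = EvalConfig(),
    transform_cfg: TransformConfig = TransformConfig(),
) -> EvalSummary:
    """Evaluate a model over repeated shuffled 70/30 train/test splits.

    Per repeat: fit on the training fraction, compute per-test-row
    absolute error in GPR percentage points, then MAE, RMSE and R^2 on
    the test set.  The summary reports mean +/- SD across repeats plus
    the overall maximum error and fraction of test predictions within
    ``eval_cfg.error_threshold``.  Bit-reproducible for a fixed seed.
    """
    X = features if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    y = np.asarray(gpr, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 rows for repeated hold-out evaluation")
    master = np.random.default_rng(eval_cfg.seed)
    rows = []
    max_err = 0.0
    n_within = 0
    n_total = 0
    for rep in range(eval_cfg.n_repeats):
        split_seed = int(master.integers(2**31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=eval_cfg.test_fraction, shuffle=True, random_state=split_seed
        )
        model = fit_model(X_tr, y_tr, model_kind, model_cfg, transform_cfg,
                          random_state=split_seed)
        pred = model.predict(X_te)
        err = np.abs(pred - y_te)
        rows.append(
            {
                "repeat": rep,
                "mae": mean_absolute_error(y_te, pred),
                "rmse": float(np.sqrt(mean_squared_error(y_te, pred))),
                "r2": r2_score(y_te, pred),
            }
        )
        max_err = max(max_err, float(err.max()))
        n_within += int(np.sum(err < eval_cfg.error_threshold))
        n_total += len(err)
    per_repeat = pd.DataFrame(rows)
    sd = per_repeat.std(ddof=1) if len(per_repeat) > 1 else per_repeat * 0.0
    return EvalSummary(
        model_kind=model_kind,
        mae_mean=float(per_repeat["mae"].mean()),
        mae_sd=float(sd["mae"]),
        rmse_mean=float(per_repeat["rmse"].mean()),
        rmse_sd=float(sd["rmse"]),
        r2_mean=float(per_repeat["r2"].mean()),
        r2_sd=float(sd["r2"]),
        max_abs_error=max_err,
        fraction_within_threshold=n_within / n_total,
        error_threshold=eval_cfg.error_threshold,
        per_repeat=per_repeat,
    )


def permutation_importance(
    model: FittedGPRModel,
    test_features,
    test_gpr,
    n_shuffles: int = 30,
    random_state: int | None = 0,
) -> pd.DataFrame:
    """Permutation importance on the GPR percentage scale.

    Per feature: the mean decrease in test R^2 over ``n_shuffles``
    independent permutations of that column, with its SD.  Returned
    sorted descending by importance.
    """
    y = np.asarray(test_gpr, dtype=float)
    X = (
        test_features[model.feature_names]
        if isinstance(test_features, pd.DataFrame)
        else pd.DataFrame(np.asarray(test_features, dtype=float), columns=model.feature_names)
    )
    if len(X) == 0:
        raise ValueError("test set is empty")

    def scoring(est, Xs, ys):
        return r2_score(ys, est.predict(Xs))

    res = _sk_permutation_importance(
        model, X, y, scoring=scoring, n_repeats=n_shuffles, random_state=random_state
    )
    out = pd.DataFrame(
        {
            "feature": model.feature_names,
            "importance_mean": res.importances_mean,
            "importance_sd": res.importances_std,
        }
    )
    return out.sort_values("importance_mean", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# statistics


def correlation_category(r: float) -> str:
    """Correlation-strength label on |r| with half-open bins.

    none (0, 0.2]; weak (0.2, 0.4]; moderate (0.4, 0.6]; strong
    (0.6, 0.8); very strong >= 0.8.  The published band edges leave
    gaps (0.20-0.21 etc.); assignment at a boundary goes to the lower
    band, except 0.8 which opens "very strong".
    """
    a = abs(r)
    if np.isnan(a):
        return "undefined"
    if a <= 0.2:
        return "none"
    if a <= 0.4:
        return "weak"
    if a <= 0.6:
        return "moderate"
    if a < 0.8:
        return "strong"
    return "very strong"


def correlation_report(features: pd.DataFrame, gpr) -> pd.DataFrame:
    """Pearson r, two-sided p and strength category per feature column."""
    y = np.asarray(gpr, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 rows for a correlation report")
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append(
            {"feature": col, "r": float(r), "p": float(p),
             "category": correlation_category(r)}
        )
    return pd.DataFrame(rows)


def site_anova(features: pd.DataFrame, metrics: Sequence[str],
               group_column: str = "site") -> pd.DataFrame:
    """Classical one-way ANOVA of each metric across site groups."""
    groups = {k: v for k, v in features.groupby(group_column)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for ANOVA")
    for name, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    rows = []
    for metric in metrics:
        samples = [g[metric].to_numpy(dtype=float) for g in groups.values()]
        f, p = stats.f_oneway(*samples)
        rows.append({"metric": metric, "F": float(f), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optional hyperparameter tuning


_DEFAULT_GRIDS: dict[str, dict] = {
    "rfr": {
        "n_estimators": [100, 150, 200],
        "min_samples_leaf": [2, 6, 10],
        "min_samples_split": [2, 3, 5],
        "max_features": ["sqrt", 1.0],
        "max_depth": [20, 80, None],
    },
    "svr": {
        "kernel": ["linear", "rbf", "poly"],
        "C": [0.1, 1.0, 10.0],
        "epsilon": [0.1, 0.5, 1.0],
    },
}


def tune_hyperparameters(
    features,
    gpr,
    model_kind: ModelKind,
    grid: Mapping[str, Sequence] | None = None,
    cv_folds: int = 10,
    transform_cfg: TransformConfig = TransformConfig(),
    random_state: int | None = 0,
) -> dict:
    """Grid-search CV over a declared grid; returns the best parameters.

    Provided for completeness — the packaged :class:`ModelConfig`
    defaults pin the published values and are used everywhere else.
    """
    X = _as_matrix(features)
    y = np.asarray(gpr, dtype=float)
    if model_kind == "svr":
        X = StandardScaler().fit_transform(X)
        if transform_cfg.applies_to("svr"):
            y = gpr_forward_transform(y, transform_cfg)
        base = SVR()
    else:
        base = RandomForestRegressor(random_state=random_state)
    search = GridSearchCV(base, dict(grid or _DEFAULT_GRIDS[model_kind]), cv=cv_folds)
    search.fit(X, y)
    return dict(search.best_params_)
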