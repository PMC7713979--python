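"""A-priori prediction of gene richness and coverage depths from partial curves.

The full effort pipeline needs a deep library; in practice one wants the
answer from a shallow pilot run.  This module trains regressors that map
features of the first ~20% of a rarefaction curve — the asymptotes of
logistic and four-parameter Weibull fits to the truncated curve plus its
observed depth/richness ranges — onto the quantities the full curve would
yield (maximum gene count and the depths covering 90/95/99% of it).

Three regression strategies are supported: stepwise linear regression,
radial-basis support-vector regression, and gradient-boosted trees
(XGBoost).  Prediction intervals come from bagging: the model is refit on
bootstrap resamples of the training table and the spread of the ensemble's
predictions gives the interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.compose import TransformedTargetRegressor
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .effort import DEFAULT_COVER_FRACTIONS, effort_percent, estimate_effort, invert_growth
from .errors import DataValidationError, NumericalError, ParameterError
from .growth_models import fit_growth, grid_init, select_model
from .rarefaction import (
    KIND_EXTRAPOLATED,
    RarefactionCurve,
    build_curve,
    curve_from_vector,
    pool_samples,
)

__all__ = [
    "FeatureVector",
    "TrainedPredictor",
    "ValidationReport",
    "PredictionResult",
    "MODEL1_FEATURES",
    "MODEL2_FEATURES",
    "TARGETS",
    "truncate_curve",
    "extract_features",
    "build_training_table",
    "train_predictor",
    "predict_with_interval",
    "cross_validate",
    "regression_metrics",
    "predict_from_partial",
]

KINDS = ("linear", "kernel", "boosting")
TARGETS = ("max_genes", "reads_q90", "reads_q95", "reads_q99")

# Predictor presets mirroring the two published feature sets: model 1 keeps
# both asymptotes, model 2 drops the logistic one.
MODEL1_FEATURES = ("asym_logistic", "asym_weibull4", "min_reads", "max_reads")
MODEL2_FEATURES = ("asym_weibull4", "min_reads", "max_reads")


@dataclass(frozen=True)
class FeatureVector:
    """Features of a truncated rarefaction curve used for a-priori prediction."""

    asym_logistic: float
    asym_weibull4: float
    min_reads: float
    max_reads: float
    min_genes: float
    max_genes: float
    logistic_ok: bool = True
    weibull_ok: bool = True

    def to_row(self) -> dict:
        return {
            "asym_logistic": self.asym_logistic,
            "asym_weibull4": self.asym_weibull4,
            "min_reads": self.min_reads,
            "max_reads": self.max_reads,
            "min_genes": self.min_genes,
            "max_genes": self.max_genes,
            "logistic_ok": self.logistic_ok,
            "weibull_ok": self.weibull_ok,
        }


@dataclass
class TrainedPredictor:
    """A fitted regressor plus its bagging ensemble for intervals.

    ``oob_residuals`` are out-of-bag residuals of the ensemble on the
    training rows; prediction intervals combine the ensemble's spread with
    these residuals so they reflect irreducible per-curve noise as well as
    model variance.
    """

    kind: str
    target: str
    feature_names: tuple[str, ...]
    primary: object
    bag: list
    train_seed: int
    oob_residuals: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.primary.predict(X[list(self.feature_names)].to_numpy(dtype=float)))


@dataclass(frozen=True)
class PredictionResult:
    target: str
    point: float
    interval: tuple[float, float]
    level: float


@dataclass(frozen=True)
class ValidationReport:
    """Held-out metrics over repeated random train/test splits."""

    per_resample: list
    summary: dict
    n_resamples: int
    split_fraction: float


def truncate_curve(
    curve: RarefactionCurve, fraction: float, mode: str = "by_knots"
) -> RarefactionCurve:
    """Keep the initial part of a curve.

    ``by_knots`` keeps the first ceil(fraction * n_knots) knots (the "first
    20 points of a 100-knot curve" convention); ``by_depth`` keeps knots with
    depth <= fraction * max depth.
    """
    if not (0.0 < fraction <= 1.0):
        raise ParameterError("fraction must be in (0, 1]")
    if mode == "by_knots":
        keep = math.ceil(fraction * curve.n_knots)
        mask = np.arange(curve.n_knots) < keep
    elif mode == "by_depth":
        mask = curve.depths <= fraction * curve.depths.max()
    else:
        raise ParameterError(f"unknown truncation mode {mode!r}")
    if int(mask.sum()) < 5:
        raise DataValidationError(
            f"truncation leaves {int(mask.sum())} knots; at least 5 are required"
        )
    return curve.subset(mask)


def extract_features(truncated: RarefactionCurve) -> FeatureVector:
    """Fit logistic and Weibull asymptotes to a truncated curve and read off
    its depth/richness ranges.

    A failed asymptote fit falls back to the two-parameter Weibull asymptote
    with the corresponding ``*_ok`` flag cleared; if every fit fails the
    asymptotes are NaN (flagged) so callers can drop or impute the row.
    """
    if truncated.n_knots < 5:
        raise ParameterError("feature extraction needs >= 5 knots")

    def _asymptote(family: str) -> tuple[float, bool]:
        try:
            fit = fit_growth(truncated, family)
        except (ParameterError, NumericalError):
            fit = None
        if fit is not None and fit.converged and np.isfinite(fit.asymptote):
            return fit.asymptote, True
        try:
            fb = fit_growth(truncated, "weibull2")
            if fb.converged and np.isfinite(fb.asymptote):
                return fb.asymptote, False
        except (ParameterError, NumericalError):
            pass
        return float("nan"), False

    asym_log, log_ok = _asymptote("logistic3")
    asym_wei, wei_ok = _asymptote("weibull4")
    return FeatureVector(
        asym_logistic=asym_log,
        asym_weibull4=asym_wei,
        min_reads=float(truncated.depths.min()),
        max_reads=float(truncated.depths.max()),
        min_genes=float(truncated.richness.min()),
        max_genes=float(truncated.richness.max()),
        logistic_ok=log_ok,
        weibull_ok=wei_ok,
    )


def build_training_table(
    matrices: Sequence,
    n_knots: int = 100,
    fraction: float = 0.2,
    mode: str = "by_knots",
    candidates: Sequence[str] = ("weibull4", "weibull2"),
) -> pd.DataFrame:
    """Corpus -> one row per matrix with truncated-curve features, full-curve
    effort targets and (when available) the generating truth.

    Rows where the full-curve fit or the feature fits fail carry NaNs; the
    trainer drops them.  Targets are the full-curve estimates (asymptote and
    coverage depths), matching the design in which the a-priori predictor
    recovers what the complete curve would have said.
    """
    rows: list[dict] = []
    for mat in matrices:
        row: dict = {}
        meta = getattr(mat, "meta", None) or {}
        row["true_k"] = meta.get("k", np.nan)
        row["concentration"] = meta.get("concentration", np.nan)
        try:
            ab = pool_samples(mat)
            curve = build_curve(ab, n_knots=n_knots)
            row["n_observed"] = curve.N_ref
            fit = select_model(curve, candidates)
            row["max_genes"] = fit.asymptote
            for q in DEFAULT_COVER_FRACTIONS:
                row[f"reads_q{int(round(q * 100))}"] = invert_growth(fit, q)
            eff = effort_percent(fit, curve.N_ref)
            row["effort_percent"] = np.nan if eff is None else eff
            feats = extract_features(truncate_curve(curve, fraction, mode=mode))
            row.update(feats.to_row())
        except (DataValidationError, ParameterError, NumericalError):
            pass
        rows.append(row)
    return pd.DataFrame(rows)


def _stepwise_select(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> list[str]:
    """Backward elimination on AIC over ordinary least squares."""

    def aic(cols: list[int]) -> float:
        A = np.column_stack([np.ones(len(y))] + [X[:, c] for c in cols])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((y - A @ coef) ** 2))
        n = len(y)
        rss = max(rss, 1e-300)
        return n * math.log(rss / n) + 2 * (len(cols) + 1)

    current = list(range(X.shape[1]))
    best = aic(current)
    improved = True
    while improved and len(current) > 1:
        improved = False
        for c in list(current):
            trial = [i for i in current if i != c]
            score = aic(trial)
            if score < best - 1e-9:
                best, current, improved = score, trial, True
                break
    return [names[i] for i in current]


def _make_estimator(kind: str, seed: int):
    if kind == "linear":
        return LinearRegression()
    if kind == "kernel":
        return TransformedTargetRegressor(
            regressor=make_pipeline(StandardScaler(), SVR(kernel="rbf", C=10.0)),
            transformer=StandardScaler(),
        )
    if kind == "boosting":
        return XGBRegressor(
            n_estimators=500,
            max_depth=4,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise ParameterError(f"unknown predictor kind {kind!r}; expected one of {KINDS}")


def _clean_xy(
    features: pd.DataFrame, targets: Sequence[float], feature_names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    X = features[list(feature_names)].to_numpy(dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.shape[0] != y.size:
        raise ParameterError("feature table and target vector lengths differ")
    if np.any(~np.isfinite(y)):
        raise DataValidationError("targets contain missing values")
    if np.any(~np.isfinite(X)):
        raise DataValidationError("feature table contains missing values")
    return X, y


def train_predictor(
    features: pd.DataFrame,
    targets: Sequence[float],
    kind: str,
    seed: int = 0,
    bag_size: int = 100,
    feature_names: Sequence[str] = MODEL1_FEATURES,
    target: str = "max_genes",
) -> TrainedPredictor:
    """Fit a regressor of one effort quantity plus its bagging ensemble.

    The linear kind performs stepwise (backward-AIC) feature selection before
    the final fit; the bag refits the chosen model on ``bag_size`` bootstrap
    row resamples with per-member derived seeds.
    """
    X, y = _clean_xy(features, targets, feature_names)
    if X.shape[0] < 10:
        raise ParameterError("training needs at least 10 rows")
    if bag_size < 1:
        raise ParameterError("bag_size must be >= 1")
    if float(np.ptp(y)) == 0.0:
        raise DataValidationError("constant target; regression is degenerate")
    names = list(feature_names)
    if kind == "linear":
        names = _stepwise_select(X, y, names)
        X = features[names].to_numpy(dtype=float)
    primary = _make_estimator(kind, seed)
    primary.fit(X, y)
    rng = np.random.default_rng(seed)
    bag = []
    n = X.shape[0]
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    for b in range(bag_size):
        idx = rng.integers(0, n, size=n)
        member = _make_estimator(kind, seed + 1 + b)
        member.fit(X[idx], y[idx])
        bag.append(member)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size:
            oob_sum[oob] += np.asarray(member.predict(X[oob]))
            oob_cnt[oob] += 1
    has_oob = oob_cnt > 0
    if np.any(has_oob):
        oob_residuals = y[has_oob] - oob_sum[has_oob] / oob_cnt[has_oob]
    else:  # bag too small to leave rows out; fall back to training residuals
        oob_residuals = y - np.asarray(primary.predict(X))
    return TrainedPredictor(
        kind=kind,
        target=target,
        feature_names=tuple(names),
        primary=primary,
        bag=bag,
        train_seed=seed,
        oob_residuals=np.asarray(oob_residuals, dtype=float),
    )


def _features_frame(features) -> pd.DataFrame:
    if isinstance(features, FeatureVector):
        return pd.DataFrame([features.to_row()])
    if isinstance(features, pd.Series):
        return features.to_frame().T
    return pd.DataFrame(features)


def predict_with_interval(
    model: TrainedPredictor, features, level: float = 0.95
) -> PredictionResult:
    """Point prediction from the primary model; interval from the bag.

    The interval is read off the percentiles of the ensemble's predictions
    convolved with the out-of-bag residual pool (every member prediction
    plus every OOB residual), so it widens both with model variance and
    with the irreducible noise of the target.  It always contains both the
    point prediction and the bag median.
    """
    if not (0.0 < level < 1.0):
        raise ParameterError("level must be in (0, 1)")
    frame = _features_frame(features)
    missing = [
        n
        for n in model.feature_names
        if n not in frame.columns or not np.all(np.isfinite(frame[n].to_numpy(dtype=float)))
    ]
    if missing:
        raise DataValidationError(f"missing features: {', '.join(missing)}")
    X = frame[list(model.feature_names)].to_numpy(dtype=float)
    point = float(np.asarray(model.primary.predict(X))[0])
    bag_preds = np.array([float(np.asarray(m.predict(X))[0]) for m in model.bag])
    resid = np.asarray(model.oob_residuals, dtype=float)
    vals = (bag_preds[:, None] + resid[None, :]).ravel()
    lo_p, hi_p = 100 * (0.5 - level / 2.0), 100 * (0.5 + level / 2.0)
    lo, hi = np.percentile(vals, [lo_p, hi_p])
    med = float(np.median(bag_preds))
    lo = min(float(lo), point, med)
    hi = max(float(hi), point, med)
    return PredictionResult(
        target=model.target, point=point, interval=(lo, hi), level=level
    )


def regression_metrics(
    y: Sequence[float], yhat: Sequence[float]
) -> tuple[float | None, float, float]:
    """(R^2, RMSE, MAE) between observed and predicted vectors.

    R^2 = 1 - SSres/SStot (None when y has zero variance); RMSE and MAE are
    in the units of the target.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ParameterError("vectors must have equal length >= 2")
    resid = yhat - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if sstot == 0.0 else 1.0 - float(np.sum(resid**2)) / sstot
    return r2, rmse, mae


def _band(values: np.ndarray, level: float) -> tuple[float, float]:
    """Normal-approximation confidence band for the mean of the resample
    distribution (degenerate for a single resample)."""
    mean = float(values.mean())
    if values.size < 2:
        return (mean, mean)
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    half = z * float(values.std(ddof=1)) / math.sqrt(values.size)
    return (mean - half, mean + half)


def cross_validate(
    features: pd.DataFrame,
    targets: Sequence[float],
    kind: str,
    n_resamples: int = 300,
    split: float = 0.7,
    seed: int = 0,
    feature_names: Sequence[str] = MODEL1_FEATURES,
) -> ValidationReport:
    """Repeated random 70/30 validation: fit on the training split, score
    (R^2, RMSE, MAE) on the held-out split, summarize across resamples."""
    X, y = _clean_xy(features, targets, feature_names)
    n = X.shape[0]
    if n < 20:
        raise ParameterError("cross-validation needs at least 20 rows")
    n_train = int(round(split * n))
    if n - n_train < 3:
        raise ParameterError("split leaves fewer than 3 test rows")
    frame = features[list(feature_names)].astype(float)
    rng = np.random.default_rng(seed)
    per_resample: list[tuple[float, float, float]] = []
    for _ in range(n_resamples):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = _make_estimator(kind, int(rng.integers(0, 2**31 - 1)))
        Xtr = frame.iloc[tr].to_numpy(dtype=float)
        if kind == "linear":
            sel = _stepwise_select(Xtr, y[tr], list(feature_names))
            model.fit(frame.iloc[tr][sel].to_numpy(dtype=float), y[tr])
            yhat = model.predict(frame.iloc[te][sel].to_numpy(dtype=float))
        else:
            model.fit(Xtr, y[tr])
            yhat = model.predict(frame.iloc[te].to_numpy(dtype=float))
        r2, rmse, mae = regression_metrics(y[te], yhat)
        per_resample.append((np.nan if r2 is None else r2, rmse, mae))
    arr = np.asarray(per_resample, dtype=float)
    summary: dict = {}
    for i, name in enumerate(("r2", "rmse", "mae")):
        vals = arr[:, i]
        vals = vals[np.isfinite(vals)]
        summary[name] = {
            "mean": float(vals.mean()),
            "band95": _band(vals, 0.95),
            "band99": _band(vals, 0.99),
        }
    return ValidationReport(
        per_resample=per_resample,
        summary=summary,
        n_resamples=n_resamples,
        split_fraction=split,
    )


def predict_from_partial(
    depths: Sequence[int],
    richness: Sequence[float],
    models: Mapping[str, TrainedPredictor],
    level: float = 0.95,
) -> dict:
    """Predict effort quantities from an incomplete depth-richness vector.

    Builds a curve from the vector, extracts the a-priori features, and
    applies each trained predictor; the direct Weibull-only estimate on the
    partial curve is included for comparison.
    """
    d = np.asarray(list(depths))
    if d.size < 5:
        raise ParameterError("partial vectors need at least 5 points")
    curve = curve_from_vector(depths, richness)
    feats = extract_features(curve)
    predictions = {
        target: predict_with_interval(model, feats, level=level)
        for target, model in models.items()
    }
    direct: dict | None
    try:
        est = estimate_effort(curve, level=level, compute_ci=False)
        direct = {
            "max_genes": est.a_hat,
            **{f"reads_q{int(round(q * 100))}": est.x_q[q] for q in DEFAULT_COVER_FRACTIONS},
            "family": est.fit.family,
        }
    except (NumericalError, ParameterError):
        direct = None
    return {"features": feats, "predictions": predictions, "direct_weibull": direct}
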