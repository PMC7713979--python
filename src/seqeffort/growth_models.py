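"""Nonlinear growth models for rarefaction-curve extrapolation.

Three saturating families are supported, all parameterized so the upper
asymptote ``a`` — interpreted as the maximum number of expressible genes —
is a direct parameter:

* ``weibull4``:  W(x) = a - b * exp(-c * x^m), with 0 <= b <= a so the curve
  starts at W(0) = a - b >= 0.  This is the flexible sigmoid used as the
  primary extrapolation model.
* ``weibull2``:  W(x) = a * (1 - exp(-c * x)), the asymptotic-regression-
  through-the-origin special case (b = a, m = 1).
* ``logistic3``: L(x) = a / (1 + exp((x0 - x) / s)), kept because its
  asymptote is a useful predictor feature for partial curves.

Fitting is nonlinear least squares (Levenberg-Marquardt) started from a
coarse brute-force grid search; positivity and ordering constraints are
enforced by fitting in a log / logit internal parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .errors import NumericalError, ParameterError
from .rarefaction import KIND_EXTRAPOLATED, RarefactionCurve

__all__ = [
    "FAMILIES",
    "N_PARAMS",
    "GrowthFit",
    "FitMetrics",
    "eval_weibull4",
    "eval_weibull2",
    "eval_logistic3",
    "eval_family",
    "grid_init",
    "fit_growth",
    "fit_metrics",
    "accuracy_metrics",
    "select_model",
]

FAMILIES = ("weibull4", "weibull2", "logistic3")
N_PARAMS = {"weibull4": 4, "weibull2": 2, "logistic3": 3}
PARAM_NAMES = {
    "weibull4": ("a", "b", "c", "m"),
    "weibull2": ("a", "c"),
    "logistic3": ("a", "x0", "s"),
}


def eval_weibull4(x, a: float, b: float, c: float, m: float):
    """Four-parameter Weibull growth curve W(x) = a - b e^{-c x^m}."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):  # x^m may overflow to inf; exp(-inf) = 0 is the right limit
        return a - b * np.exp(-c * np.power(x, m))


def eval_weibull2(x, a: float, c: float):
    """Asymptotic regression through the origin, W(x) = a (1 - e^{-c x}).

    Implemented as the b = a, m = 1 special case of :func:`eval_weibull4` so
    the two agree bitwise.
    """
    return eval_weibull4(x, a, a, c, 1.0)


def eval_logistic3(x, a: float, x0: float, s: float):
    """Three-parameter logistic L(x) = a / (1 + e^{(x0 - x)/s})."""
    x = np.asarray(x, dtype=float)
    return a * expit((x - x0) / s)


def eval_family(family: str, x, params: Mapping[str, float]):
    if family == "weibull4":
        return eval_weibull4(x, params["a"], params["b"], params["c"], params["m"])
    if family == "weibull2":
        return eval_weibull2(x, params["a"], params["c"])
    if family == "logistic3":
        return eval_logistic3(x, params["a"], params["x0"], params["s"])
    raise ParameterError(f"unknown growth family {family!r}")


@dataclass(frozen=True)
class GrowthFit:
    """A fitted growth model with parameter covariance and diagnostics."""

    family: str
    params: dict
    param_cov: np.ndarray | None
    converged: bool
    n_points: int
    warnings: tuple[str, ...] = ()
    rss: float = float("nan")

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.family]

    @property
    def asymptote(self) -> float:
        return float(self.params["a"])

    def predict(self, x):
        return eval_family(self.family, x, self.params)


@dataclass(frozen=True)
class FitMetrics:
    """Goodness-of-fit summary for a growth fit.

    ``pseudo_r2`` is Efron's pseudo r-squared (1 - SSres/SStot; can be
    negative, None when the observations have zero variance);
    ``minmax_accuracy`` averages min(obs, pred)/max(obs, pred) over points
    (1 for a perfect fit); ``rmse`` is in gene units.
    """

    pseudo_r2: float | None
    minmax_accuracy: float
    rmse: float


def accuracy_metrics(obs: Sequence[float], pred: Sequence[float]) -> FitMetrics:
    y = np.asarray(obs, dtype=float)
    yhat = np.asarray(pred, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise ParameterError("observed and predicted vectors must match and be nonempty")
    resid = y - yhat
    sstot = float(np.sum((y - y.mean()) ** 2))
    pseudo_r2 = None if sstot == 0.0 else 1.0 - float(np.sum(resid**2)) / sstot
    lo = np.minimum(y, yhat)
    hi = np.maximum(y, yhat)
    ratios = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0), np.where(lo == hi, 1.0, 0.0))
    return FitMetrics(
        pseudo_r2=pseudo_r2,
        minmax_accuracy=float(ratios.mean()),
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


def _fit_xy(curve: RarefactionCurve, use_extrapolated: bool) -> tuple[np.ndarray, np.ndarray]:
    if use_extrapolated:
        mask = np.ones(curve.n_knots, dtype=bool)
    else:
        mask = np.array([k != KIND_EXTRAPOLATED for k in curve.kinds])
    return curve.depths[mask].astype(float), curve.richness[mask]


def grid_init(
    curve: RarefactionCurve,
    family: str,
    use_extrapolated: bool = False,
    n_grid: int = 20,
) -> dict:
    """Brute-force starting values: the coarse-grid point minimizing the RSS.

    The asymptote axis spans [max richness, 10x max richness] (log-spaced);
    rate axes span six decades bracketing the reciprocal of the deepest knot;
    the Weibull shape m is screened over {0.5, 1, 2, 4} with b tied to a so
    that W(0) matches the first knot.
    """
    if family not in FAMILIES:
        raise ParameterError(f"unknown growth family {family!r}")
    x, y = _fit_xy(curve, use_extrapolated)
    if x.size < 5:
        raise ParameterError("grid initialization needs >= 5 knots")
    ymax = float(y.max())
    y0 = float(y[0])
    xmax = float(x.max())
    xmin = float(x.min())
    if ymax <= 0:
        raise ParameterError("degenerate curve: nonpositive richness")
    a_grid = np.geomspace(ymax, 10.0 * ymax, n_grid)

    best: tuple[float, dict] | None = None

    def consider(params: dict) -> None:
        nonlocal best
        pred = eval_family(family, x, params)
        rss = float(np.sum((y - pred) ** 2))
        if best is None or rss < best[0]:
            best = (rss, params)

    if family == "weibull2":
        for a in a_grid:
            for c in np.geomspace(1e-3, 1e3, n_grid) / xmax:
                consider({"a": a, "c": c})
    elif family == "weibull4":
        for m in (0.5, 1.0, 2.0, 4.0):
            c_grid = np.geomspace(1e-3, 1e3, n_grid) / xmax**m
            for a in a_grid:
                b = float(np.clip(a - y0, 0.0, a))
                for c in c_grid:
                    consider({"a": a, "b": b, "c": c, "m": m})
    else:  # logistic3
        for a in a_grid:
            for x0 in np.linspace(xmin, 2.0 * xmax, 10):
                for s in np.geomspace(xmax / 1000.0, xmax, 10):
                    consider({"a": a, "x0": x0, "s": s})
    assert best is not None
    return best[1]


def _to_internal(family: str, params: Mapping[str, float]) -> np.ndarray:
    if family == "weibull4":
        r = np.clip(params["b"] / params["a"], 1e-9, 1.0 - 1e-12)
        return np.array(
            [np.log(params["a"]), logit(r), np.log(params["c"]), np.log(params["m"])]
        )
    if family == "weibull2":
        return np.array([np.log(params["a"]), np.log(params["c"])])
    return np.array([np.log(params["a"]), params["x0"], np.log(params["s"])])


def _exp(v: float) -> float:
    # clip to avoid overflow while LM explores; 700 is near the float64 limit
    return float(np.exp(np.clip(v, -700.0, 700.0)))


def _from_internal(family: str, u: np.ndarray) -> dict:
    if family == "weibull4":
        a = _exp(u[0])
        return {"a": a, "b": a * float(expit(u[1])), "c": _exp(u[2]), "m": _exp(u[3])}
    if family == "weibull2":
        return {"a": _exp(u[0]), "c": _exp(u[1])}
    return {"a": _exp(u[0]), "x0": float(u[1]), "s": _exp(u[2])}


def _external_jacobian(family: str, x: np.ndarray, params: dict) -> np.ndarray:
    """Finite-difference Jacobian of the model w.r.t. the natural parameters."""
    names = PARAM_NAMES[family]
    p0 = np.array([params[n] for n in names], dtype=float)
    J = np.empty((x.size, p0.size))
    for j in range(p0.size):
        h = 1e-6 * max(abs(p0[j]), 1e-12)
        up, dn = p0.copy(), p0.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (
            eval_family(family, x, dict(zip(names, up)))
            - eval_family(family, x, dict(zip(names, dn)))
        ) / (2 * h)
    return J


def fit_growth(
    curve: RarefactionCurve,
    family: str,
    init: Mapping[str, float] | None = None,
    use_extrapolated: bool = False,
    max_evals: int = 10_000,
    tol: float = 1e-10,
) -> GrowthFit:
    """Levenberg-Marquardt least squares on the curve knots.

    Positivity (and b <= a for the four-parameter Weibull) is enforced by
    optimizing log / logit transformed parameters.  A stalled optimizer
    yields ``converged=False`` rather than an exception; an asymptote below
    the maximum observed richness is flagged as a warning, not an error.
    """
    if family not in FAMILIES:
        raise ParameterError(f"unknown growth family {family!r}")
    x, y = _fit_xy(curve, use_extrapolated)
    n_par = N_PARAMS[family]
    if x.size < max(5, n_par + 1):
        raise ParameterError(
            f"{family} needs at least {max(5, n_par + 1)} knots, got {x.size}"
        )
    if init is None:
        init = grid_init(curve, family, use_extrapolated=use_extrapolated)
    u0 = _to_internal(family, init)

    def resid(u: np.ndarray) -> np.ndarray:
        return eval_family(family, x, _from_internal(family, u)) - y

    try:
        res = least_squares(
            resid, u0, method="lm", max_nfev=max_evals, xtol=tol, ftol=tol, gtol=tol
        )
    except Exception as exc:  # pragma: no cover - defensive
        return GrowthFit(family, dict(init), None, False, int(x.size), (str(exc),))

    params = _from_internal(family, res.x)
    converged = bool(res.success) and all(np.isfinite(v) for v in params.values())
    warnings_: list[str] = []
    rss = float(np.sum(res.fun**2))
    cov = None
    if converged:
        if params["a"] < float(y.max()) * (1 - 1e-9):
            warnings_.append("fitted asymptote below the maximum observed richness")
        dof = x.size - n_par
        if dof > 0:
            J = _external_jacobian(family, x, params)
            # column-scale before inverting: parameter magnitudes differ by
            # many orders (a ~ 1e5, c ~ 1e-6), and an unscaled pseudo-inverse
            # truncates the well-determined directions
            norms = np.linalg.norm(J, axis=0)
            norms[norms == 0] = 1.0
            Js = J / norms
            s2 = rss / dof
            try:
                inv = np.linalg.pinv(Js.T @ Js)
                cov = s2 * (inv / np.outer(norms, norms))
                cov = (cov + cov.T) / 2.0
            except np.linalg.LinAlgError:
                warnings_.append("singular Jacobian; covariance unavailable")
    return GrowthFit(
        family=family,
        params=params,
        param_cov=cov,
        converged=converged,
        n_points=int(x.size),
        warnings=tuple(warnings_),
        rss=rss,
    )


def fit_metrics(
    fit: GrowthFit, curve: RarefactionCurve, use_extrapolated: bool = False
) -> FitMetrics:
    """Efron's pseudo r-squared, min-max accuracy and RMSE on the curve knots."""
    x, y = _fit_xy(curve, use_extrapolated)
    return accuracy_metrics(y, fit.predict(x))


def select_model(
    curve: RarefactionCurve,
    candidates: Sequence[str] = ("weibull4", "weibull2"),
    use_extrapolated: bool = False,
    **fit_kwargs,
) -> GrowthFit:
    """Fit every candidate family and return the best by pseudo r-squared.

    Non-converged candidates are excluded; score ties (within 1e-12) break
    toward the family with fewer parameters.
    """
    if len(candidates) < 1:
        raise ParameterError("at least one candidate family is required")
    fits: list[tuple[float, GrowthFit]] = []
    diagnostics: dict[str, str] = {}
    for family in candidates:
        try:
            fit = fit_growth(curve, family, use_extrapolated=use_extrapolated, **fit_kwargs)
        except ParameterError as exc:
            diagnostics[family] = f"precondition: {exc}"
            continue
        if not fit.converged:
            diagnostics[family] = "did not converge"
            continue
        metrics = fit_metrics(fit, curve, use_extrapolated=use_extrapolated)
        score = metrics.pseudo_r2 if metrics.pseudo_r2 is not None else -np.inf
        fits.append((score, fit))
    if not fits:
        raise NumericalError(f"all growth-model fits failed: {diagnostics}")
    best_score = max(score for score, _ in fits)
    tied = [fit for score, fit in fits if score >= best_score - 1e-12]
    tied.sort(key=lambda f: N_PARAMS[f.family])
    return tied[0]
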