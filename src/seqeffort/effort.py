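"""Sequencing-effort estimation from a fitted growth model.

Given a growth fit with asymptote ``a`` (maximum number of expressible
genes), the closed-form inversions below give the read depth x_q at which
the model reaches a fraction q of the asymptote.  The sampling effort is the
depth needed to cover 99% of the asymptote expressed as a percentage of the
reads actually sequenced, capped at 100: deeply over-sampled libraries score
a few percent, unsaturated ones hit the cap.  Curves are classified into the
four canonical typologies (over-sampled, correct, under-sampled, very
under-sampled) by where the observed depth falls relative to x_90 and x_99.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .errors import NumericalError, ParameterError
from .growth_models import GrowthFit, PARAM_NAMES, select_model
from .rarefaction import RarefactionCurve

__all__ = [
    "EffortEstimate",
    "invert_growth",
    "asymptote_band",
    "effort_percent",
    "classify_curve",
    "estimate_effort",
    "DEFAULT_COVER_FRACTIONS",
]

DEFAULT_COVER_FRACTIONS = (0.90, 0.95, 0.99)

LABEL_OVER = "over_sampled"
LABEL_CORRECT = "correct"
LABEL_UNDER = "under_sampled"
LABEL_VERY_UNDER = "very_under_sampled"


@dataclass(frozen=True)
class EffortEstimate:
    """Asymptote, coverage depths, effort percentage and curve typology."""

    a_hat: float
    a_ci: tuple[float, float] | None
    x_q: dict
    x_q_ci: dict | None
    n_observed: int
    effort_percent: float
    label: str
    fit: GrowthFit
    level: float = 0.95
    warnings: tuple[str, ...] = ()


def _invert_params(family: str, params: Mapping[str, float], q: float) -> float:
    a = params["a"]
    if family == "weibull2":
        return -np.log1p(-q) / params["c"]
    if family == "weibull4":
        b, c, m = params["b"], params["c"], params["m"]
        if b <= a * (1.0 - q):  # curve starts at or above q*a
            return 0.0
        return float((np.log(b / (a * (1.0 - q))) / c) ** (1.0 / m))
    if family == "logistic3":
        x = params["x0"] - params["s"] * np.log(1.0 / q - 1.0)
        return float(max(x, 0.0))
    raise ParameterError(f"unknown growth family {family!r}")


def invert_growth(fit: GrowthFit, q: float) -> float:
    """Depth at which the fitted model covers a fraction q of its asymptote.

    Returns 0 when the model already starts at or above q * a.  The round
    trip fit.predict(invert_growth(fit, q)) == q * a holds to 1e-9 relative
    whenever the returned depth is positive.
    """
    if not (0.0 < q < 1.0):
        raise ParameterError("coverage fraction q must be in (0, 1)")
    if not fit.converged:
        raise NumericalError("cannot invert a non-converged fit")
    return _invert_params(fit.family, fit.params, q)


def _sample_params(fit: GrowthFit, n: int, rng: np.random.Generator) -> list[dict]:
    names = PARAM_NAMES[fit.family]
    mean = np.array([fit.params[k] for k in names])
    draws = rng.multivariate_normal(mean, fit.param_cov, size=4 * n, check_valid="ignore", method="svd")
    out: list[dict] = []
    for row in draws:
        p = dict(zip(names, row))
        if p["a"] <= 0:
            continue
        if fit.family == "weibull4" and not (0.0 <= p["b"] <= p["a"] and p["c"] > 0 and p["m"] > 0):
            continue
        if fit.family == "weibull2" and p["c"] <= 0:
            continue
        if fit.family == "logistic3" and p["s"] <= 0:
            continue
        out.append(p)
        if len(out) == n:
            break
    return out


def asymptote_band(
    fit: GrowthFit,
    level: float = 0.95,
    qs: Sequence[float] = DEFAULT_COVER_FRACTIONS,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Confidence intervals for the asymptote and each coverage depth.

    The asymptote interval is the delta-method (Wald) interval from the
    parameter covariance.  The coverage-depth intervals come from a
    parametric bootstrap: parameter vectors are drawn from the asymptotic
    normal of the estimates (invalid draws rejected) and the closed-form
    inversion is applied to each.  Returns a mapping with keys ``a``,
    ``x_q`` (q -> (low, high)) and ``warnings``.
    """
    if not (0.0 < level < 1.0):
        raise ParameterError("confidence level must be in (0, 1)")
    if not fit.converged:
        raise NumericalError("confidence band requires a converged fit")
    warnings_: list[str] = []
    a = fit.asymptote
    if fit.param_cov is None or not np.all(np.isfinite(fit.param_cov)):
        warnings_.append("covariance unavailable; band reported as unbounded")
        return {
            "a": (-np.inf, np.inf),
            "x_q": {q: (0.0, np.inf) for q in qs},
            "warnings": tuple(warnings_),
        }
    z = norm.ppf(0.5 + level / 2.0)
    se_a = float(np.sqrt(max(fit.param_cov[0, 0], 0.0)))
    band = {"a": (a - z * se_a, a + z * se_a)}
    rng = np.random.default_rng(seed)
    draws = _sample_params(fit, n_boot, rng)
    x_q_band: dict = {}
    lo_p, hi_p = 100 * (0.5 - level / 2.0), 100 * (0.5 + level / 2.0)
    for q in qs:
        point = _invert_params(fit.family, fit.params, q)
        vals = np.array([_invert_params(fit.family, p, q) for p in draws])
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            warnings_.append(f"too few valid bootstrap draws for x_{q}")
            x_q_band[q] = (point, point)
            continue
        lo, hi = np.percentile(vals, [lo_p, hi_p])
        x_q_band[q] = (float(min(lo, point)), float(max(hi, point)))
    band["x_q"] = x_q_band
    band["warnings"] = tuple(warnings_)
    return band


def effort_percent(fit: GrowthFit, n_observed: int, q: float = 0.99) -> float | None:
    """Reads needed to cover a fraction q of the asymptote, as a percentage
    of the reads actually sequenced, capped at 100.

    Returns None for a non-converged fit (the effort is then undefined).
    """
    if n_observed < 1:
        raise ParameterError("n_observed must be >= 1")
    if not fit.converged:
        return None
    x_q = invert_growth(fit, q)
    return float(min(100.0, 100.0 * x_q / n_observed))


def _classify(x90: float, x99: float, n_observed: int, over_factor: float = 0.1) -> str:
    if x99 <= over_factor * n_observed:
        return LABEL_OVER
    if x99 <= n_observed:
        return LABEL_CORRECT
    if x90 <= n_observed:
        return LABEL_UNDER
    return LABEL_VERY_UNDER


def classify_curve(est: EffortEstimate, over_factor: float = 0.1) -> str:
    """Assign the curve typology from the coverage depths and observed reads.

    ``over_sampled`` when x_99 <= over_factor * n; ``correct`` when x_99 <= n;
    ``under_sampled`` when only x_90 <= n; ``very_under_sampled`` otherwise.
    The thresholds are conventions, exposed for tuning.
    """
    return _classify(est.x_q[0.90], est.x_q[0.99], est.n_observed, over_factor)


def estimate_effort(
    curve: RarefactionCurve,
    n_observed: int | None = None,
    level: float = 0.95,
    candidates: Sequence[str] = ("weibull4", "weibull2"),
    q_effort: float = 0.99,
    compute_ci: bool = True,
    use_extrapolated: bool = False,
    seed: int = 0,
) -> EffortEstimate:
    """End-to-end effort estimate for one rarefaction curve.

    Selects the best growth family, inverts it at 90/95/99% coverage,
    attaches confidence intervals and classifies the curve.  Deterministic
    for a given curve (the bootstrap seed defaults to a constant).
    """
    if n_observed is None:
        n_observed = curve.N_ref
    if curve.n_knots < 5:
        raise ParameterError("effort estimation needs a curve with at least 5 knots")
    fit = select_model(curve, candidates, use_extrapolated=use_extrapolated)
    x_q = {q: invert_growth(fit, q) for q in DEFAULT_COVER_FRACTIONS}
    if compute_ci:
        band = asymptote_band(fit, level=level, seed=seed)
        a_ci = band["a"]
        x_q_ci = band["x_q"]
        warnings_ = tuple(fit.warnings) + tuple(band["warnings"])
    else:
        a_ci = None
        x_q_ci = None
        warnings_ = tuple(fit.warnings)
    eff = effort_percent(fit, n_observed, q=q_effort)
    assert eff is not None  # select_model only returns converged fits
    return EffortEstimate(
        a_hat=fit.asymptote,
        a_ci=a_ci,
        x_q=x_q,
        x_q_ci=x_q_ci,
        n_observed=int(n_observed),
        effort_percent=eff,
        label=_classify(x_q[0.90], x_q[0.99], int(n_observed)),
        fit=fit,
        level=level,
        warnings=warnings_,
    )
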