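"""Sample-size-based rarefaction and extrapolation of gene richness.

Interpolation uses the classical hypergeometric expectation: the expected
number of distinct genes in a without-replacement subsample of m reads from a
pooled abundance vector with total N and per-gene counts x_i is

    S(m) = S_obs - sum_i C(N - x_i, m) / C(N, m).

Extrapolation beyond the observed depth is Chao1-based (Hill order q = 0):
the unseen-gene mass f0 is estimated from singletons f1 and doubletons f2,

    f0 = f1^2 / (2 f2)              if f2 > 0
    f0 = f1 (f1 - 1) / (2 (f2 + 1)) otherwise,

and expected richness m* reads beyond N is

    S(N + m*) = S_obs + f0 * [1 - (1 - f1 / (N f0 + f1))^{m*}].

Both estimators are evaluated in log-gamma space so that depths of 10^7
reads and beyond do not overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from scipy.special import gammaln

from .errors import DataValidationError, ParameterError

__all__ = [
    "AbundanceVector",
    "CurveKnot",
    "RarefactionCurve",
    "KIND_INTERPOLATED",
    "KIND_OBSERVED",
    "KIND_EXTRAPOLATED",
    "pool_samples",
    "rarefy_interpolate",
    "rarefy_extrapolate",
    "chao1_unseen",
    "build_curve",
    "curve_from_vector",
]

KIND_INTERPOLATED = "interpolated"
KIND_OBSERVED = "observed"
KIND_EXTRAPOLATED = "extrapolated"


@dataclass(frozen=True)
class AbundanceVector:
    """Pooled per-gene read counts (zero-count genes removed)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 1:
            raise DataValidationError("abundance vector must be 1-D and nonempty")
        if np.any(counts <= 0):
            raise DataValidationError("abundance counts must be strictly positive")
        object.__setattr__(self, "counts", counts)

    @property
    def N_total(self) -> int:
        return int(self.counts.sum())

    @property
    def S_obs(self) -> int:
        return int(self.counts.size)

    @property
    def f1(self) -> int:
        """Number of singleton genes (observed exactly once)."""
        return int(np.count_nonzero(self.counts == 1))

    @property
    def f2(self) -> int:
        """Number of doubleton genes (observed exactly twice)."""
        return int(np.count_nonzero(self.counts == 2))


class CurveKnot(NamedTuple):
    depth: int
    richness: float
    kind: str


@dataclass(frozen=True)
class RarefactionCurve:
    """A depth -> expected-richness curve with interpolation/extrapolation flags.

    ``N_ref`` is the reference (actually sequenced) depth; exactly one knot,
    at that depth, carries the ``observed`` kind when the curve was built from
    counts.  ``f1``/``f2`` are carried along for diagnostics; they are None
    for curves read from external depth-richness vectors.
    """

    depths: np.ndarray
    richness: np.ndarray
    kinds: tuple[str, ...]
    N_ref: int
    S_obs: float
    f1: int | None = None
    f2: int | None = None

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=np.int64)
        rich = np.asarray(self.richness, dtype=float)
        if depths.ndim != 1 or depths.size != rich.size or depths.size != len(self.kinds):
            raise DataValidationError("depths, richness and kinds must have equal lengths")
        if depths.size < 1 or depths[0] < 1:
            raise DataValidationError("depths must be positive")
        if np.any(np.diff(depths) <= 0):
            raise DataValidationError("depths must be strictly increasing")
        if not np.all(np.isfinite(rich)) or np.any(rich < 0):
            raise DataValidationError("richness must be finite and nonnegative")
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "richness", rich)
        object.__setattr__(self, "kinds", tuple(self.kinds))

    @property
    def n_knots(self) -> int:
        return int(self.depths.size)

    @property
    def knots(self) -> list[CurveKnot]:
        return [
            CurveKnot(int(d), float(r), k)
            for d, r, k in zip(self.depths, self.richness, self.kinds)
        ]

    def subset(self, mask: np.ndarray) -> "RarefactionCurve":
        mask = np.asarray(mask, dtype=bool)
        return RarefactionCurve(
            depths=self.depths[mask],
            richness=self.richness[mask],
            kinds=tuple(k for k, m in zip(self.kinds, mask) if m),
            N_ref=self.N_ref,
            S_obs=self.S_obs,
            f1=self.f1,
            f2=self.f2,
        )


def pool_samples(matrix) -> AbundanceVector:
    """Pool the sample columns of a count matrix into one abundance vector.

    Genes with zero total are dropped (they were never observed and carry no
    information for abundance-based rarefaction).
    """
    totals = np.asarray(matrix.counts).sum(axis=1)
    totals = totals[totals > 0]
    if totals.size == 0:
        raise DataValidationError("matrix has no observed reads; cannot rarefy")
    return AbundanceVector(counts=totals)


def _interp_many(ab: AbundanceVector, depths: np.ndarray) -> np.ndarray:
    """Vectorized hypergeometric rarefaction over integer depths <= N_total."""
    x = ab.counts.astype(float)
    N = float(ab.N_total)
    m = depths.astype(float)[:, None]  # (n_depths, 1)
    nx = N - x[None, :]  # (1, S_obs)
    # log C(N - x_i, m) - log C(N, m); terms with N - x_i < m vanish.
    with np.errstate(invalid="ignore"):
        logterm = (
            gammaln(nx + 1)
            - gammaln(nx - m + 1)
            - gammaln(N + 1)
            + gammaln(N - m + 1)
        )
    term = np.where(nx >= m, np.exp(logterm), 0.0)
    return ab.S_obs - term.sum(axis=1)


def rarefy_interpolate(ab: AbundanceVector, m: int) -> float:
    """Expected number of distinct genes in a size-m subsample (1 <= m <= N)."""
    m = int(m)
    if m < 1 or m > ab.N_total:
        raise ParameterError(f"subsample size m={m} outside [1, {ab.N_total}]")
    return float(_interp_many(ab, np.array([m]))[0])


def chao1_unseen(f1: int, f2: int) -> float:
    """Chao1 estimate of the number of unseen genes from singletons/doubletons."""
    if f2 > 0:
        return f1 * f1 / (2.0 * f2)
    return f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _extrap_many(ab: AbundanceVector, m_stars: np.ndarray) -> np.ndarray:
    f1, f2 = ab.f1, ab.f2
    S, N = ab.S_obs, ab.N_total
    f0 = chao1_unseen(f1, f2)
    if f1 == 0 or f0 == 0.0:
        return np.full(m_stars.shape, float(S))
    ratio = 1.0 - f1 / (N * f0 + f1)
    return S + f0 * (1.0 - np.power(ratio, m_stars.astype(float)))


def rarefy_extrapolate(ab: AbundanceVector, m_star: int) -> float:
    """Expected richness m_star reads beyond the observed depth N (Chao1-based)."""
    m_star = int(m_star)
    if m_star < 0:
        raise ParameterError("m_star must be >= 0")
    return float(_extrap_many(ab, np.array([m_star]))[0])


def build_curve(
    ab: AbundanceVector,
    n_knots: int = 100,
    endpoint: int | None = None,
) -> RarefactionCurve:
    """Build an n-knot rarefaction/extrapolation curve from 1 to ``endpoint``.

    Knots are spaced linearly in depth; the observed depth N_total is always
    one of them (flagged ``observed``).  The default endpoint doubles the
    observed depth, mirroring common extrapolation practice.
    """
    if n_knots < 5:
        raise ParameterError("n_knots must be >= 5 (downstream fitting needs >= 5 points)")
    N = ab.N_total
    if endpoint is None:
        endpoint = 2 * N
    if endpoint < N:
        raise ParameterError("endpoint must be >= the observed depth")
    depths = np.unique(np.round(np.linspace(1, endpoint, n_knots)).astype(np.int64))
    if N not in depths:
        depths[np.argmin(np.abs(depths - N))] = N
        depths = np.unique(depths)
    interp_mask = depths <= N
    richness = np.empty(depths.size, dtype=float)
    richness[interp_mask] = _interp_many(ab, depths[interp_mask])
    richness[~interp_mask] = _extrap_many(ab, depths[~interp_mask] - N)
    kinds = tuple(
        KIND_OBSERVED if d == N else (KIND_INTERPOLATED if d < N else KIND_EXTRAPOLATED)
        for d in depths
    )
    return RarefactionCurve(
        depths=depths,
        richness=richness,
        kinds=kinds,
        N_ref=N,
        S_obs=float(ab.S_obs),
        f1=ab.f1,
        f2=ab.f2,
    )


def curve_from_vector(
    depths: Iterable[int],
    richness: Iterable[float],
    kinds: Iterable[str] | None = None,
) -> RarefactionCurve:
    """Wrap an externally produced depth-richness vector as a curve.

    All knots are taken as empirical: the deepest point becomes the observed
    reference and earlier points are flagged interpolated, unless explicit
    kinds are given.  A locally decreasing richness is tolerated with a
    warning by nudging it up to the running maximum (empirical vectors may
    jitter); decreasing depth is an error.
    """
    d = np.asarray(list(depths), dtype=np.int64)
    r = np.asarray(list(richness), dtype=float)
    if d.size != r.size or d.size < 2:
        raise DataValidationError("depth and richness vectors must match and have >= 2 points")
    if np.any(np.diff(d) == 0):
        raise DataValidationError("duplicated depth value in curve vector")
    if np.any(np.diff(d) < 0):
        raise DataValidationError("depths must be strictly increasing")
    if np.any(np.diff(r) < 0):
        warnings.warn("richness decreases along the vector; nudging to running maximum")
        r = np.maximum.accumulate(r)
    if kinds is None:
        kinds = tuple(
            KIND_OBSERVED if i == d.size - 1 else KIND_INTERPOLATED for i in range(d.size)
        )
    else:
        kinds = tuple(kinds)
    if KIND_OBSERVED in kinds:
        n_ref = int(d[kinds.index(KIND_OBSERVED)])
    else:
        n_ref = int(d[-1])
    return RarefactionCurve(
        depths=d,
        richness=r,
        kinds=kinds,
        N_ref=n_ref,
        S_obs=float(r[-1]),
    )
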