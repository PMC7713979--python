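"""Monte-Carlo simulation of gene-by-sample count matrices.

A metatranscriptomic (or shotgun metagenomic) experiment, after mapping and
annotation, reduces to a sparse integer matrix with genes in rows and samples
in columns.  Each sample column is modelled as a multinomial draw of its
library size over the k genes, with the gene-probability vector drawn from a
Dirichlet prior (the multinomial's conjugate).  Sampling the probabilities
per column and then the counts reproduces the sparse, long-tailed
rank-abundance structure seen in real community expression matrices.

Corpora of such matrices, spanning over- to under-sampled regimes, are the
training material for the downstream effort predictors.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "CountMatrix",
    "SimulationConfig",
    "draw_theta",
    "posterior_alpha",
    "simulate_matrix",
    "simulate_corpus",
]


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CountMatrix:
    """A k-genes x n-samples nonnegative integer count matrix.

    Attributes
    ----------
    counts
        Integer array of shape (k, n); entry (i, j) is the number of reads of
        gene i observed in sample j.
    gene_ids, sample_ids
        Row and column labels.
    meta
        Optional provenance (true gene count, Dirichlet concentration, seed)
        attached by :func:`simulate_corpus` so recovery tests can compare
        estimates against the generating truth.
    """

    counts: np.ndarray
    gene_ids: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()
    meta: dict | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ParameterError("counts must be a 2-D matrix with k >= 1 genes and n >= 1 samples")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ParameterError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ParameterError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))
        k, n = counts.shape
        if not self.gene_ids:
            object.__setattr__(self, "gene_ids", tuple(f"gene_{i + 1}" for i in range(k)))
        if not self.sample_ids:
            object.__setattr__(self, "sample_ids", tuple(f"sample_{j + 1}" for j in range(n)))
        if len(self.gene_ids) != k or len(self.sample_ids) != n:
            raise ParameterError("label lengths must match the matrix shape")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def col_totals(self) -> np.ndarray:
        """Per-sample library sizes N.j."""
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        """Total reads N across all samples."""
        return int(self.counts.sum())


@dataclass(frozen=True)
class SimulationConfig:
    """Corpus-generation settings.

    ``k_range`` and ``reads_range`` are inclusive [min, max] bounds sampled
    log-uniformly per matrix (per sample for reads), so the corpus spans
    over- and under-sampled regimes roughly evenly in order of magnitude.
    ``alpha_spec`` is either a fixed symmetric Dirichlet concentration or a
    [low, high] range drawn log-uniformly per matrix.
    """

    k_range: tuple[int, int] = (267, 339_319)
    reads_range: tuple[int, int] = (550, 6_823_774)
    n_samples: int = 3
    alpha_spec: float | tuple[float, float] = (0.01, 1.0)
    n_matrices: int = 1
    seed: int = 0
    share_theta: bool = False

    def __post_init__(self) -> None:
        for name, rng_ in (("k_range", self.k_range), ("reads_range", self.reads_range)):
            lo, hi = rng_
            if lo < 1 or hi < lo:
                raise ParameterError(f"{name} must satisfy 1 <= min <= max, got {rng_}")
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        if self.n_matrices < 0:
            raise ParameterError("n_matrices must be >= 0")
        spec = self.alpha_spec
        vals = (spec,) if np.isscalar(spec) else tuple(spec)
        if any(v <= 0 for v in vals):
            raise ParameterError("Dirichlet concentration values must be > 0")
        if not np.isscalar(spec) and vals[1] < vals[0]:
            raise ParameterError("alpha_spec range must be increasing")


def draw_theta(alpha: Sequence[float] | np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Draw one gene-probability vector from Dirichlet(alpha).

    Returns a length-k simplex vector (components in [0, 1], summing to 1).
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or alpha.size < 1:
        raise ParameterError("alpha must be a 1-D vector")
    if np.any(alpha <= 0) or not np.all(np.isfinite(alpha)):
        raise ParameterError("all Dirichlet parameters must be finite and > 0")
    rng = _as_rng(seed)
    return rng.dirichlet(alpha)


def posterior_alpha(prior_alpha: Sequence[float], counts: Sequence[int]) -> np.ndarray:
    """Conjugate update: Dirichlet(alpha) prior + multinomial counts -> Dirichlet(alpha + counts)."""
    prior = np.asarray(prior_alpha, dtype=float)
    x = np.asarray(counts, dtype=float)
    if prior.shape != x.shape:
        raise ParameterError("prior and counts must have the same length")
    if np.any(prior <= 0):
        raise ParameterError("prior concentrations must be > 0")
    if np.any(x < 0):
        raise ParameterError("counts must be nonnegative")
    return prior + x


def simulate_matrix(
    k: int,
    library_sizes: Sequence[int],
    alpha: float | Sequence[float],
    seed: int | np.random.Generator,
    share_theta: bool = False,
    meta: dict | None = None,
) -> CountMatrix:
    """Simulate one count matrix: per column a multinomial of size N.j with
    theta drawn from Dirichlet(alpha).

    Parameters
    ----------
    k
        Number of genes (rows).
    library_sizes
        Per-sample read totals N.j; each column sum is exact by construction.
    alpha
        Symmetric concentration (scalar) or a length-k parameter vector.
    share_theta
        If True, one theta draw is shared by all replicate columns instead of
        drawing one per sample.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    sizes = np.asarray(library_sizes, dtype=np.int64)
    if sizes.ndim != 1 or sizes.size < 1 or np.any(sizes < 1):
        raise ParameterError("library_sizes must be positive integers")
    alpha_vec = np.full(k, float(alpha)) if np.isscalar(alpha) else np.asarray(alpha, dtype=float)
    if alpha_vec.shape != (k,):
        raise ParameterError(f"alpha length {alpha_vec.size} does not match k={k}")
    if np.any(alpha_vec <= 0):
        raise ParameterError("all Dirichlet parameters must be > 0")
    rng = _as_rng(seed)
    counts = np.empty((k, sizes.size), dtype=np.int64)
    theta = rng.dirichlet(alpha_vec) if share_theta else None
    for j, n_j in enumerate(sizes):
        th = theta if theta is not None else rng.dirichlet(alpha_vec)
        counts[:, j] = rng.multinomial(int(n_j), th)
    return CountMatrix(counts=counts, meta=meta)


def _log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    val = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    return int(min(max(round(val), lo), hi))


def simulate_corpus(config: SimulationConfig) -> list[CountMatrix]:
    """Generate a heterogeneous corpus of count matrices.

    Each matrix gets an independent substream spawned deterministically from
    ``config.seed``, so the corpus is bitwise reproducible and individual
    matrices can be regenerated in isolation.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_matrices)
    matrices: list[CountMatrix] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        k = _log_uniform_int(rng, *config.k_range)
        sizes = [_log_uniform_int(rng, *config.reads_range) for _ in range(config.n_samples)]
        if np.isscalar(config.alpha_spec):
            conc = float(config.alpha_spec)
        else:
            lo, hi = config.alpha_spec
            conc = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        meta = {
            "index": i,
            "k": k,
            "concentration": conc,
            "library_sizes": list(map(int, sizes)),
            "seed": config.seed,
        }
        matrices.append(
            simulate_matrix(k, sizes, conc, rng, share_theta=config.share_theta, meta=meta)
        )
    return matrices
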