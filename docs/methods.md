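# Methods

This note documents the models, numerical choices and known limitations of
`seqeffort`, in the order of the pipeline.

## Count-matrix model

A sample column X·j of the gene-by-sample matrix is multinomial,
X·j ~ MN(N·j; θ₁j, …, θkj), with the gene-probability simplex drawn from the
conjugate Dirichlet prior, θ·j ~ Dirichlet(α₁, …, αk). The package draws one
θ per sample column by default (replicates of the same community then differ
both by multinomial noise and by composition noise); `share_theta=True`
shares one θ across the replicate columns instead. Conjugacy is exposed via
`posterior_alpha` (Dirichlet(α) prior + counts x → Dirichlet(α + x)).

Corpus generation (`simulate_corpus`) draws, per matrix:

* gene count k log-uniform over `k_range` (default [267, 339319]);
* per-sample library size log-uniform over `reads_range`
  (default [550, 6823774]);
* a symmetric Dirichlet concentration log-uniform over `alpha_spec`
  (default [0.01, 1.0]).

Log-uniform draws spread the corpus evenly across orders of magnitude, so
over- and under-sampled regimes are both represented; concentrations below 1
produce the sparse, long-tailed rank-abundance structure of real community
expression data. Every matrix has its own `SeedSequence` substream spawned
from the corpus seed, so corpora are bitwise reproducible and individual
matrices can be regenerated in isolation.

**What the simulator does not emulate:** read-level artifacts (sequencing
error, rRNA contamination, mapping/assembly ambiguity), between-sample batch
effects, and ecological covariance between genes (the Dirichlet induces only
the weak negative correlation of the simplex). Passing tests therefore
demonstrate correctness of the estimators under the stated sampling model,
not robustness to upstream bioinformatics noise.

## Rarefaction and extrapolation

Interpolation is the exact hypergeometric expectation of distinct genes in a
without-replacement subsample; extrapolation is Chao1-based at Hill order
q = 0 (richness), with

    f0 = f1² / (2 f2)                if f2 > 0
    f0 = f1 (f1 − 1) / (2 (f2 + 1))  otherwise
    S(N + m*) = S_obs + f0 [1 − (1 − f1/(N f0 + f1))^{m*}].

Numerical choices:

* Binomial coefficients are evaluated in log-gamma space; depths of 10⁷
  reads and more are safe from overflow.
* Knots are spaced linearly from 1 to the endpoint (default 2× the observed
  depth, overridable), with the observed depth always inserted as the single
  `observed` knot; 100 knots by default.
* Depths are integers; richness is real.
* Replicate columns are pooled into one abundance vector by default (one
  curve per matrix); `--per-sample` computes one curve per column.
* Externally supplied depth–richness vectors with locally decreasing
  richness are tolerated with a warning by nudging to the running maximum;
  duplicated or decreasing depths are errors.

## Growth models and fitting

Families: the four-parameter Weibull sigmoid W(x) = a − b·e^(−c·xᵐ)
(0 ≤ b ≤ a, so W(0) = a − b ≥ 0), its two-parameter asymptotic-regression
special case (b = a, m = 1, implemented literally as that special case so
the two agree bitwise), and a three-parameter logistic
L(x) = a/(1 + e^((x0−x)/s)) parameterized so the asymptote is a direct
parameter.

Fitting:

* **Initialization** is a brute-force grid: asymptote log-spaced over
  [max richness, 10× max richness] (20 values), rate constants log-spaced
  over six decades bracketing 1/(deepest knot) (20 values, rescaled by the
  shape for the four-parameter family), shape m screened over
  {0.5, 1, 2, 4} with b tied so W(0) matches the first knot; for the
  logistic, midpoints span [min depth, 2× max depth] and scales one to three
  decades below the deepest knot. The grid point with the smallest residual
  sum of squares starts the optimizer.
* **Optimization** is Levenberg–Marquardt (`scipy.optimize.least_squares`,
  `method="lm"`), at most 10,000 evaluations, relative tolerances 1e-10, in
  a log/logit internal parameterization that enforces positivity and
  b ≤ a without constraint handling. A stalled optimizer returns
  `converged=False`, never an exception.
* **Covariance** comes from the finite-difference Jacobian at the optimum
  with residual variance RSS/(n−p); columns are rescaled before the
  pseudo-inverse because parameter magnitudes differ by many orders
  (a ~ 10⁵ genes, c ~ 10⁻⁶ per read).
* Fitting uses the interpolated + observed knots by default
  (`use_extrapolated=True` includes the Chao1 tail); the conservative
  default keeps the fit anchored to the exactly known part of the curve.
* Model selection scores candidates by Efron's pseudo r-squared on the
  fitted knots; ties within 1e-12 break toward fewer parameters (so exact
  two-parameter data is reported as the two-parameter family).
* A fitted asymptote below the maximum observed richness is reported with a
  warning flag, not suppressed.

Fit quality is summarized by Efron's pseudo r-squared
(1 − SSres/SStot, possibly negative), min-max accuracy
(mean of min(obs, pred)/max(obs, pred); 1 = perfect), and RMSE in gene
units.

## Effort estimation

Closed-form inversions give x_q with W(x_q) = q·a:

* two-parameter: x_q = −ln(1−q)/c;
* four-parameter: x_q = (ln(b/(a(1−q)))/c)^{1/m}, and x_q = 0 when
  W(0) ≥ q·a already;
* logistic: x_q = x0 − s·ln(1/q − 1), floored at 0.

The asymptote interval is the delta-method (Wald) interval; x_q intervals
use a parametric bootstrap (200 draws from the asymptotic normal of the
parameters, invalid draws rejected) because the inversion is nonlinear in
all parameters. A missing or non-finite covariance yields an unbounded band
with a warning rather than a failure.

**Effort** is defined as min(100, 100·x₀.₉₉/N_observed) percent: the reads
needed to cover 99% of the asymptote relative to the reads actually
sequenced, capped at 100 for unsaturated libraries. The typology thresholds
— over-sampled when x₀.₉₉ ≤ 0.1·N, correct when x₀.₉₉ ≤ N, under-sampled
when only x₀.₉₀ ≤ N, very under-sampled otherwise — are conventions of this
package and are configurable (`over_factor`).

## A-priori prediction

Features of a truncated curve (default: first 20 of 100 knots; a
truncate-by-depth mode keeps knots below a fraction of the deepest depth):
the logistic and four-parameter Weibull asymptotes fitted to the truncated
curve (falling back to the two-parameter asymptote, flagged, when a fit
fails) and the observed depth/richness ranges. The model-1 preset uses both
asymptotes plus the read range; model 2 drops the logistic asymptote.

Targets are the **full-curve estimates** (asymptote and coverage depths),
not the generating truth: the predictor's job is to recover what the
complete curve would have said. The true simulated gene count is carried
separately for oracle checks.

Regressors: stepwise linear (backward elimination on AIC over OLS), RBF
support-vector regression (standardized features and target, C = 10), and
gradient-boosted trees (XGBoost; 500 rounds, depth 4, learning rate 0.1,
single thread). Hyperparameters are ordinary defaults for tables of this
size, not tuned per dataset.

**Prediction intervals.** Each predictor carries a bag of B = 100 refits on
bootstrap row resamples. The interval at level L is read off the
percentiles of the ensemble's predictions *convolved with the out-of-bag
residual pool* (every member prediction plus every OOB residual). The pure
ensemble spread measures only model variance and collapses to near zero
when the features are strongly informative, which would make nominal
coverage of the true value impossible; adding the OOB residuals — the
standard bagged prediction-interval construction — makes the interval a
genuine prediction interval that widens with both model variance and the
irreducible per-curve noise. When the target is exactly realizable both
components vanish and the interval is degenerate, as it should be. The
interval is expanded, if needed, to contain the point prediction and the
bag median.

Validation (`cross_validate`) repeats random 70/30 splits (default 300
resamples), scoring R², RMSE and MAE on the held-out split; summaries report
the mean with 95%/99% normal-approximation confidence bands for the mean
across resamples (degenerate for a single resample).

## Problem sizes used in the shipped studies

The acceptance study simulates 150 matrices (3 replicate samples each) with
k log-uniform in [267, 30000] and per-sample reads log-uniform in
[550, 500000] — the documented corpus ranges with reduced upper bounds, a
deliberate desk-scale choice that preserves the span of sampling regimes —
concentration log-uniform in [0.01, 1], 100-knot curves, features from the
first 20 knots, and 20 random 70/30 resamples of a stepwise linear
predictor. The interval-coverage study uses saturated communities
(k in [267, 2000], per-sample reads in [30000, 300000], concentration in
[0.5, 2], where the true gene count is essentially fully observable), 80
training and 50 held-out communities, and a 100-member XGBoost bag.

## Known limitations

* Effort extrapolation inherits the biases of Chao1 and of the growth-model
  family: genes rare beyond the reach of the singleton/doubleton estimate
  are invisible, so for very uneven communities (concentration « 1) the
  asymptote tracks the *observable* richness, which can sit well below the
  nominal gene count.
* The effort definition and typology thresholds are conventions; they are
  stable and documented but not uniquely determined by theory.
* Confidence bands assume the asymptotic normal of the least-squares
  estimates; for barely saturating curves the asymptote likelihood is
  strongly skewed and the Wald band can be optimistic.
* Predictors are trained on simulated corpora; applying them to real
  metatranscriptomes assumes the Dirichlet-multinomial family is an adequate
  description of the count structure after upstream cleaning.
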