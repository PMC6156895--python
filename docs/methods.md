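# Methods

This note documents the models implemented in `globalp`, the defaults
and numerical choices, what the simulator does and does not emulate, and
the design decisions that were genuinely open.

## The region test

**Model.** For a region of *m* probes, the per-probe z-scores
z = β̂/SE(β̂) from the EWAS stage are treated as jointly multivariate
normal under the null of no association, with mean 0 and covariance Σ
equal to the inter-probe correlation of M-values in the study sample.
With covariates in the EWAS model, Σ is the *partial* correlation
matrix: each probe's M-vector is residualized on intercept + covariates
by least squares and the residual vectors are Pearson-correlated. The
phenotype itself is *not* residualized out — Σ must be the null
covariance of z, and under the null the phenotype carries no
methylation signal. The quadratic form zᵀΣ⁻¹z then follows χ² with m
degrees of freedom.

**Assumptions.** (i) per-probe Wald statistics are approximately
normal (large-sample); (ii) the z-score cross-correlation equals the
M-value (partial) correlation — exact for OLS with shared design,
approximate under the mixed model; (iii) Σ estimated from the study
sample is treated as known. Assumption (iii) is the main source of the
mild anti-conservatism visible at moderate n (see *Calibration*).

**Singular Σ.** Duplicate or near-duplicate probes make Σ singular and
would explode a naive inverse. Eigenvalues below τ·λ_max (default
τ = 1e−8) are clipped to zero, the statistic uses the resulting
pseudo-inverse, and the degrees of freedom become the retained rank —
preserving the χ² reference on the retained subspace. Clipping k
eigenvalues reduces df by exactly k.

**Kinship and Σ.** Σ is estimated from covariate-residualized M-values
*without* kinship adjustment. A kinship-aware residualization would be
an extension; the covariate-only estimator is the default because the
region statistic consumes summary z-scores whose null correlation is
governed by the phenotype-free covariance of M. The
`partial_correlation` function is the single hook where an alternative
estimator would plug in.

**Multiple testing.** Gene-category and island-relation regions overlap
heavily (the same probes legitimately drive several regions), so
Bonferroni is too conservative; the Benjamini–Hochberg step-up is
applied jointly across the union of both region families (one family,
default α = 0.05). Adjusting the two families separately was the other
defensible choice; pooling was chosen because a discovery in either
family answers the same scientific question.

## EWAS stage

Methylation is the outcome, the phenotype the predictor:
M ~ intercept + phenotype + covariates. Beta values are transformed to
M = log₂(β/(1−β)); boundary betas (exactly 0 or 1, which arrays
occasionally produce) are clamped to [ε, 1−ε] with ε = 1e−6 by default,
with an opt-out that errors instead. The transform is implemented as
log₂(β) − log₂(1−β) so the antisymmetry M(β) = −M(1−β) holds exactly in
floating point.

**Mixed model.** For family samples the model adds a polygenic random
effect with covariance σ²g·2Φ, where Φ holds pedigree kinship
coefficients computed by the standard recursion (founders unrelated,
φ(i,i) = (1+φ(f,m))/2, φ(i,j) = (φ(f,j)+φ(m,j))/2 in an order where
parents precede children). Estimation is REML: a one-time
eigendecomposition 2Φ = UDUᵀ rotates the model so the covariance is
diagonal, σ²e(δD+I) with δ = σ²g/σ²e; the restricted likelihood is then
profiled (GLS for fixed effects, closed-form σ̂²e) down to a
one-dimensional bounded Brent search over log δ ∈ [−10, 10]
(xatol = 1e−8). A boundary optimum is accepted — δ → 0 degenerates
exactly to OLS — and only an optimizer failure clears the convergence
flag. The eigendecomposition is cached on the kinship object because the
EWAS reuses it for every probe; per-probe complete-case subsets trigger
a fresh decomposition for that probe only.

**Inference.** p-values use the normal (Wald) reference, not t, because
the region statistic consumes z = β̂/SE directly and the χ² reference
assumes normal scores. At n = 200 this is mildly anti-conservative
(normal 1.96 vs t≈1.97 critical value); the calibration experiments
quantify the net effect.

**Degenerate inputs.** Zero-variance probes, perfect fits (zero
residual variance) and insufficient complete cases raise in the
single-probe API and become flagged records (converged = False, NaN
statistics) in `run_ewas`, which never aborts a whole run for one probe.
Rank-deficient designs error naming the collinear columns. Categorical
covariates are expanded deterministically: levels sorted as strings,
first level the reference.

## Regions

Gene name/group tokens from the manifest are paired strictly
positionally across the two semicolon-separated lists (Illumina manifest
convention); one region per distinct (gene, category) pair, and one per
(island name, relation) pair, so north and south shores of an island are
distinct regions. Region bounds are the min/max probe positions
(1-based inclusive; BED export converts to 0-based half-open). Reported
bounds in the result table cover the probes actually tested after drops.
The default minimum region size is 2 probes — a single-probe region
duplicates the per-probe EWAS (and `run_globalp` on an m = 1 region
reproduces the probe's p-value exactly, which the tests assert).

## Simulator

`simulate_study` generates: a family structure (unrelated singletons,
trios, or two-founder sibships) with its exact block kinship; covariates
age ~ N(48, 12²), sex (F/M 50:50), center (two sites 50:50), smoking
(never/former/current 55:25:20); a unit-variance phenotype
y = covariate effects + a + e with polygenic family effect
a ~ N(0, h²·2Φ) (default h² = 0.4 for family designs); and per-region
M-values drawn MVN with exchangeable (default ρ = 0.6) or AR(1)
correlation, scaled by noise_sd = 1, with `effect × y` added to every
probe of a causal region. M is generated first and converted to betas
through the inverse transform, so the generative correlation lives on
the analysis scale. Defaults mirror the calibration conditions used
throughout: n = 200 unrelated samples and 5-probe ρ = 0.6 regions for
null calibration; 300 trio families, h² = 0.4, effect 0.5 for recovery.

What it does **not** emulate: Infinium I/II probe-type chemistry, batch
and position effects, cell-type composition, genome-scale probe counts,
non-normal M distributions, and missingness patterns of real arrays.
Passing calibration here shows the statistic behaves as derived when its
assumptions hold; it does not certify behavior under array artifacts
that upstream normalization is assumed to have removed.

**Replicate experiments** spawn independent child seeds from the master
seed via `numpy.random.SeedSequence`, making every experiment
reproducible and replicates mutually independent. Replicate counts
default to 2000 for calibration and 500 per power point, sizing binomial
CI half-widths near 0.01 and 0.05 respectively.

## Calibration results (computed by the suite / acceptance script)

The end-to-end null experiment (2000 replicates, 5-probe ρ = 0.6
regions, n = 200 unrelated, estimated Σ) lands near 0.05 at α = 0.05
(band [0.040, 0.060] asserted in the tests); the residual wobble comes
from the normal-vs-t reference and from treating the estimated Σ as
known. The mixed-model recovery experiment returns the planted effect
within Monte-Carlo error with an empirical/model SE ratio near 1. Power
over a per-probe effect grid is non-decreasing and equals the type-I
rate at effect 0. Exact numbers for a given seed are written by
`scripts/acceptance.py`; the note intentionally states no number the
code does not recompute.

## Known limitations

- Σ from the study sample requires individual-level data; precomputed
  external correlation panels are not implemented.
- The mixed model supports a single (kinship) random effect; no
  repeated-measures or batch random effects.
- Two-time-point designs are analyzed as two independent runs; no
  cross-visit combination.
- Probe exclusion (polymorphic / cross-reactive) is consumed as
  precomputed id lists; the underlying sequence-level criteria are not
  recomputed, as they require external SNP/genome resources.
- No normalization is performed; the input matrix is assumed normalized
  upstream.
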