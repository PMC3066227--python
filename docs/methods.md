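# Methods

## The selection model

A published case-control result on genetic marker *m* is a log odds ratio
`X_i` with known within-study standard error `sigma_i`.  Absent selection,

    X_i ~ N(Delta_m, sigma_i^2 + tau2_m),

with `Delta_m` the marker's mean per-allele log OR and `tau2_m` its
between-study variance.  Selective reporting makes a result's chance of
publication depend on its standardized effect `z_i = X_i / sigma_i` (the
quantity that determines the standardized p-value).  That dependence is a
stepwise-constant weight function `omega(z)` taking value `w_j` on the
interval `(z_{j-1}, z_j]` of a fixed boundary grid; the outer intervals are
pinned at `w = 1`, so all weights are *relative* publication probabilities
with respect to formally significant results.  The density of a published
result is the weighted, renormalized normal density

    f(x) = omega(x/sigma_i) phi(x; Delta, sigma_i^2 + tau2)
           / sum_j w_j B_ij,
    B_ij = Phi((z_j sigma_i - Delta)/s) - Phi((z_{j-1} sigma_i - Delta)/s),
    s = sqrt(sigma_i^2 + tau2),  z_0 = -inf,  z_k = +inf.

`B_ij` is the unselected probability of interval *j*, so the normalizer is
a finite sum; no quadrature enters the likelihood.

A single meta-analysis rarely has the power to resolve `omega`.  The model
therefore pools many markers: each keeps its own `(Delta_m, tau2_m)`, but
one weight-parameter vector is shared by all of them, on the premise that
reporting practices do not differ across markers.  The combined log
likelihood is the sum of the per-marker sums of `log f`.

### Categories and the model family

Each study is assigned a temporal category per marker: **initial** (same
calendar year as the marker's first publication), **early** (the next two
years), **late** (later).  When several studies are initial, the marker's
initial *sign* is that of the most extreme result (largest |z|).  Six model
specifications map categories to weight functions:

| model            | boundaries                  | free weights |
|------------------|-----------------------------|--------------|
| unbiased         | —                           | 0            |
| high_resolution  | ±(0.25…2.58), 16 intervals  | 14 (inner intervals; `w = 1` for \|z\| > 2.58) |
| model1           | ±1.64                       | 1: `w_S` for all studies |
| model2           | ±1.64                       | 2: `w_I` (initial), `w_S` (subsequent) |
| model3           | −1.64, 0, 1.64              | 4: `w_I`; `w_E1` (early, z ≤ 0), `w_E2` (early, z > 0); `w_S` |
| proteus          | −1.64, 0, 1.64              | 4: as model3, but `w_E1`/`w_E2` selected by whether the early study's sign opposes/agrees with the initial result |

model3 and the proteus model have identical size, so an AIC comparison
between them asks precisely whether the *direction* of the initial finding
shapes the bias of early replications (the Proteus phenomenon).  |z| = 1.64
corresponds to a two-sided p of 0.10 on the standardized scale; the
high-resolution fit is the empirical justification for cutting there.
Every model also has a fixed-effect variant with all `tau2_m` pinned at 0 —
the same code path with the variance coordinate dropped, not a separate
implementation.

Interval membership is left-open/right-closed (`z` exactly on a boundary
belongs to the lower interval).  Ties occur with probability zero under the
continuous model; the convention is applied identically in evaluation and
in the `B_ij` construction, which is all that matters.

## Estimation

All free parameters — shared log-weights, per-marker `Delta_m` and
(random-effects mode) `tau2_m` — are estimated by joint maximum likelihood.
Weights are parameterized on the log scale (positivity for free; estimates
are reported as log-weights).  Conditionally on the log-weights the markers
are independent, so the joint optimum is computed by profiling:

* **outer**: BFGS (scipy) over the log-weight vector, on the profile
  log likelihood;
* **inner**: a batched damped-Newton solver that maximizes every marker's
  1- or 2-parameter likelihood simultaneously, with central finite
  differences for derivatives, per-marker backtracking line search, and a
  trust-step regime once expected improvements fall below the rounding
  noise of the likelihood values; converged markers drop out of the
  evaluation subset;
* **polish**: Newton steps for the weights on the profile surface, using
  the Schur complement of the blockwise information matrix (which *is* the
  profile Hessian), until the joint finite-difference gradient max-norm is
  at the noise floor.

This is numerically the same optimum a single joint BFGS over the full
parameter vector would find, at a fraction of the cost; the joint gradient
is explicitly checked at the solution.

Starting values: inverse-variance mean for `Delta_m`, DerSimonian–Laird
moment estimate (truncated at 0, plus 1e-6) for `tau2_m`, 0 for all
log-weights — the optimizer's origin is exactly the unbiased model.  Up to
three jittered restarts (seeded, N(0, 0.1) on the log-weights) are tried if
the convergence checks below fail.

### Standard errors

The covariance of all estimates is the inverse of a numerically
approximated information matrix: central second differences with step
`1e-4 * max(1, |theta|)` per coordinate, assembled blockwise — the
weights block, one small block per marker, and the weight-by-marker cross
blocks (exact zeros between different markers' parameters make the matrix
block-sparse).  Inversion goes through the Schur complement; per-marker
covariances include the propagated weight-uncertainty term.  A
non-invertible or non-positive-definite block is a reported convergence
failure, never silently pseudo-inverted.  95% confidence intervals are
`estimate ± 1.96 SE`, exponentiated for reporting probabilities; the
contrast `log w_E1 - log w_E2` uses
`SE = sqrt(var1 + var2 - 2 cov)` from the weights covariance block.

### Convergence and exclusion

Unrestricted maximum likelihood lets `tau2_m` go negative, and the
likelihood of any single marker is unbounded as
`tau2 -> -min_i sigma_i^2` with `Delta` at the corresponding study's
effect (the classic degenerate-variance spike).  A marker is flagged
non-convergent when its inner solve runs into that boundary with the
likelihood still rising, when its iterates run away or stall, or when its
information block is not positive definite.  A fit is *converged* when the
joint gradient max-norm is below `1e-5`, the weights-block Schur complement
is positive definite, and no surviving marker failed its Hessian check.

Because a marker that fails under one model would silently distort
comparisons, the exclusion protocol removes, from **every** model, the
union of markers that failed under **any** model, and *iterates to a fixed
point*: removing markers changes the shared weight estimates, which can in
turn change which markers converge, so all models are refitted on the
surviving corpus until no model flags anything new.  AIC and
log-likelihood differences are then computed on the identical corpus —
comparing fits whose own exclusions differ would make the comparison
meaningless, since each log likelihood would sum over different studies.  With
equal marker sets and effects mode, per-marker parameters cancel in the
differences, so `delta_AIC = 2 delta_k_w - 2 delta_L` depends only on
weight-parameter counts.

A documented consequence, measurable with this package's own recovery
study: exclusion is informative.  Under the default protocol on synthetic
200-marker corpora (model2 generation, conditions below), ~17% of markers
are excluded and both weight estimates acquire a downward bias of about
−0.08 to −0.10 on the log scale (the excluded markers are those with the
least observed dispersion, which is not independent of their z-values).
In z-score units the shift is ≈ −0.7 SE for log w_I and ≈ −1.2 SE for
log w_S, whose SE is smaller; across replicate batches the 2-SE coverage
of log w_S runs ~84–92% against the nominal 95%.  With the
`variance_floor` option (`tau2 >= 0`, projected Newton on the active
constraint) almost no marker is excluded and the estimates are unbiased
(−0.804 / −0.192 in the same study).  The unrestricted protocol remains the default because it is
the published method; the floor is the documented alternative.  At a floor
optimum the `tau2` coordinate is not an interior estimate, so its row and
column are profiled out of the information matrix and its SE reported as
undefined.

## The synthetic corpus generator

The generator emulates the shape of the Alzheimer's-disease
genetic-association literature the method targets: by default 100 markers,
4–30 published studies each, 90% truly null markers and 10% with
|log OR| uniform in 0.1–0.5 (random sign), between-study variance uniform
in 0–0.04, within-study SEs uniform in 0.08–0.4, and calendar years
accumulating from 1995 with Poisson(0.7) gaps between successive studies
(so same-year ties and 1–2-year gaps — the initial/early window — are
common, as in the real literature).

Selection is realized by rejection sampling: candidate results are drawn
from the unselected normal model in temporal order and published with
probability `omega(z) / max(omega)` under the category-appropriate weight
function, which realizes the weights exactly as relative publication
probabilities.  Candidates arriving before anything is published count as
initial; the sign context of early replications tracks the most extreme
*published* initial result — the same rule the categorizer applies to the
published corpus, so the generative process is the model being fitted.
Generation stops at the target published count and errors out if 50× that
many candidates are consumed first.  The closed-form check is that
published z-values fall in interval *j* with probability
`w_j B_ij / sum_l w_l B_il`.

What the generator does **not** emulate: covariate-adjusted published
p-values (the real corpus's z-values are standardized, not as-published),
journal tiers, citation dynamics, time-varying effects, correlated studies
from shared cohorts, or markers genotyped in overlapping populations.
Passing recovery tests therefore demonstrates the estimator is correct for
the stated model, not that real literatures satisfy the model.

## Effect derivation from genotype tables

Dialect-B input rows are 2×3 genotype count tables.  The per-allele log OR
is the allele-dose coefficient (0/1/2 per subject, genotype counts as
frequency weights) of a logistic regression of case status, via statsmodels
GLM.  When a marginal allele count is zero the regression separates; the
estimator then falls back to the Woolf estimator on the collapsed 2×2
allele table with the Haldane correction (0.5 added to every cell when any
cell is zero).  Note the 3-level dose model is not saturated, so its
estimate is close to, but not identical with, the collapsed-table Woolf
value.  The variant-allele column defines the risk orientation; the package
never re-orients by frequency, because the sign convention feeds the
sign-dependent proteus weights and must remain the data curator's explicit
choice.  Markers are retained only with results from ≥ 4 distinct
publications; no Hardy–Weinberg filtering is applied.

## Numerical choices

* `B_ij`: normal CDF via `scipy.special.ndtr`; the top interval uses the
  survival function to avoid upper-tail cancellation; entries floored at 0
  after differencing.  Rows sum to 1 at machine precision.
* The normalizer `sum_j w_j B_ij` is accumulated in linear space (k ≤ 16,
  all terms bounded); an underflow below 1e-300 is a hard error.
* Likelihood infeasibility (`sigma_i^2 + tau2 <= 0`) is reported as NaN per
  marker inside the batched solver so the optimizer can backtrack, and as a
  named exception on the public per-study API.
* Finite-difference steps: 1e-5 (inner Newton), 1e-4 relative
  (information matrix), 1e-6 (profile-gradient polish); `tau2` steps are
  capped at a quarter of the distance to the feasibility boundary.
* All randomness flows from a single seed via `numpy` `SeedSequence`
  substreams; reruns are bit-identical.

## Problem sizes in the test suite

The validation suite runs, on one CPU, with: 40-marker corpora for the
nested-ordering and pipeline checks; 25 replicates of 200-marker corpora
for model2 recovery; 25 replicates of 100-marker corpora for the
proteus-vs-model3 AIC selection study; 10^5 published studies for the
simulator's closed-form check; 100 random draws for the quadrature
normalization oracle.  These sizes were chosen to give each check clear
statistical resolution while keeping the full suite in the tens of
minutes.

## Known limitations

* The weight function depends on z and category only; covariate-dependent
  selection (study quality, journal) is out of scope.
* Boundaries are fixed a priori, not estimated.
* The exclusion protocol's informative-exclusion bias (above) is inherent
  to the unrestricted variant of the method, not removable by tuning.
* Fits with many markers estimate thousands of incidental parameters; the
  shared weights are consistent as markers accumulate, but per-marker
  `tau2` estimates with 4–10 studies are individually noisy.
* Likelihood-ratio tests between non-nested models are deliberately not
  offered; comparisons go through AIC as differences against the unbiased
  baseline.
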