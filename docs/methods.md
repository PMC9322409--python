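# Methods

## Data-generating model

All simulated studies draw from a standard bivariate normal distribution
with population Pearson correlation ρ, constructed by linear mixing of
unit-variance Gaussians:

    x ~ N(0, 1),   y = ρ·x + sqrt(1 − ρ²)·e,   e ~ N(0, 1).

This is the Cholesky factorisation of the 2×2 correlation matrix, so the
population correlation of the generating process is exactly ρ; a test
confirms agreement with an independent multivariate-normal sampling route.
Marginals are zero-mean, unit-variance without loss of generality — the
Pearson correlation and every statistic built on it here are invariant to
affine rescaling of either variable (property-tested).

The generator emulates the idealised setting in which the statistical model
is exactly true: Gaussian marginals, linear dependence, homoscedastic noise,
independent observations. It deliberately does *not* emulate features of
real data — heavy tails, outliers, heteroscedasticity, measurement error,
dependence between observations, or selective analysis choices. Passing
tests therefore show that the significance filter biases effect sizes *even
when every model assumption holds*; with real data the picture can only get
worse, not better.

### Seeding

One master seed governs a whole experiment. Substreams are derived with
`numpy.random.SeedSequence(master_seed, spawn_key=path)` where `path` is an
integer tuple naming the consumer — grid cell (i, j) = (ρ-index, n-index)
for the replication engine, separate paths for a simulated sample versus its
bootstrap stream. Cells are therefore reproducible independently, in any
order, and identical configuration + seed reproduces byte-identical output
files (the CLI manifest records SHA-256 checksums to make this checkable).

## Replication engine

Per (ρ, n) cell, `replicates` studies are simulated and each is tested
against the zero null with the classical exact t test under bivariate
normality: t = r·sqrt(n−2)/sqrt(1−r²) against a central t distribution with
n−2 degrees of freedom. "Significant" means strictly p < α; p = α counts as
non-significant (immaterial for continuous p-values, but documented).

Cell summaries report power (significant fraction), quantiles of the
p-value distribution, and quantiles of the observed correlation separately
for the significant and non-significant classes, plus the percent bias of
each class median relative to ρ, 100·(median − ρ)/ρ (absolute bias is
reported alongside; percent bias is undefined at ρ = 0 and reported as NaN).

Defaults are the study conditions: ρ ∈ {0.45, 0.24}, n = 8…100 in steps of
2, 10,000 replicates per cell, α = 0.05, quantile probabilities
{0.05, 0.25, 0.5, 0.75, 0.95} (central 90% and 50% bands plus the median).
The full 94-cell grid runs in well under a minute on one CPU because each
cell is a single vectorised pass. Tests exercising many cells or
distributional properties use 2,000–10,000 replicates as noted per test,
with tolerances derived from binomial/median Monte-Carlo standard errors.

Conventions worth making explicit:

* **Quantile estimator** — linear interpolation between order statistics
  (numpy default). Band endpoints at the 4th decimal depend on this choice.
* **Sign handling** — significant replicates with negative r at tiny n stay
  in the significant class; the selection event is p < α regardless of sign
  (this is what makes the significant class bimodal at n = 8 for ρ = 0.24).
* **Empty classes** — at high power a cell's non-significant class can be
  empty; its quantiles are NaN with count 0, never imputed.
* **Degenerate replicates** — |r| = 1 yields p = 0 with an infinite
  statistic rather than an exception, flagged as degenerate.

A closed-form power approximation via the Fisher z transformation,
Φ(√(n−3)·|atanh ρ| − z_{1−α/2}) + Φ(−√(n−3)·|atanh ρ| − z_{1−α/2}),
serves as an independent oracle; simulated power must match it within
Monte-Carlo noise plus an explicit allowance for the t-versus-z gap, which
is largest at the smallest n.

## Compatibility curves

For one observed sample, the compatibility curve maps hypothesized true
correlations ρ₀ to the two-sided p-value for the null ρ = ρ₀.

* **Parametric**: level(ρ₀) = 2·(1 − Φ(√(n−3)·|atanh r − atanh ρ₀|)). This
  is exactly dual to the Fisher-z interval at every level, so the 0.05-level
  crossings coincide with the 95% interval bounds; the curve is unimodal
  with level 1 at the point estimate.
* **Bootstrap**: pairs (xᵢ, yᵢ) are resampled jointly with replacement
  (case resampling — resampling x and y independently would destroy the very
  correlation under study), the sample correlation is recomputed per
  resample (default 100,000; a warning fires below 1,000), and
  level(ρ₀) = min(1, 2·min(F̂(ρ₀), 1 − F̂(ρ₀))) with F̂ the bootstrap ECDF.
  This stacks central percentile intervals (not BCa). Ties between ρ₀ and
  bootstrap replicates get midpoint mass, shifting levels by at most
  O(1/resamples); the cap at 1 (attained at the bootstrap median) is a cap,
  not a renormalisation. Degenerate resamples (zero variance, possible at
  tiny n) are dropped and counted; above 1% dropped, the curve is flagged
  unreliable.

The default ρ₀ grid is −0.999…0.999 in steps of 0.001 with levels forced to
0 at ±1 by continuity; interval endpoints are linearly interpolated at the
threshold crossing, which recovers Fisher bounds about three orders of
magnitude tighter than the grid step. Asymptotic agreement between the two
constructions is verified at n = 1,000 (sup level difference below 0.02).

Test/interval conventions differ deliberately between the two halves of the
package: the replication engine uses the t test, the classical default for
"p < 0.05" power against the zero null, while the compatibility machinery
uses Fisher z throughout because curve/interval duality is exact there. The
95% Fisher interval excludes 0 exactly when the Fisher-z test rejects at
α = 0.05; against the t test the correspondence is approximate, with a
narrow disagreement window at small n (quantified in the tests: at n = 8
the critical |r| values are ≈ 0.7045 vs ≈ 0.7067).

The report generator emits an estimation-style sentence — point estimate
plus the range of most compatible true values at the stated level, naming
both directions when the interval spans zero — and never a significance
verdict.

## Known limitations

* Only the Pearson correlation of bivariate-normal data is modelled; no
  non-Gaussian marginals, no other estimators, no multiple-testing or
  p-hacking simulations.
* The bootstrap curve inherits percentile-interval behaviour: at small n it
  can be noticeably asymmetric and need not match the parametric curve.
* The analytic power formula is an approximation to t-test power; it is used
  only as a cross-check with an explicit error allowance, never as the
  simulation itself.
* Exemplary single-sample curves depend on the particular simulated sample;
  only their qualitative features (peak at the point estimate, zero inside
  but below the peak of a covering interval, narrower curves at larger n)
  are stable and tested.
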