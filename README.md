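# corrcompat

Simulation and estimation tools for two closely related questions about the
Pearson correlation coefficient in small-sample research, typical of ecology
and evolutionary biology:

1. **What does filtering results by statistical significance do to reported
   effect sizes?** The replication engine simulates thousands of replicate
   bivariate-normal studies per (true correlation ρ, sample size n) cell,
   tests each with the classical two-sided t test of ρ = 0 at α = 0.05, and
   summarises the p-value distribution, power, and the observed correlations
   *conditional on the significance verdict*. Because noisy overestimates
   cross the significance threshold more easily than underestimates, the
   median significant-class r systematically exceeds ρ (the winner's curse),
   while non-significant estimates are biased downward — increasingly so as
   power grows.
2. **How should a single estimate be reported instead?** The compatibility
   module computes the compatibility (consonance) curve of an observed
   sample: the function mapping each hypothesized true correlation ρ₀ to the
   two-sided p-value it would receive as a null hypothesis. Its γ-level
   cross-sections are the stacked compatibility ("confidence") intervals and
   its peak is the point estimate. Both a parametric construction (Fisher z:
   level(ρ₀) = 2(1 − Φ(√(n−3)·|atanh r − atanh ρ₀|))) and a non-parametric
   one (percentile stacking over paired bootstrap resamples) are provided.

The intended users are quantitative biologists and statistics educators who
want to demonstrate — or quantify for their own study designs — p-value
variability, power, significance-filter inflation, and estimation-based
reporting.

## Worked example

```sh
python examples/significance_filter.py
```

prints (seeded, so reproducible):

```
true correlation          rho = 0.45
power (share with p<0.05)     = 0.532
median r | significant        = 0.569
median r | non-significant    = 0.311
significant-class bias        = +26.4%
non-significant-class bias    = -30.9%
```

Read: with a substantial true correlation of 0.45 and n = 20, only 53% of
replicate studies reach p < 0.05; the median *significant* estimate (0.569)
overstates the truth by about 26%, while the median non-significant estimate
(0.311) understates it by 31%. `examples/power_grid.py` sweeps sample sizes
and shows the significant-class inflation fading as power approaches one,
and `examples/compatibility_curve.py` computes, for one n = 30 sample,

```
observed correlation r = 0.591  (true rho = 0.45, n = 30)
parametric 95% compatibility interval: (+0.293, +0.784)   level at rho0=0: 0.0004
bootstrap  95% compatibility interval: (+0.348, +0.792)   level at rho0=0: 0.0000
```

together with a recommended estimation-style summary sentence that names the
point estimate and the range of most compatible true values instead of a
significance verdict.

A thin CLI drives the same machinery end to end with provenance manifests
(config echo, master seed, SHA-256 checksums per output):

```sh
corrcompat replication --config config.yaml --out results/
corrcompat curve --simulate 0.45 30 --method both --resamples 100000 --out results/
```

## Library layout

| module                    | contents |
|---------------------------|----------|
| `corrcompat.sampler`      | seeded bivariate-normal sampling with exact population correlation; substream scheme; x,y CSV I/O |
| `corrcompat.inference`    | Pearson r, two-sided t test of ρ = 0, Fisher-z intervals and p-values |
| `corrcompat.replication`  | per-cell and full-grid Monte-Carlo summaries (power, p-value bands, class-split effect sizes), analytic power approximation, tidy table writer |
| `corrcompat.compatibility`| parametric and bootstrap compatibility curves, interval extraction, report sentence, curve writer |
| `corrcompat.cli`          | `replication` and `curve` subcommands with run manifests |
| `corrcompat.plotting`     | cosmetic two-panel grid figure and curve plot |

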