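"""Compatibility curves for one observed sample.

Simulates a single n = 30 sample with true correlation 0.45, then maps every
hypothesized true correlation to the p-value it would receive as a null
hypothesis — parametrically through the Fisher z transformation and
non-parametrically by stacking bootstrap percentile intervals (100,000
paired resamples).
"""

from corrcompat import (
    bootstrap_curve,
    describe_estimate,
    interval_at_level,
    parametric_curve,
    pearson_r,
    sample_bivariate,
    substream,
)

data = sample_bivariate(n=30, rho=0.45, stream=substream(2, 0))
r_hat = pearson_r(data.x, data.y)
print(f"observed correlation r = {r_hat:.3f}  (true rho = 0.45, n = {data.n})")

par = parametric_curve(r_hat, data.n)
boot = bootstrap_curve(data, resamples=100_000, stream=substream(2, 1))

for name, curve in [("parametric", par), ("bootstrap ", boot)]:
    iv = interval_at_level(curve, 0.95)
    print(f"{name} 95% compatibility interval: ({iv.lower:+.3f}, {iv.upper:+.3f})"
          f"   level at rho0=0: {curve.level_at(0.0):.4f}")

print()
print(describe_estimate(r_hat, interval_at_level(par, 0.95)))
print()
print("Every value inside a 95% interval would give p > 0.05 as a null")
print("hypothesis; compatibility is highest at the point estimate and")
print("declines smoothly - it does not vanish at the interval ends.")
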