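"""A sample-size sweep of power and conditional effect-size bias.

Runs a reduced grid (two true correlations, a coarse n sweep, 2,000
replicates per cell) and prints the tidy per-cell summary. The full study
design (n = 8..100 step 2, 10,000 replicates) is the GridConfig default.
"""

import pandas as pd

from corrcompat import GridConfig, run_grid, summaries_to_frame

cfg = GridConfig(
    rhos=(0.45, 0.24),
    n_grid=(10, 20, 40, 60, 80, 100),
    replicates=2_000,
    master_seed=1,
)
frame = summaries_to_frame(run_grid(cfg))

cols = ["rho", "n", "power", "median_r_sig", "median_bias_sig_pct", "median_r_nonsig"]
with pd.option_context("display.float_format", "{:.3f}".format):
    print(frame[cols].to_string(index=False))
print()
print("Power rises with n; the upward bias of significant-class medians")
print("shrinks as power grows, while non-significant medians fall further")
print("below the true correlation the larger the sample gets.")
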