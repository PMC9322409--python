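"""The winner's curse in one simulation cell.

Simulates 10,000 studies of n = 20 observations with a true Pearson
correlation of 0.45, tests each against the zero null at alpha = 0.05, and
compares the median observed correlation inside the significant and
non-significant classes with the true value.
"""

from corrcompat import run_cell, substream

s = run_cell(rho=0.45, n=20, replicates=10_000, alpha=0.05, stream=substream(1, 0))

print(f"true correlation          rho = {s.rho}")
print(f"power (share with p<0.05)     = {s.power:.3f}")
print(f"median r | significant        = {s.median_r_sig:.3f}")
print(f"median r | non-significant    = {s.median_r_nonsig:.3f}")
print(f"significant-class bias        = +{s.median_bias_sig_pct:.1f}%")
print(f"non-significant-class bias    = {s.median_bias_nonsig_pct:.1f}%")
print()
print("Half the replicate studies are non-significant despite a substantial")
print("true effect, and the median significant estimate overshoots the true")
print("correlation by roughly a quarter: selecting on p < 0.05 inflates")
print("reported effect sizes.")
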