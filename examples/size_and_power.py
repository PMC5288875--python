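"""Monte-Carlo calibration of the test: empirical size and a power curve.

Runs the size driver under the exchangeable null (delta = 0) and the power
driver over a grid of differential-connectivity magnitudes, at a small desk
scale (60 subjects per group, 100 bootstrap replicates, 60 repetitions) so
the whole script takes about a minute.
"""

from masterreg import empirical_size, power_curve

SCALE = dict(n_mc=60, n_bootstrap=100, n_case=60, n_control=60, seed=5)

size = empirical_size(**SCALE)
print(f"empirical size at nominal 0.05: {size.estimate:.3f} "
      f"(+/- {size.stderr:.3f}, {size.n_mc} repetitions)")
print("a value at or below ~0.05 means the bootstrap null is calibrated "
      "(slightly conservative is expected)\n")

curve = power_curve([0.0, 0.4, 0.7, 1.0], **SCALE)
print("delta  rejection rate")
for r in curve:
    print(f" {r.delta:.1f}    {r.estimate:.2f}  (+/- {r.stderr:.2f})")
print(
    "\nthe rate at delta = 0 equals the size estimate exactly (same seed, "
    "same code path);\npower grows toward 1 as the case/control difference "
    "in TF-gene loadings grows.\nAt this small sample size intermediate "
    "deltas reject less often than at the\nreference scale of 500 subjects "
    "per group."
)
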