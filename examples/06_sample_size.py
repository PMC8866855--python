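"""Group-size estimate for a two-group comparison of cell morphometry.

n = 2 sigma^2 f(alpha, beta) / Delta^2, with f built from normal
quantiles: f(0.05, 0.2) = (z_0.975 + z_0.8)^2 ~ 7.85.  With the spread
and effect size typical of circularity-based activation measures
(sigma ~ 18.4, Delta ~ 42 percentage points), about three animals per
group suffice.
"""

from gliamorph import sample_size

n, n_up = sample_size(sigma=18.42, delta=42.0, alpha=0.05, beta=0.2)
print(f"n = {n:.3f} -> use {n_up} animals per group")

n2, n2_up = sample_size(sigma=18.42, delta=20.0)
print(f"halving the detectable difference: n = {n2:.2f} -> {n2_up} per group")
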