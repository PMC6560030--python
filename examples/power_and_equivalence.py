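"""Replication sample sizes and TOST equivalence bounds.

The power calculators use the noncentral-t distribution: minimum n for a
one-sample t test at a given effect size, and the symmetric Cohen's-d
bound at which a one-sample TOST reaches a target power when the true
effect is zero.
"""

import numpy as np

from futurestate import required_n, tost_bound_for_power, tost_test

print("minimum n for d = 0.47, 80% power, alpha .05:")
print(f"  two-tailed: {required_n(0.47, 0.80, 0.05, tails=2)}")
print(f"  one-tailed: {required_n(0.47, 0.80, 0.05, tails=1)}")

for n in (32, 29):
    print(f"TOST bound for 80% power with n={n}: d = "
          f"{tost_bound_for_power(n, 0.80, 0.05):.2f}")

rng = np.random.default_rng(0)
sample = rng.normal(0.0, 1.0, 32)           # a genuinely null effect
res = tost_test(sample, bound_d=0.53)
print(f"\nTOST on a null sample (n=32, bound d=0.53): "
      f"p = {res.p_tost:.4f}, equivalent = {res.equivalent}")
print("equivalent=True means the effect is significantly inside the "
      "+-0.53 d bounds, i.e. a medium effect can be rejected.")
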