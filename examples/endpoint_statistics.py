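"""The trial's design and endpoint statistics at desk scale.

Reproduces the design sample size (42 per arm for sd 0.8%, difference
0.5%, 80% power) and the exact-test comparisons of responder proportions,
and shows the normality-gated two-group comparison.
"""

import numpy as np

from glucodss.outcomes import (
    proportion_test,
    sample_size_two_sample_t,
    two_group_compare,
)

n = sample_size_two_sample_t(sd=0.8, delta=0.5, power=0.80, alpha=0.05)
print(f"two-sample t design: sd 0.8%, delta 0.5%, power 80%, alpha 0.05 "
      f"-> {n} per arm ({2 * n} total)")

for (k1, k2), label in [((5, 0), "HbA1c <= 7.0% achieved"),
                        ((8, 7), "HbA1c <= 7.5% achieved")]:
    diff, ci, p = proportion_test(k1, 42, k2, 42, method="fisher")
    print(f"{label}: {k1}/42 vs {k2}/42 -> difference {100*diff:.0f}%, "
          f"Fisher exact p = {p:.3f}")

diff, ci, p = proportion_test(22, 42, 13, 42, method="chi_squared")
print(f"HbA1c improvement >= 0.5%: 22/42 vs 13/42 -> chi-squared p = {p:.3f}")

rng = np.random.default_rng(0)
x, y = rng.normal(0, 1, 60), rng.normal(0.4, 1, 60)
stat, p, used = two_group_compare(x, y)
print(f"normal-looking samples: {used} chosen, p = {p:.3f}")
x, y = rng.exponential(1, 60), rng.exponential(1.5, 60)
stat, p, used = two_group_compare(x, y)
print(f"skewed samples: {used} chosen, p = {p:.3f}")
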