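"""Sample-size calculation and ddCT relative expression.

The study design question: how many mice per group does a two-sided
two-sample t-test need at Cohen's d = 1.66, alpha 0.05, 80% power?
"""

import numpy as np

from glycoforms.stats import ddct_percent, power_two_sample_t, sample_size_t

n = sample_size_t(d=1.66, alpha=0.05, power=0.80)
print(f"required sample size: {n} per group "
      f"(power at n={n}: {power_two_sample_t(n, 1.66):.3f}; "
      f"at n={n-1}: {power_two_sample_t(n-1, 1.66):.3f})")
print(f"a medium effect d=0.5 would instead need {sample_size_t(0.5)} per group")

# qPCR: glycosyltransferase CT values against the 18S housekeeping gene,
# expressed as % of the reference (placebo) group
ct_target = np.array([24.8, 25.1, 25.0, 24.1, 23.9, 24.0])
ct_house = np.array([10.0, 10.1, 10.0, 10.0, 9.9, 10.0])
is_reference = np.array([True, True, True, False, False, False])
pct = ddct_percent(ct_target, ct_house, is_reference)
print("\nddCT relative expression (% of reference group):")
print("  reference:", np.round(pct[is_reference], 1))
print("  treated:  ", np.round(pct[~is_reference], 1))
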