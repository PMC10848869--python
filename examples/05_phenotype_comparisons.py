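"""Compare run timing, age composition and freshwater age between origins.

Uses the same reconstruction logic as the published tables: age classes
3 and 4 pooled for the chi-square, Fisher's exact test on freshwater age,
Holm step-down correction within each test family.
"""

import numpy as np

from kinboost import (
    age_composition_test,
    freshwater_age_test,
    holm_bonferroni,
    ks_run_timing,
)

# age-composition: proportions by origin (x N) reconstructed into counts
wild = [3] * 5 + [4] * 21 + [5] * 345 + [6] * 157      # N=528, skewed old
hatch = [3] * 1 + [4] * 103 + [5] * 556 + [6] * 51     # N=711, skewed young
r_age = age_composition_test(hatch, wild)
print(f"age composition: chi2={r_age.statistic:.2f} (df={r_age.df}), p={r_age.p_raw:.3g}")

# freshwater age: hatchery fish mostly leave the lake after one winter
fw_wild = [1] * 60 + [2] * 174
fw_hatch = [1] * 27 + [2] * 4
r_fw = freshwater_age_test(fw_hatch, fw_wild)
print(f"freshwater age: Fisher p={r_fw.p_raw:.2g}")

# run timing: similar distributions -> KS cannot reject
rng = np.random.default_rng(0)
doy_h = rng.normal(200, 12, 150)
doy_w = rng.normal(200, 12, 600)
r_ks = ks_run_timing(doy_h, doy_w)
print(f"run timing: D={r_ks.statistic:.3f}, p={r_ks.p_raw:.2f}, "
      f"median shift {r_ks.extra['delta_days']:+.1f} d")

adj = holm_bonferroni([r_age.p_raw, r_fw.p_raw, r_ks.p_raw])
print("Holm-adjusted p-values:", [f"{p:.3g}" for p in adj])
# The age shift survives correction; run timing does not differ.
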