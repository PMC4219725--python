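"""Scalar group statistics on the bundled 6-vs-6 clinical SUVt table.

Loads the per-subject gray/white-matter SUVt values of the reference
acetate-PET cohort (6 relapsing-remitting MS patients vs 6 healthy
volunteers), checks the internal consistency of the WM/GM ratio column,
and runs the exact Mann-Whitney U test plus the age-adjusted ANCOVA for
each outcome.
"""

import numpy as np

from petquant import (ancova_group_age, bonferroni_alpha,
                      load_reference_cohort, mann_whitney)

tab = load_reference_cohort()
print(tab.to_string(index=False))

dev = np.abs(tab.wm_suvt / tab.gm_suvt - tab.wm_gm_ratio)
print(f"\nWM/GM ratio column vs WM SUVt / GM SUVt: max |dev| = {dev.max():.2e}")
print("(within the 4-decimal rounding of the table, < 5e-4)")

ms = tab[tab.group == "MS"]
hv = tab[tab.group == "HV"]
print(f"\nBonferroni threshold for 9 regional comparisons at alpha 0.05: "
      f"{bonferroni_alpha(0.05, 9):.4f}")

for outcome in ("gm_suvt", "wm_suvt", "wm_gm_ratio"):
    mw = mann_whitney(ms[outcome], hv[outcome], mode="exact")
    an = ancova_group_age(tab[outcome], tab.group, tab.age)
    print(f"\n{outcome}:")
    print(f"  exact Mann-Whitney U = {mw.statistic:.0f}, "
          f"two-sided p = {mw.p_two_sided:.5f} "
          f"(enumeration over {mw.effect_summary['n_assignments']} splits)")
    print(f"  ANCOVA (group + age): t({an.df}) = {an.statistic:.3f}, "
          f"p = {an.p_two_sided:.5f}; "
          f"MS mean {an.effect_summary['mean_ms']:.4f} vs "
          f"HV mean {an.effect_summary['mean_hv']:.4f}")

print("\nA positive t means higher uptake in the MS group after adjusting "
      "for the\nolder age of the healthy volunteers.")
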