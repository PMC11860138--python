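"""Generate a synthetic two-arm immune panel and run the paired analysis.

Emulates a placebo-controlled 21-day course: cytokines suppressed and most
immune cell subsets stimulated in the treated arm.  The analysis imputes
missing values (LOCF with arm-day-median fallback), derives the blood
indices (NLR/LMR/PLR/SII/CD4:CD8) and applies normality-routed paired tests
between baseline and day 22.
"""

from alpbpk import (
    add_derived_indices,
    impute_missing,
    panel_comparisons,
)
from alpbpk.synthetic import ImmunePanelGeneratorSpec, generate_immune_panel

spec = ImmunePanelGeneratorSpec(n_per_arm=16, missing_fraction=0.05, seed=7)
panel, truth = generate_immune_panel(spec)
print(f"panel: {panel.subject.nunique()} subjects × "
      f"{panel.variable.nunique()} variables × days {list(spec.days)}; "
      f"{panel.value.isna().sum()} missing cells")

panel = impute_missing(panel)
print(f"imputed cells: {panel.imputed.sum()}")
panel = add_derived_indices(panel[["subject", "arm", "day", "variable", "value"]])

for arm in ("AL", "placebo"):
    res = panel_comparisons(panel, baseline_day=1, compare_day=22, arm=arm)
    hits = res[res.significant]
    print(f"\n{arm} arm, baseline vs day 22: "
          f"{len(hits)}/{len(res)} variables significant at α=0.05")
    print(hits[["variable", "test", "p_value"]].to_string(index=False))
# In the treated arm the configured cytokine decreases and cell-count
# increases are recovered; the placebo arm shows only chance-level hits.
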