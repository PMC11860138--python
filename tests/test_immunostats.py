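import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from alpbpk import (
    derived_indices,
    impute_missing,
    paired_comparison,
    panel_comparisons,
)
from alpbpk.synthetic import ImmunePanelGeneratorSpec, generate_immune_panel


class TestDerivedIndices:
    def test_sii_direct_arithmetic(self):
        d = derived_indices({"platelets": 250e3, "neutrophils": 4e3,
                             "lymphocytes": 2e3})
        assert d.sii == pytest.approx(500e3)
        assert d.nlr == pytest.approx(2.0)
        assert d.plr == pytest.approx(125.0)

    def test_zero_lymphocytes_yield_missing(self):
        d = derived_indices({"platelets": 250e3, "neutrophils": 4e3,
                             "lymphocytes": 0.0, "monocytes": 500.0})
        assert math.isnan(d.nlr) and math.isnan(d.plr) and math.isnan(d.sii)
        assert d.lmr == 0.0

    def test_balanced_cd4_cd8(self):
        d = derived_indices({"cd4": 800.0, "cd8": 800.0})
        assert d.cd4_cd8_ratio == 1.0

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scale_consistency(self, c):
        base = {"platelets": 250e3, "neutrophils": 4e3, "lymphocytes": 2e3,
                "monocytes": 500.0, "cd4": 900.0, "cd8": 500.0}
        d0 = derived_indices(base)
        d1 = derived_indices({k: v * c for k, v in base.items()})
        assert d1.nlr == pytest.approx(d0.nlr, rel=1e-9)
        assert d1.lmr == pytest.approx(d0.lmr, rel=1e-9)
        assert d1.plr == pytest.approx(d0.plr, rel=1e-9)
        assert d1.cd4_cd8_ratio == pytest.approx(d0.cd4_cd8_ratio, rel=1e-9)
        assert d1.sii == pytest.approx(c * d0.sii, rel=1e-9)


class TestPairedComparison:
    def test_identical_vectors_degenerate(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = paired_comparison(x, x)
        assert res.degenerate and not res.significant

    def test_large_normal_shift_detected(self):
        rng = np.random.default_rng(21)
        base = rng.normal(10, 1, size=30)
        post = base + 2.0 + rng.normal(0, 1, size=30)   # 2-SD shift
        res = paired_comparison(base, post)
        assert res.significant
        assert res.test == "paired-t"

    def test_heavy_tails_route_to_wilcoxon(self):
        rng = np.random.default_rng(22)
        diff = rng.standard_cauchy(40)
        base = rng.normal(10, 1, size=40)
        res = paired_comparison(base, base + diff)
        assert res.test == "wilcoxon-signed-rank"

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_comparison([1.0, 2.0], [2.0, 3.0])

    def test_missing_pairs_dropped(self):
        base = [1.0, 2.0, np.nan, 4.0, 5.0]
        post = [1.5, 2.5, 3.0, np.nan, 5.5]
        res = paired_comparison(base, post)
        assert res.n == 3

    def test_type_one_error_controlled(self):
        """Null rejection rate ≤ 0.07 at α = 0.05 (2000 seeded replicates)."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            base = rng.normal(0, 1, size=15)
            post = base + rng.normal(0, 1, size=15)
            if paired_comparison(base, post).significant:
                rejections += 1
        assert rejections / n_rep <= 0.07


class TestImputation:
    def panel(self):
        rows = []
        for s in ("A", "B"):
            for day in (1, 4, 22):
                rows.append((s, "AL", day, "il6", float(day)))
        return pd.DataFrame(rows, columns=["subject", "arm", "day",
                                           "variable", "value"])

    def test_identity_when_complete(self):
        p = self.panel()
        out = impute_missing(p)
        assert (out["value"] == p["value"]).all()
        assert not out["imputed"].any()

    def test_locf_mid_series(self):
        p = self.panel()
        p.loc[(p.subject == "A") & (p.day == 4), "value"] = np.nan
        out = impute_missing(p)
        filled = out[(out.subject == "A") & (out.day == 4)]["value"].iloc[0]
        assert filled == 1.0          # carried forward from day 1
        assert out[(out.subject == "A") & (out.day == 4)]["imputed"].iloc[0]

    def test_leading_gap_uses_arm_day_median(self):
        p = self.panel()
        p.loc[(p.subject == "A") & (p.day == 1), "value"] = np.nan
        out = impute_missing(p)
        filled = out[(out.subject == "A") & (out.day == 1)]["value"].iloc[0]
        assert filled == 1.0          # median of subject B's day-1 value

    def test_never_alters_observed_cells(self):
        p = self.panel()
        p.loc[(p.subject == "B") & (p.day == 22), "value"] = np.nan
        out = impute_missing(p)
        observed = p["value"].notna()
        assert (out.loc[observed, "value"] == p.loc[observed, "value"]).all()

    def test_entirely_missing_variable_rejected(self):
        p = self.panel()
        p["value"] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(p)


class TestPanelComparisons:
    def test_configured_effects_detected(self):
        spec = ImmunePanelGeneratorSpec(n_per_arm=16, seed=31)
        panel, truth = generate_immune_panel(spec)
        res = panel_comparisons(panel, baseline_day=1, compare_day=22, arm="AL")
        il6 = res[res.variable == "il6"].iloc[0]
        assert il6.significant

    def test_holm_adjustment_is_conservative(self):
        spec = ImmunePanelGeneratorSpec(n_per_arm=16, seed=32)
        panel, _ = generate_immune_panel(spec)
        raw = panel_comparisons(panel, 1, 22)
        holm = panel_comparisons(panel, 1, 22, holm=True)
        assert holm["significant"].sum() <= raw["significant"].sum()
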