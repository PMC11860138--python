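"""Peripheral-blood indices and paired statistics for immune panels.

Panels are long-format tables (subject, arm, day, variable, value) covering
blood counts (neutrophils, lymphocytes, monocytes, platelets), immune cell
subsets (T, B, CD4+, CD8+, NK) and cytokines (IL-2/4/6/10/17A, TNF-α, IFN-γ).
Derived indices follow their standard definitions: NLR, LMR, PLR, the
systemic immune-inflammation index SII = platelets × neutrophils /
lymphocytes, and the CD4+/CD8+ ratio; zero denominators yield missing values
rather than infinities.

Baseline-vs-follow-up comparisons test normality of the paired differences
(Shapiro-Wilk) and route to the paired t-test or the Wilcoxon signed-rank
test accordingly, two-sided at α = 0.05, without multiplicity correction
(a Holm option is available).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DerivedIndices",
    "PairedTestResult",
    "derived_indices",
    "add_derived_indices",
    "paired_comparison",
    "impute_missing",
    "panel_comparisons",
]

PANEL_COLUMNS = ("subject", "arm", "day", "variable", "value")


@dataclass(frozen=True)
class DerivedIndices:
    """Ratio indices; missing inputs or zero denominators give NaN."""

    nlr: float
    lmr: float
    plr: float
    sii: float
    cd4_cd8_ratio: float


def _ratio(num: Optional[float], den: Optional[float]) -> float:
    if num is None or den is None or not np.isfinite(num) or not np.isfinite(den):
        return math.nan
    if den == 0:
        return math.nan
    return num / den


def derived_indices(record: Mapping[str, float]) -> DerivedIndices:
    """Compute NLR/LMR/PLR/SII/CD4:CD8 from a counts mapping.

    Expected keys: neutrophils, lymphocytes, monocytes, platelets, cd4, cd8
    (counts per µL).  Any absent key simply yields NaN for the indices that
    need it.
    """
    get = record.get
    neut, lymp = get("neutrophils"), get("lymphocytes")
    mono, plt_ = get("monocytes"), get("platelets")
    cd4, cd8 = get("cd4"), get("cd8")
    sii = math.nan
    if all(v is not None and np.isfinite(v) for v in (plt_, neut, lymp)) and lymp:
        sii = plt_ * neut / lymp
    return DerivedIndices(
        nlr=_ratio(neut, lymp),
        lmr=_ratio(lymp, mono),
        plr=_ratio(plt_, lymp),
        sii=sii,
        cd4_cd8_ratio=_ratio(cd4, cd8),
    )


def add_derived_indices(panel: pd.DataFrame) -> pd.DataFrame:
    """Append derived-index rows to a long-format panel."""
    wide = panel.pivot_table(index=["subject", "arm", "day"],
                             columns="variable", values="value",
                             aggfunc="first")
    rows = []
    for idx, row in wide.iterrows():
        d = derived_indices(row.to_dict())
        for name, val in (("nlr", d.nlr), ("lmr", d.lmr), ("plr", d.plr),
                          ("sii", d.sii), ("cd4_cd8_ratio", d.cd4_cd8_ratio)):
            rows.append((*idx, name, val))
    extra = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
    return pd.concat([panel, extra], ignore_index=True)


@dataclass(frozen=True)
class PairedTestResult:
    variable: str
    test: str                  # "paired-t" or "wilcoxon-signed-rank"
    p_normality: float
    p_value: float
    significant: bool
    alpha: float
    n: int
    degenerate: bool = False


def paired_comparison(
    baseline: Sequence[float],
    followup: Sequence[float],
    alpha: float = 0.05,
    variable: str = "",
) -> PairedTestResult:
    """Two-sided paired comparison with normality-routed test choice.

    Shapiro-Wilk on the paired differences decides between the paired t-test
    (normal) and the Wilcoxon signed-rank test.  Pairs with missing values
    are dropped; all-zero differences return a degenerate non-significant
    result.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.ndim != 1:
        raise ValueError("baseline and followup must be 1-D of equal length")
    keep = np.isfinite(b) & np.isfinite(f)
    b, f = b[keep], f[keep]
    if len(b) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(b)}")
    diff = f - b
    if np.all(diff == 0):
        return PairedTestResult(variable, "paired-t", 1.0, 1.0, False,
                                alpha, len(b), degenerate=True)
    with warnings.catch_warnings():
        # near-identical samples trigger harmless precision warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        p_norm = float(stats.shapiro(diff).pvalue)
        if p_norm >= alpha:
            test = "paired-t"
            p = float(stats.ttest_rel(f, b).pvalue)
        else:
            test = "wilcoxon-signed-rank"
            p = float(stats.wilcoxon(f, b, zero_method="wilcox").pvalue)
    return PairedTestResult(variable, test, p_norm, p, p < alpha, alpha, len(b))


def impute_missing(
    panel: pd.DataFrame,
    strategy: str = "locf",
    max_missing_fraction: float = 0.2,
) -> pd.DataFrame:
    """Single imputation of missing panel values.

    Last observation carried forward within each (subject, variable) series
    sorted by day, falling back to the arm-day median for leading gaps.
    Imputed cells are flagged in a boolean ``imputed`` column; non-missing
    cells are never altered.
    """
    if strategy != "locf":
        raise ValueError(f"unknown imputation strategy: {strategy!r}")
    df = panel.copy()
    missing = df["value"].isna()
    for var, grp in df.groupby("variable"):
        if grp["value"].isna().all():
            raise ValueError(f"variable {var!r} is entirely missing")
        frac = grp["value"].isna().mean()
        if frac > max_missing_fraction:
            raise ValueError(
                f"variable {var!r} missing fraction {frac:.2f} exceeds "
                f"{max_missing_fraction}"
            )
    df = df.sort_values(["variable", "subject", "day"], kind="stable")
    df["value"] = df.groupby(["variable", "subject"])["value"].ffill()
    # leading gaps: arm-day median of observed values
    med = (panel.dropna(subset=["value"])
           .groupby(["variable", "arm", "day"])["value"].median())
    still = df["value"].isna()
    if still.any():
        keys = list(zip(df.loc[still, "variable"], df.loc[still, "arm"],
                        df.loc[still, "day"]))
        df.loc[still, "value"] = [med.get(k, np.nan) for k in keys]
    df["imputed"] = missing.reindex(df.index)
    return df.sort_index()


def panel_comparisons(
    panel: pd.DataFrame,
    baseline_day: int,
    compare_day: int,
    arm: str = "AL",
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Paired baseline-vs-day comparisons for every variable in one arm."""
    sub = panel[panel["arm"] == arm]
    wide = sub.pivot_table(index=["subject"], columns=["variable", "day"],
                           values="value", aggfunc="first")
    results = []
    for var in sorted(sub["variable"].unique()):
        try:
            base = wide[(var, baseline_day)]
            post = wide[(var, compare_day)]
        except KeyError:
            continue
        try:
            res = paired_comparison(base, post, alpha=alpha, variable=var)
        except ValueError:
            continue
        results.append(res)
    out = pd.DataFrame([{
        "variable": r.variable, "test": r.test, "p_normality": r.p_normality,
        "p_value": r.p_value, "significant": r.significant, "n": r.n,
    } for r in results])
    if holm and len(out):
        order = np.argsort(out["p_value"].values)
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].values[i])
            adj[i] = min(1.0, running)
        out["p_holm"] = adj
        out["significant"] = out["p_holm"] < alpha
    return out
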