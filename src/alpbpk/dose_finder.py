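"""Regimen enumeration and FIH / MTD / phase-2A selection rules.

The candidate grid multiplies a 1000 mg/day base by {1, 2, 4, 6, 8, 10}
(capped at 10 000 mg/day) and splits each total evenly across OD, BID and QID
schedules; explicit extra doses (OD 1500 mg by default at the pipeline level)
can be appended so that doses off the multiplier grid are available to the
phase-2A rule.  Decision rules, applied to population risk summaries:

* FIH — at the configured first-in-human total daily dose (2000 mg), pick the
  frequency with the lowest risk (lexicographic %E then fold-ULN; ties go to
  more divided doses).
* MTD — the highest total daily dose whose mean %E ≤ 5% and fold-ULN < 3;
  ties across frequencies go to the lowest %E.
* Phase 2A — OD regimens at or above the 1000 mg/day immunomodulatory
  efficacy floor with %E ≤ 3% and liver fold ≤ 1.5; up to the two lowest
  qualifying doses strictly above the floor (falling back to at-floor doses
  when none lie above).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .compound import CompoundProperties
from .pbpk import DoseRegimen, PBPKParameterSet, TissuePartitionMap
from .toxicity import enzyme_fold_and_grade
from .vpop import (
    ToxicityConfig,
    VirtualSubject,
    simulate_regimen_population,
)

__all__ = [
    "DecisionCriteria",
    "RegimenReport",
    "RegimenDecision",
    "enumerate_regimens",
    "evaluate_regimens",
    "select_fih",
    "select_mtd",
    "select_phase2a",
]


class DecisionCriteria(BaseModel, frozen=True):
    """Thresholds behind the dose-selection workflow (all doses mg/day)."""

    efficacy_floor_daily_mg: float = Field(default=1000.0, gt=0)
    fih_total_daily_mg: float = Field(default=2000.0, gt=0)
    mtd_max_percent_e: float = Field(default=5.0, gt=0)
    mtd_max_fold_uln: float = Field(default=3.0, gt=0)
    phase2a_max_percent_e: float = Field(default=3.0, gt=0)
    phase2a_max_liver_fold: float = Field(default=1.5, gt=0)
    max_daily_mg: float = Field(default=10000.0, gt=0)
    noael_reference_mg: float = Field(default=5000.0, gt=0)  # informational
    phase2a_frequencies: Tuple[str, ...] = ("OD",)

    @model_validator(mode="after")
    def _check_order(self) -> "DecisionCriteria":
        if self.phase2a_max_percent_e > self.mtd_max_percent_e:
            raise ValueError("phase-2A %E threshold must not exceed the MTD one")
        if self.phase2a_max_liver_fold > self.mtd_max_fold_uln:
            raise ValueError("phase-2A liver threshold must not exceed the MTD one")
        return self


@dataclass(frozen=True)
class RegimenRow:
    regimen: DoseRegimen
    total_daily_mg: float
    percent_e_mean: float
    percent_e_sd: float
    liver_ratio: float
    fold_uln: float
    grade: int
    flags: Dict[str, bool]


@dataclass
class RegimenReport:
    rows: List[RegimenRow]
    criteria: DecisionCriteria

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec = {
                "regimen": f"{r.regimen.frequency} {r.regimen.dose_mg_extract:g} mg",
                "frequency": r.regimen.frequency,
                "dose_mg": r.regimen.dose_mg_extract,
                "total_daily_mg": r.total_daily_mg,
                "percent_e_mean": r.percent_e_mean,
                "percent_e_sd": r.percent_e_sd,
                "liver_ratio": r.liver_ratio,
                "fold_uln": r.fold_uln,
                "grade": r.grade,
            }
            rec.update(r.flags)
            records.append(rec)
        return pd.DataFrame(records)


@dataclass(frozen=True)
class RegimenDecision:
    label: str                      # FIH, MTD or PHASE2A
    selected: Tuple[DoseRegimen, ...]
    rationale: str


def enumerate_regimens(
    base_daily_mg: float = 1000.0,
    multipliers: Sequence[float] = (1, 2, 4, 6, 8, 10),
    frequencies: Sequence[str] = ("OD", "BID", "QID"),
    duration_days: int = 21,
    max_daily_mg: float = 10000.0,
    extras: Sequence[Tuple[str, float]] = (),
) -> List[DoseRegimen]:
    """Build the candidate regimen list.

    ``extras`` holds (frequency, per-administration mg) pairs appended after
    the multiplier grid.  Totals above ``max_daily_mg`` are excluded with a
    warning.
    """
    if base_daily_mg <= 0 or any(m <= 0 for m in multipliers):
        raise ValueError("base dose and multipliers must be positive")
    regimens: List[DoseRegimen] = []
    for freq in frequencies:
        for mult in multipliers:
            total = base_daily_mg * mult
            if total > max_daily_mg:
                warnings.warn(
                    f"{freq} total {total:g} mg/day exceeds the "
                    f"{max_daily_mg:g} mg cap; excluded"
                )
                continue
            regimens.append(DoseRegimen(
                dose_mg_extract=total / {"OD": 1, "BID": 2, "QID": 4}[freq],
                frequency=freq,
                duration_days=duration_days,
            ))
    for freq, dose in extras:
        n = {"OD": 1, "BID": 2, "QID": 4}[freq]
        if dose * n > max_daily_mg:
            warnings.warn(f"extra {freq} {dose:g} mg exceeds the cap; excluded")
            continue
        regimens.append(DoseRegimen(dose_mg_extract=dose, frequency=freq,
                                    duration_days=duration_days))
    return regimens


def evaluate_regimens(
    regimens: Sequence[DoseRegimen],
    population: List[VirtualSubject],
    compound: CompoundProperties,
    partition: TissuePartitionMap,
    params: PBPKParameterSet,
    tox: ToxicityConfig,
    criteria: DecisionCriteria = DecisionCriteria(),
    grid_step: float = 0.05,
) -> RegimenReport:
    """Population risks plus boolean criterion flags for every regimen."""
    cache: Dict = {}
    rows: List[RegimenRow] = []
    for regimen in regimens:
        summary = simulate_regimen_population(
            population, regimen, compound, partition, params, tox,
            grid_step=grid_step, cache=cache)
        fold, grade = enzyme_fold_and_grade(summary.liver_ratio_mean)
        total = regimen.total_daily_mg
        flags = {
            "efficacy_ok": total >= criteria.efficacy_floor_daily_mg,
            "hema_ok_mtd": summary.mean <= criteria.mtd_max_percent_e,
            "liver_ok_mtd": fold < criteria.mtd_max_fold_uln,
            "hema_ok_p2a": summary.mean <= criteria.phase2a_max_percent_e,
            "liver_ok_p2a": fold <= criteria.phase2a_max_liver_fold,
        }
        rows.append(RegimenRow(
            regimen=regimen,
            total_daily_mg=total,
            percent_e_mean=summary.mean,
            percent_e_sd=summary.sd,
            liver_ratio=summary.liver_ratio_mean,
            fold_uln=fold,
            grade=grade,
            flags=flags,
        ))
    return RegimenReport(rows=rows, criteria=criteria)


_FREQ_DIVISIONS = {"OD": 1, "BID": 2, "QID": 4}


def select_fih(report: RegimenReport,
               criteria: Optional[DecisionCriteria] = None) -> RegimenDecision:
    """Minimum-risk frequency at the configured FIH total daily dose."""
    criteria = criteria or report.criteria
    if not report.rows:
        raise ValueError("empty regimen report")
    candidates = [r for r in report.rows
                  if abs(r.total_daily_mg - criteria.fih_total_daily_mg) < 1e-9]
    if not candidates:
        raise ValueError(
            f"no regimen at the FIH total of {criteria.fih_total_daily_mg:g} mg/day"
        )
    best = min(candidates, key=lambda r: (
        r.percent_e_mean, r.fold_uln, -_FREQ_DIVISIONS[r.regimen.frequency]))
    note = ""
    if len(candidates) == 1:
        note = " (only candidate at this total daily dose)"
    rationale = (
        f"Lowest hematological and liver risk among {len(candidates)} "
        f"schedule(s) totalling {criteria.fih_total_daily_mg:g} mg/day: "
        f"%E {best.percent_e_mean:.2f}%, fold-ULN {best.fold_uln:.2f}{note}."
    )
    return RegimenDecision("FIH", (best.regimen,), rationale)


def select_mtd(report: RegimenReport,
               criteria: Optional[DecisionCriteria] = None) -> RegimenDecision:
    """Highest total daily dose meeting both MTD risk ceilings."""
    criteria = criteria or report.criteria
    if not report.rows:
        raise ValueError("empty regimen report")
    ok = [r for r in report.rows
          if r.percent_e_mean <= criteria.mtd_max_percent_e
          and r.fold_uln < criteria.mtd_max_fold_uln]
    if not ok:
        return RegimenDecision(
            "MTD", (),
            f"No regimen satisfies %E ≤ {criteria.mtd_max_percent_e:g}% with "
            f"fold-ULN < {criteria.mtd_max_fold_uln:g}.")
    top_total = max(r.total_daily_mg for r in ok)
    at_top = [r for r in ok if abs(r.total_daily_mg - top_total) < 1e-9]
    best = min(at_top, key=lambda r: r.percent_e_mean)
    rationale = (
        f"Highest tolerated total daily dose {top_total:g} mg "
        f"({best.regimen.frequency} {best.regimen.dose_mg_extract:g} mg): "
        f"%E {best.percent_e_mean:.2f}% ≤ {criteria.mtd_max_percent_e:g}% and "
        f"fold-ULN {best.fold_uln:.2f} < {criteria.mtd_max_fold_uln:g}."
    )
    return RegimenDecision("MTD", (best.regimen,), rationale)


def select_phase2a(report: RegimenReport,
                   criteria: Optional[DecisionCriteria] = None) -> RegimenDecision:
    """Up to two low phase-2A doses meeting efficacy and safety criteria."""
    criteria = criteria or report.criteria
    if not report.rows:
        raise ValueError("empty regimen report")
    ok = [r for r in report.rows
          if r.regimen.frequency in criteria.phase2a_frequencies
          and r.total_daily_mg >= criteria.efficacy_floor_daily_mg
          and r.percent_e_mean <= criteria.phase2a_max_percent_e
          and r.fold_uln <= criteria.phase2a_max_liver_fold]
    if not ok:
        return RegimenDecision(
            "PHASE2A", (),
            "No regimen meets the phase-2A efficacy floor "
            f"({criteria.efficacy_floor_daily_mg:g} mg/day) with %E ≤ "
            f"{criteria.phase2a_max_percent_e:g}% and liver fold ≤ "
            f"{criteria.phase2a_max_liver_fold:g}.")
    above = sorted((r for r in ok
                    if r.total_daily_mg > criteria.efficacy_floor_daily_mg),
                   key=lambda r: r.total_daily_mg)
    pool = above if above else sorted(ok, key=lambda r: r.total_daily_mg)
    chosen = pool[:2]
    doses = ", ".join(f"{r.regimen.frequency} {r.regimen.dose_mg_extract:g} mg"
                      for r in chosen)
    rationale = (
        f"Lowest qualifying daily doses above the "
        f"{criteria.efficacy_floor_daily_mg:g} mg immunomodulatory floor with "
        f"%E ≤ {criteria.phase2a_max_percent_e:g}% and liver fold ≤ "
        f"{criteria.phase2a_max_liver_fold:g}: {doses}."
    )
    return RegimenDecision("PHASE2A", tuple(r.regimen for r in chosen), rationale)
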