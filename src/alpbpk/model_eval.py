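"""Model qualification: AAFE, predictive checks, sensitivity coefficients.

AAFE (absolute average fold error) summarises predicted-vs-observed agreement
as ``10^(mean |log10(pred/obs)|)``; 1.0 is perfect and ≤2-fold is the
conventional acceptance bound for PBPK models.  The virtual predictive check
overlays observed points on empirical percentile bands of a simulated
population.  Normalised sensitivity coefficients measure the elasticity of a
scalar exposure metric to a fractional parameter perturbation
(``%ΔY / %ΔX``, one-sided +20% by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Literal, Sequence, Tuple

import numpy as np

__all__ = [
    "AAFEResult",
    "VPCSummary",
    "SensitivityResult",
    "aafe",
    "vpc",
    "sensitivity_coefficient",
    "compound_sensitivities",
]


@dataclass(frozen=True)
class AAFEResult:
    aafe: float
    n: int
    per_pair_fold_error: Tuple[float, ...]


def aafe(
    predicted: Sequence[float],
    observed: Sequence[float],
    signed: bool = False,
) -> AAFEResult:
    """Absolute average fold error between paired positive values.

    With ``signed=True`` the absolute value is dropped (the literal
    averaged-log form), so over- and under-predictions cancel; the default
    keeps the standard AAFE, which is ≥ 1 and symmetric in pred/obs.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be 1-D and equal length")
    if len(p) < 1:
        raise ValueError("need at least one prediction/observation pair")
    if np.any(p <= 0) or np.any(o <= 0):
        raise ValueError("all values must be strictly positive")
    logs = np.log10(p / o)
    mean_log = np.mean(logs) if signed else np.mean(np.abs(logs))
    return AAFEResult(
        aafe=float(10.0 ** mean_log),
        n=len(p),
        per_pair_fold_error=tuple(10.0 ** np.abs(logs)),
    )


@dataclass(frozen=True)
class VPCSummary:
    """Percentile bands of a simulated population vs observed points."""

    time: np.ndarray
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray
    observed_time: np.ndarray
    observed_conc: np.ndarray
    fraction_observed_in_band: float


def vpc(
    simulated: np.ndarray,
    time: np.ndarray,
    observed_time: Sequence[float],
    observed_conc: Sequence[float],
    percentiles: Tuple[float, float, float] = (5.0, 50.0, 95.0),
    min_subjects: int = 20,
) -> VPCSummary:
    """Virtual predictive check.

    ``simulated`` is (n_subjects, n_times) on the common grid ``time``;
    band limits are interpolated at each observed time to compute the
    fraction of observations falling inside the lower-upper band.
    """
    sims = np.asarray(simulated, dtype=float)
    time = np.asarray(time, dtype=float)
    obs_t = np.asarray(observed_time, dtype=float)
    obs_c = np.asarray(observed_conc, dtype=float)
    if sims.ndim != 2 or sims.shape[0] < min_subjects:
        raise ValueError(f"need a (n≥{min_subjects}) × times simulation matrix")
    if sims.shape[1] != len(time):
        raise ValueError("simulation matrix and time grid disagree")
    if len(obs_t) == 0:
        raise ValueError("no observed points")
    if obs_t.min() > time.max() or obs_t.max() < time.min():
        raise ValueError("observed and simulated time ranges are disjoint")

    lo, med, hi = np.percentile(sims, percentiles, axis=0)
    lo_at = np.interp(obs_t, time, lo)
    hi_at = np.interp(obs_t, time, hi)
    inside = (obs_c >= lo_at - 1e-12) & (obs_c <= hi_at + 1e-12)
    return VPCSummary(
        time=time,
        lower=lo,
        median=med,
        upper=hi,
        observed_time=obs_t,
        observed_conc=obs_c,
        fraction_observed_in_band=float(np.mean(inside)),
    )


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    coefficient: float       # %ΔY / %ΔX
    perturbation: float
    metric: str


def sensitivity_coefficient(
    metric_fn: Callable[[float], float],
    base_value: float,
    parameter: str = "",
    perturbation: float = 0.2,
    metric: str = "auc",
    central: bool = False,
) -> SensitivityResult:
    """Normalised elasticity of ``metric_fn`` at ``base_value``.

    One-sided forward difference by default:
    ``((Y(x·(1+p)) − Y(x)) / Y(x)) / p``; ``central=True`` switches to the
    symmetric ±p difference.
    """
    if perturbation <= 0:
        raise ValueError("perturbation must be positive")
    try:
        y0 = metric_fn(base_value)
        y_up = metric_fn(base_value * (1.0 + perturbation))
        y_dn = metric_fn(base_value * (1.0 - perturbation)) if central else None
    except Exception as exc:  # propagate with context
        raise RuntimeError(f"metric evaluation failed for {parameter!r}") from exc
    if y0 <= 0:
        raise ValueError(f"metric must be positive at base for {parameter!r}")
    if central:
        coef = (y_up - y_dn) / y0 / (2.0 * perturbation)
    else:
        coef = (y_up - y0) / y0 / perturbation
    return SensitivityResult(parameter=parameter, coefficient=float(coef),
                             perturbation=perturbation, metric=metric)


def compound_sensitivities(
    compound,
    physiology,
    partition,
    params,
    regimen=None,
    parameters: Sequence[str] = ("fu", "papp", "rbp", "solubility", "pka"),
    perturbation: float = 0.2,
    metric: Literal["auc_0_last", "cmax"] = "auc_0_last",
    grid_step: float = 0.05,
    central: bool = False,
) -> List[SensitivityResult]:
    """Elasticity of plasma exposure to each compound parameter.

    Re-simulates the PBPK model with the named ``CompoundProperties`` field
    scaled by (1+p) and summarises the plasma profile as AUC0-last (default)
    or Cmax.
    """
    from .nca import auc_0_t
    from .pbpk import DoseRegimen, simulate_pbpk

    if regimen is None:
        regimen = DoseRegimen(dose_mg_extract=1000.0, frequency="OD",
                              duration_days=21)

    def run(compound_mod) -> float:
        profile = simulate_pbpk(compound_mod, physiology, partition, params,
                                regimen, grid_step=grid_step)
        if metric == "cmax":
            return float(np.max(profile.plasma_conc))
        return auc_0_t(profile.time, profile.plasma_conc)

    results = []
    for name in parameters:
        base = getattr(compound, name)

        def metric_fn(value: float, _name=name):
            # fu is a fraction: keep the perturbed model valid
            update = {_name: min(value, 1.0) if _name == "fu" else value}
            return run(compound.model_copy(update=update))

        results.append(sensitivity_coefficient(
            metric_fn, base, parameter=name, perturbation=perturbation,
            metric=metric, central=central,
        ))
    return results
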