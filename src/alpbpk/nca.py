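"""Non-compartmental analysis of plasma concentration-time profiles.

Estimates the five standard parameters — AUC0-inf, Cmax, terminal half-life,
Vz/F and CL/F — from a sampled profile.  The terminal rate constant λz comes
from log-linear regression over the best contiguous tail after Cmax (highest
adjusted R², ties resolved toward more points), AUC uses the linear-up /
log-down trapezoid by default, and AUC0-inf adds the standard Clast/λz tail.

All functions are array-based: they accept explicit ``time``/``conc`` arrays
so any profile source (simulated, synthetic or loaded from CSV) can be
analysed without extra plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Tuple

import numpy as np

__all__ = [
    "LambdaZFit",
    "PKParameters",
    "estimate_lambda_z",
    "auc_0_t",
    "nca_parameters",
]


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression diagnostics."""

    lambda_z: float          # 1/h
    n_points: int
    adjusted_r2: float
    time_window: Tuple[float, float]
    intercept_log: float     # ln-concentration intercept at t=0


@dataclass(frozen=True)
class PKParameters:
    """The five reported NCA outputs plus diagnostics.

    Units follow the clinical table: AUC in µmol·h/L, Cmax in µmol/L,
    t1/2 in h, Vz/F in L/kg, CL/F in L/h/kg.  ``t_half = ln2/lambda_z`` and
    ``vz_f × lambda_z = cl_f`` hold exactly by construction.
    """

    auc_0_inf: float
    cmax: float
    t_half: float
    vz_f: float
    cl_f: float
    lambda_z: float
    extrapolated_fraction: float
    auc_0_last: float
    warnings: Tuple[str, ...] = field(default=())


def _validate_grid(time: np.ndarray, conc: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if time.ndim != 1 or time.shape != conc.shape:
        raise ValueError("time and conc must be 1-D arrays of equal length")
    if np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")
    if np.any(~np.isfinite(conc)):
        raise ValueError("concentrations contain NaN/inf")
    return time, conc


def estimate_lambda_z(
    time: np.ndarray,
    conc: np.ndarray,
    min_points: int = 3,
    r2_threshold: float = 0.80,
) -> LambdaZFit:
    """Fit the terminal elimination rate constant.

    Considers every contiguous tail of ≥ ``min_points`` positive
    concentrations strictly after Cmax (the Cmax point itself is excluded)
    and keeps the fit with the best adjusted R²; exact ties go to the longer
    window.  Raises if no declining tail reaches ``r2_threshold``.
    """
    time, conc = _validate_grid(time, conc)
    i_cmax = int(np.argmax(conc))
    t_tail = time[i_cmax + 1:]
    c_tail = conc[i_cmax + 1:]
    pos = c_tail > 0
    # drop trailing below-quantification zeros entirely; interior nonpositive
    # values simply cannot enter a log fit
    t_tail, c_tail = t_tail[pos], c_tail[pos]
    n = len(t_tail)
    if n < min_points:
        raise ValueError(
            f"only {n} positive post-Cmax points; need at least {min_points}"
        )
    y = np.log(c_tail)

    # Suffix regressions in O(n) via reversed cumulative sums.
    t_r = t_tail[::-1]
    y_r = y[::-1]
    cs_t = np.cumsum(t_r)
    cs_y = np.cumsum(y_r)
    cs_tt = np.cumsum(t_r * t_r)
    cs_ty = np.cumsum(t_r * y_r)
    cs_yy = np.cumsum(y_r * y_r)

    best: Tuple[float, int] = (-np.inf, 0)
    best_fit = None
    for m in range(min_points, n + 1):        # m = suffix length
        st, sy = cs_t[m - 1], cs_y[m - 1]
        stt, sty, syy = cs_tt[m - 1], cs_ty[m - 1], cs_yy[m - 1]
        sxx = stt - st * st / m
        sxy = sty - st * sy / m
        syy_c = syy - sy * sy / m
        if sxx <= 0:
            continue
        slope = sxy / sxx
        if slope >= 0:
            continue
        r2 = 1.0 if syy_c <= 0 else min(1.0, sxy * sxy / (sxx * syy_c))
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2) if m > 2 else r2
        # >= favours longer windows among exact ties (loop ascends in length)
        if adj >= best[0]:
            intercept = (sy - slope * st) / m
            best = (adj, m)
            best_fit = LambdaZFit(
                lambda_z=-slope,
                n_points=m,
                adjusted_r2=adj,
                time_window=(float(t_tail[n - m]), float(t_tail[-1])),
                intercept_log=intercept,
            )
    if best_fit is None or best_fit.adjusted_r2 < r2_threshold:
        raise ValueError(
            "no declining terminal phase found "
            f"(best adjusted R² = {best[0]:.3g}, threshold {r2_threshold})"
        )
    return best_fit


def auc_0_t(
    time: np.ndarray,
    conc: np.ndarray,
    method: Literal["linear", "linear-up-log-down"] = "linear-up-log-down",
) -> float:
    """Trapezoidal AUC over the observed range, µmol·h/L.

    "linear-up-log-down" uses the log trapezoid on strictly declining
    positive segments and the linear rule elsewhere.
    """
    time, conc = _validate_grid(time, conc)
    if len(time) < 2:
        raise ValueError("need at least two time points")
    dt = np.diff(time)
    c1, c2 = conc[:-1], conc[1:]
    linear = 0.5 * (c1 + c2) * dt
    if method == "linear":
        return float(np.sum(linear))
    if method != "linear-up-log-down":
        raise ValueError(f"unknown AUC method: {method!r}")
    down = (c2 < c1) & (c2 > 0)
    seg = linear.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_seg = (c1 - c2) / np.log(c1 / c2) * dt
    seg[down] = log_seg[down]
    return float(np.sum(seg))


def nca_parameters(
    time: np.ndarray,
    conc: np.ndarray,
    dose_umol: float,
    body_weight: float = 60.0,
    auc_method: Literal["linear", "linear-up-log-down"] = "linear-up-log-down",
    min_points: int = 3,
) -> PKParameters:
    """Full NCA: AUC0-inf, Cmax, t1/2, Vz/F and CL/F for one profile.

    ``dose_umol`` is the dose used for the per-kg clearance/volume
    normalisation; which dose convention to use (nominal, active content,
    absorbed) is the caller's choice.
    """
    time, conc = _validate_grid(time, conc)
    if dose_umol <= 0:
        raise ValueError("dose_umol must be positive")
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")

    fit = estimate_lambda_z(time, conc, min_points=min_points)
    pos = conc > 0
    t_last = time[pos][-1]
    c_last = conc[pos][-1]
    sel = time <= t_last + 1e-12
    auc_last = auc_0_t(time[sel], conc[sel], method=auc_method)
    tail = c_last / fit.lambda_z
    auc_inf = auc_last + tail
    extrap = tail / auc_inf

    warnings: List[str] = []
    if extrap > 0.2:
        warnings.append(
            f"extrapolated AUC fraction {extrap:.2f} exceeds 0.2"
        )

    cl_f = dose_umol / auc_inf / body_weight       # L/h/kg
    vz_f = cl_f / fit.lambda_z                     # L/kg
    return PKParameters(
        auc_0_inf=auc_inf,
        cmax=float(np.max(conc)),
        t_half=float(np.log(2) / fit.lambda_z),
        vz_f=vz_f,
        cl_f=cl_f,
        lambda_z=fit.lambda_z,
        extrapolated_fraction=float(extrap),
        auc_0_last=auc_last,
        warnings=tuple(warnings),
    )
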