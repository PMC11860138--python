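"""Hematological and hepatic risk across the once-daily dose ladder.

Anchors the Emax exposure scale to the reported 1.06% risk at OD 1000 mg,
then extrapolates dose-proportionally to the 2-10× doses, alongside the
liver Cmax,u fold over the non-hepatotoxic reference.
"""

from alpbpk import (
    ATRACTYLODIN,
    DEFAULT_KP,
    DEFAULT_PBPK_PARAMS,
    DoseRegimen,
    build_physiology,
    calibrate_exposure_scale,
    emax_risk,
    enzyme_fold_and_grade,
    exposure_metric,
    hepatotoxicity_ratio,
    liver_unbound_cmax,
    simulate_pbpk,
)

compound = ATRACTYLODIN
physiology = build_physiology(60.0, 40.0)


def od_profile(total_mg):
    reg = DoseRegimen(dose_mg_extract=total_mg, frequency="OD",
                      duration_days=21)
    return simulate_pbpk(compound, physiology, DEFAULT_KP,
                         DEFAULT_PBPK_PARAMS, reg)


reference = od_profile(1000.0)
scale = calibrate_exposure_scale(reference, compound.fu,
                                 reference_percent_e=1.06)
ref_liver = liver_unbound_cmax(reference.final_interval(), compound.fu)
print(f"exposure calibration scale: {scale:.1f} "
      "(bridges plasma Cmax,ss × fu to the anchored unbound exposure)")
print(f"{'dose':>9} {'%E':>7} {'liver fold':>11} {'grade':>6}")
for mult in (1, 2, 4, 6, 8, 10):
    profile = od_profile(1000.0 * mult)
    cp_u = exposure_metric(profile, compound.fu,
                           calibration_scale=scale).cp_u_metric
    ratio = hepatotoxicity_ratio(
        liver_unbound_cmax(profile.final_interval(), compound.fu), ref_liver)
    fold, grade = enzyme_fold_and_grade(ratio)
    print(f"{1000 * mult:>6} mg {emax_risk(cp_u):>6.2f}% {fold:>10.2f}× "
          f"{grade:>6}")
# %E grows sublinearly (Emax saturation): 1.06% at 1000 mg rises to ~9.7%
# at 10 000 mg, while the liver fold grows linearly with dose and crosses
# the 3-fold (grade ≥ 2) boundary at 4000 mg/day once-daily.
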