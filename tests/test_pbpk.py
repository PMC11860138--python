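import numpy as np
import pytest

from alpbpk import (
    CalibrationTarget,
    DoseRegimen,
    PBPKParameterSet,
    calibrate_model,
    liver_unbound_cmax,
    predict_nca_parameters,
    simulate_pbpk,
)
from alpbpk.nca import auc_0_t


def single_dose(compound, physiology, partition, params, days=1, step=0.05,
                dose=1000.0, **kw):
    reg = DoseRegimen(dose_mg_extract=dose, frequency="OD", duration_days=days)
    return simulate_pbpk(compound, physiology, partition, params, reg,
                         grid_step=step, **kw)


class TestMassBalance:
    def test_single_dose_conserved(self, compound, physiology, partition, params):
        prof = single_dose(compound, physiology, partition, params)
        assert prof.mass_balance_error() < 1e-3

    def test_multidose_qid_conserved(self, compound, physiology, partition, params):
        reg = DoseRegimen(dose_mg_extract=500.0, frequency="QID", duration_days=3)
        prof = simulate_pbpk(compound, physiology, partition, params, reg)
        assert prof.mass_balance_error() < 1e-3

    def test_near_zero_clearance_retains_absorbed_dose(
            self, compound, physiology, partition, params):
        from alpbpk.compound import dose_to_active_umol
        from alpbpk.pbpk import absorbed_fraction
        slow = params.model_copy(update={"cl_int_hepatic": 1e-6})
        prof = single_dose(compound, physiology, partition, slow, days=1)
        expected = absorbed_fraction(compound, slow) * dose_to_active_umol(
            1000.0, compound)
        in_system = (
            sum(prof.tissue_conc[t][-1] * prof.volumes[t] for t in prof.tissue_conc)
            + prof.arterial_blood_conc[-1] * prof.volumes["arterial"]
            + prof.venous_blood_conc[-1] * prof.volumes["venous"]
            + prof.depot_umol[-1]
        )
        assert in_system == pytest.approx(expected, rel=1e-6)


class TestLinearity:
    def test_dose_doubling_doubles_profile(self, compound, physiology, partition,
                                           params):
        p1 = single_dose(compound, physiology, partition, params)
        p2 = single_dose(compound, physiology, partition, params, dose=2000.0)
        scale = p2.plasma_conc[1:] / p1.plasma_conc[1:]
        assert np.allclose(scale, 2.0, rtol=1e-9)

    def test_auc_dose_proportional(self, compound, physiology, partition, params):
        p1 = single_dose(compound, physiology, partition, params)
        p3 = single_dose(compound, physiology, partition, params, dose=3000.0)
        a1 = auc_0_t(p1.time, p1.plasma_conc)
        a3 = auc_0_t(p3.time, p3.plasma_conc)
        assert a3 / a1 == pytest.approx(3.0, rel=1e-6)

    def test_superposition_of_repeated_doses(self, compound, physiology,
                                             partition, params):
        multi = simulate_pbpk(
            compound, physiology, partition, params,
            DoseRegimen(dose_mg_extract=1000.0, frequency="OD", duration_days=5))
        t = multi.time
        step = t[1] - t[0]
        n = len(t)
        # independent single-dose curve over the full 5-day window, computed
        # directly from the system matrix (no dose-schedule machinery)
        from alpbpk.pbpk import _build_matrix, _IDX, absorbed_fraction
        from alpbpk.compound import dose_to_active_umol
        M = _build_matrix(compound, physiology, partition, params)
        w, V = np.linalg.eig(M)
        Vinv = np.linalg.inv(V)
        x0 = np.zeros(M.shape[0], dtype=complex)
        x0[_IDX["depot"]] = absorbed_fraction(compound, params) * \
            dose_to_active_umol(1000.0, compound)
        c0 = Vinv @ x0
        states = (V @ (np.exp(np.outer(w, t)) * c0[:, None])).real
        single_curve = states[_IDX["venous"]] / physiology.volumes["venous"] / \
            compound.rbp
        expect = np.zeros(n)
        for k in range(5):
            shift = int(round(k * 24.0 / step))
            expect[shift:] += single_curve[:n - shift]
        assert np.allclose(multi.plasma_conc, expect, rtol=1e-8, atol=1e-12)


class TestNumerics:
    def test_grid_refinement_converges(self, compound, physiology, partition,
                                       params):
        coarse = single_dose(compound, physiology, partition, params, step=0.05)
        fine = single_dose(compound, physiology, partition, params, step=0.025)
        cmax_c, cmax_f = coarse.plasma_conc.max(), fine.plasma_conc.max()
        auc_c = auc_0_t(coarse.time, coarse.plasma_conc)
        auc_f = auc_0_t(fine.time, fine.plasma_conc)
        assert abs(cmax_c - cmax_f) / cmax_f < 0.005
        assert abs(auc_c - auc_f) / auc_f < 0.005

    def test_eig_matches_lsoda(self, compound, physiology, partition, params):
        p_eig = single_dose(compound, physiology, partition, params)
        p_ode = single_dose(compound, physiology, partition, params,
                            method="lsoda")
        diff = np.max(np.abs(p_eig.plasma_conc - p_ode.plasma_conc))
        assert diff / p_eig.plasma_conc.max() < 1e-6

    def test_grid_step_must_divide_interval(self, compound, physiology,
                                            partition, params):
        reg = DoseRegimen(dose_mg_extract=1000.0, frequency="OD", duration_days=1)
        with pytest.raises(ValueError, match="divide"):
            simulate_pbpk(compound, physiology, partition, params, reg,
                          grid_step=0.07)

    def test_calibrated_cmax_brackets_clinical_range(self, od1000_profile):
        cmax = od1000_profile.plasma_conc[od1000_profile.time <= 24.0].max()
        assert 0.2 <= cmax <= 0.35


class TestLiverUnboundCmax:
    def test_scales_with_fu(self, od1000_profile):
        full = liver_unbound_cmax(od1000_profile, 1.0)
        half = liver_unbound_cmax(od1000_profile, 0.5)
        assert half == pytest.approx(0.5 * full, rel=1e-12)
        assert full == pytest.approx(np.max(od1000_profile.tissue_conc["liver"]))

    def test_missing_liver_series(self, od1000_profile):
        from alpbpk.pbpk import ConcentrationProfile
        bare = ConcentrationProfile(
            time=od1000_profile.time,
            plasma_conc=od1000_profile.plasma_conc,
            tissue_conc={},
            dose_events=od1000_profile.dose_events,
        )
        with pytest.raises(ValueError, match="liver"):
            liver_unbound_cmax(bare, 0.1)

    def test_matches_fine_grid_oracle(self, compound, physiology, partition,
                                      params):
        coarse = single_dose(compound, physiology, partition, params, step=0.1)
        fine = single_dose(compound, physiology, partition, params, step=0.01)
        assert liver_unbound_cmax(coarse, 0.1) == pytest.approx(
            liver_unbound_cmax(fine, 0.1), rel=0.01)


class TestCalibration:
    def test_round_trip_recovers_parameters(self, compound, physiology, partition):
        truth = PBPKParameterSet(ka=1.5, f_abs=0.5, cl_int_hepatic=600.0,
                                 kp_scalar=1.8)
        pred = predict_nca_parameters(compound, physiology, partition, truth)
        targets = [
            CalibrationTarget("synthetic_day1", "day1", pred["day1"]),
            CalibrationTarget("synthetic_day21", "day21", pred["day21"]),
        ]
        start = PBPKParameterSet(ka=1.95, f_abs=0.4, cl_int_hepatic=780.0,
                                 kp_scalar=1.4)
        res = calibrate_model(targets, compound, physiology, partition,
                              seed=3, n_starts=1, base=start)
        assert res.aafe <= 1.05
        for name in ("ka", "f_abs", "cl_int_hepatic", "kp_scalar"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(truth, name), rel=0.15)

    def test_empty_targets_rejected(self, compound, physiology, partition):
        with pytest.raises(ValueError):
            calibrate_model([], compound, physiology, partition)
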