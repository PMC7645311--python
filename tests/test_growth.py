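"""Growth simulator: intake curve, energy budget, traits, calibration, RFI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from piglca.config import DEFAULT_CONFIG
from piglca.growth import (IntakeCurve, PigProfile, PerformanceTraits,
                           nei_at_age, simulate_growth, compute_traits,
                           calibrate_intake, fit_rfi, initial_composition,
                           bw_from_composition, EnergyDeficitError,
                           ConvergenceError, CalibrationError)
from piglca.io import write_trajectory_csv, read_trajectory_csv


def _profile(curve, rho=0.35, **kw):
    return PigProfile(id="p1", line="X", intake=curve, partition_rho=rho, **kw)


class TestIntakeCurve:
    def test_constant_degenerate(self):
        curve = IntakeCurve(amplitude=20.0, shape=0.0, rate=1e12)
        for age in (1.0, 68.0, 179.0, 400.0):
            assert nei_at_age(curve, age) == pytest.approx(20.0)

    def test_gamma_mode(self):
        # rising before age = shape*rate, falling after
        curve = IntakeCurve(amplitude=1.0, shape=2.0, rate=80.0)
        mode = 160.0
        assert nei_at_age(curve, mode - 1) < nei_at_age(curve, mode)
        assert nei_at_age(curve, mode + 1) < nei_at_age(curve, mode)

    def test_direct_arithmetic(self):
        curve = IntakeCurve(amplitude=1.2, shape=0.9, rate=150.0)
        expected = 1.2 * 100.0 ** 0.9 * math.exp(-100.0 / 150.0)
        assert nei_at_age(curve, 100.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("age", [0.0, -5.0])
    def test_nonpositive_age_rejected(self, age):
        with pytest.raises(ValueError):
            nei_at_age(IntakeCurve(amplitude=1.0, shape=1.0, rate=50.0), age)

    @given(st.floats(0.1, 3.0), st.floats(20.0, 300.0), st.floats(1.0, 390.0))
    @settings(max_examples=50, deadline=None)
    def test_positive_and_finite(self, shape, rate, age):
        v = nei_at_age(IntakeCurve(amplitude=0.01, shape=shape, rate=rate), age)
        assert 0.0 < v < math.inf


class TestSimulation:
    def test_daily_energy_conservation(self, mean_pigs):
        cfg = DEFAULT_CONFIG
        for _, traj, _ in mean_pigs.values():
            rec = traj.records.dropna()
            resid = (rec.nei - rec.nem
                     - (cfg.kj_per_g_protein * rec.pd
                        + cfg.kj_per_g_lipid * rec.ld) / 1000.0)
            assert np.abs(resid).max() < 1e-9

    def test_single_step_partition_closed_form(self, fx):
        # first simulated day: PD = rho * RE * 1000 / 23.6 below any cap
        curve = IntakeCurve(amplitude=20.0, shape=0.0, rate=1e12)
        rho = 0.4
        prof = _profile(curve, rho=rho)
        traj = simulate_growth(prof, fx.diet)
        first = traj.records.iloc[0]
        re = first.nei - first.nem
        assert re > 0
        assert first.pd == pytest.approx(rho * re * 1000.0 / 23.6, rel=1e-12)
        assert first.ld == pytest.approx((re * 1000.0 - 23.6 * first.pd) / 39.7,
                                         rel=1e-12)

    def test_zero_retained_energy_never_converges(self, fx):
        # NEI pinned (just) at maintenance of the start BW: retained energy
        # is ~0, the pig cannot grow and never reaches the target
        nem0 = DEFAULT_CONFIG.nem_coeff * 28.0 ** DEFAULT_CONFIG.nem_exp
        curve = IntakeCurve(amplitude=nem0 * (1 + 1e-6), shape=0.0, rate=1e15)
        with pytest.raises(ConvergenceError):
            simulate_growth(_profile(curve), fx.diet)

    def test_energy_deficit_names_day(self, fx):
        curve = IntakeCurve(amplitude=3.0, shape=0.0, rate=1e12)  # below NEm
        with pytest.raises(EnergyDeficitError, match="day 68"):
            simulate_growth(_profile(curve), fx.diet)

    def test_fine_step_oracle(self, fx, line_specs):
        # daily Euler against a 100x finer integration
        from piglca.synthetic import mean_pig
        prof, traj1, _ = mean_pig(line_specs["HRFI"], fx.diet)
        traj_fine = simulate_growth(prof, fx.diet, step=0.01)
        assert traj1.slaughter_bp == pytest.approx(traj_fine.slaughter_bp, rel=5e-3)
        assert traj1.slaughter_bl == pytest.approx(traj_fine.slaughter_bl, rel=5e-3)
        assert traj1.duration == pytest.approx(traj_fine.duration, rel=5e-3)

    def test_amplitude_monotonicity(self, fx, mean_pigs):
        import dataclasses
        prof, traj, _ = mean_pigs["HRFI"]
        durations = []
        for scale in (1.0, 1.05, 1.10):
            p = dataclasses.replace(
                prof, intake=dataclasses.replace(
                    prof.intake, amplitude=prof.intake.amplitude * scale))
            durations.append(simulate_growth(p, fx.diet).duration)
        assert durations[0] >= durations[1] >= durations[2]

    def test_pd_cap_is_respected(self, fx, mean_pigs):
        import dataclasses
        prof, _, _ = mean_pigs["HRFI"]
        capped = dataclasses.replace(prof, pd_max=100.0)
        traj = simulate_growth(capped, fx.diet)
        assert traj.records.pd.dropna().max() <= 100.0 + 1e-9

    def test_bw_closure_invertible(self):
        bp, bl = initial_composition(28.0, 0.8)
        assert bw_from_composition(bp, bl) == pytest.approx(28.0, abs=1e-9)
        assert bl == pytest.approx(0.8 * bp)


class TestTraits:
    def test_ratio_definitions(self, fx, mean_pigs):
        _, traj, traits = mean_pigs["HRFI"]
        gain = traj.target_bw - traj.start_bw
        assert traits.fcr == pytest.approx(traits.total_fi / gain, rel=1e-12)
        assert traits.adfi == pytest.approx(traits.total_fi / traits.duration,
                                            rel=1e-12)
        assert traits.total_fi == pytest.approx(traj.total_nei / fx.diet.ne_content,
                                                rel=1e-12)
        assert traits.bp_bl_ratio == pytest.approx(traits.bp / traits.bl, rel=1e-12)

    def test_trajectory_csv_roundtrip(self, tmp_path, fx, mean_pigs):
        _, traj, traits = mean_pigs["LRFI"]
        path = tmp_path / "traj.csv"
        write_trajectory_csv(traj, path)
        back = read_trajectory_csv(path)
        again = compute_traits(back, fx.diet, pig_id=traits.id, line=traits.line,
                               bft=traits.bft)
        for fld in ("adg", "adfi", "total_fi", "fcr", "duration", "bp", "bl",
                    "bp_bl_ratio", "mean_pd", "mid_bw"):
            assert getattr(again, fld) == getattr(traits, fld)

    def test_empty_trajectory_rejected(self, fx, mean_pigs):
        import pandas as pd
        _, traj, _ = mean_pigs["LRFI"]
        import dataclasses
        empty = dataclasses.replace(traj, records=pd.DataFrame())
        with pytest.raises(ValueError):
            compute_traits(empty, fx.diet)


class TestCalibration:
    def test_parameter_recovery(self, fx):
        # targets generated from a curve at the default shape/rate are
        # recovered to within 0.5% NEI at probe ages
        true = IntakeCurve(amplitude=0.006, shape=DEFAULT_CONFIG.intake_shape,
                           rate=DEFAULT_CONFIG.intake_rate)
        window = (68.0, 179.0)
        ages = np.arange(68.0, 179.0)
        total_ne = sum(nei_at_age(true, a) for a in ages)
        total_fi = total_ne / fx.diet.ne_content
        adfi = total_fi / (window[1] - window[0])
        fitted = calibrate_intake(adfi, total_fi, window, fx.diet)
        for probe in (70.0, 95.0, 120.0, 150.0, 178.0):
            assert nei_at_age(fitted, probe) == pytest.approx(
                nei_at_age(true, probe), rel=5e-3)

    def test_constant_curve_admissible(self, fx):
        adfi = 2.0
        window = (68.0, 179.0)
        total = adfi * (window[1] - window[0])
        curve = calibrate_intake(adfi, total, window, fx.diet, shape=0.0,
                                 rate=1e9)
        assert nei_at_age(curve, 70.0) == pytest.approx(
            adfi * fx.diet.ne_content, rel=1e-6)

    def test_inconsistent_targets_rejected(self, fx):
        with pytest.raises(ValueError, match="inconsistent"):
            calibrate_intake(2.0, 2 * 2.0 * 111.0, (68.0, 179.0), fx.diet)

    def test_irreconcilable_targets_report_residuals(self, fx):
        # 10% off is within the precondition but cannot be fit to 0.5%
        with pytest.raises(CalibrationError, match="residual"):
            calibrate_intake(2.0, 1.1 * 2.0 * 111.0, (68.0, 179.0), fx.diet)


def _planted_cohort(rng, n=40):
    adg = rng.normal(800, 60, n)
    bft = rng.normal(16, 2, n)
    mbw = rng.normal(70, 3, n) ** 0.6
    resid = rng.normal(0, 0.05, n)
    resid -= resid.mean()
    X = np.column_stack([np.ones(n), adg, bft, mbw])
    beta = np.array([0.3, 1.2e-3, 0.01, 0.04])
    # project the planted residuals out of the column space so they are the
    # exact OLS residuals
    Q, _ = np.linalg.qr(X)
    resid = resid - Q @ (Q.T @ resid)
    adfi = X @ beta + resid
    cohort = [
        PerformanceTraits(id=f"p{i}", line="X", adg=adg[i], adfi=adfi[i],
                          total_fi=adfi[i] * 100, fcr=2.6, duration=100,
                          slaughter_age=168, bp=20, bl=23, bp_bl_ratio=0.87,
                          mean_pd=140, bft=bft[i], start_bw=28, target_bw=115,
                          mid_bw=mbw[i] ** (1 / 0.6))
        for i in range(n)
    ]
    return cohort, resid


class TestRFI:
    def test_planted_residual_recovery(self):
        cohort, resid = _planted_cohort(np.random.default_rng(42))
        out = fit_rfi(cohort)
        assert np.allclose(out.rfi.to_numpy(), resid, atol=1e-8)

    def test_residual_properties(self):
        cohort, _ = _planted_cohort(np.random.default_rng(7))
        out = fit_rfi(cohort)
        rfi = out.rfi.to_numpy()
        adfi = np.array([t.adfi for t in cohort])
        assert abs(rfi.mean()) < 1e-10
        for reg in (np.array([t.adg for t in cohort]),
                    np.array([t.bft for t in cohort]),
                    np.array([t.mid_bw for t in cohort]) ** 0.6):
            assert abs(np.dot(rfi, reg - reg.mean())) < 1e-6
        assert rfi.var() <= adfi.var()

    def test_small_cohort_rejected(self):
        cohort, _ = _planted_cohort(np.random.default_rng(0), n=40)
        with pytest.raises(ValueError):
            fit_rfi(cohort[:5])

    def test_rank_deficient_design_rejected(self):
        cohort, _ = _planted_cohort(np.random.default_rng(1))
        for t in cohort:
            t.bft = 15.0
            t.mid_bw = 70.0
        with pytest.raises(ValueError, match="rank"):
            fit_rfi(cohort)
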