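import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculomet import metrics
from oculomet.metrics import (AntisaccadeParams, AntisaccadeTrialResult,
                              FixationParams, ProsaccadeParams, PursuitParams,
                              assemble_profile, bcea, bcea_from_points,
                              classify_antisaccade_trial,
                              compute_antisaccade_params,
                              compute_fixation_params, compute_pursuit_params)
from oculomet.preprocess import estimate_velocity, remove_artifacts
from oculomet.saccades import DetectionSettings, SaccadeEvent, detect_saccades
from oculomet.synth import simulate_gaze_recording
from oculomet.tasks import AntisaccadeTrial, make_task_battery
from tests.conftest import make_recording


def battery_spec(kind, seed=1):
    return next(s for s in make_task_battery(seed) if s.task_kind == kind)


class TestBCEA:
    def test_degenerate_identical_points_zero(self):
        assert bcea_from_points(np.full(100, 1.0), np.full(100, -2.0)) == 0.0

    def test_closed_form_isotropic_unit_scatter(self):
        # sigma_x = sigma_y = 1, rho = 0 -> 2*pi*2.9957 ~ 18.82 deg^2
        assert bcea(1.0, 1.0, 0.0) == pytest.approx(18.822, abs=0.01)

    def test_monte_carlo_containment(self):
        """The 95% ellipse from the closed form contains 95% of draws."""
        rng = np.random.default_rng(0)
        sx, sy, rho = 1.3, 0.7, 0.4
        cov = [[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]]
        pts = rng.multivariate_normal([0, 0], cov, size=100_000)
        area = bcea(sx, sy, rho)
        # containment: Mahalanobis^2 <= -2 ln(0.05)
        inv = np.linalg.inv(cov)
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        frac = np.mean(d2 <= -2 * np.log(0.05))
        assert frac == pytest.approx(0.95, abs=0.01)
        # and the analytic area of that contour equals the BCEA formula
        assert area == pytest.approx(
            np.pi * (-2 * np.log(0.05)) * sx * sy * np.sqrt(1 - rho**2),
            rel=1e-12)

    def test_estimator_consistent_on_samples(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1.0, 50_000)
        y = rng.normal(0, 1.0, 50_000)
        assert bcea_from_points(x, y) == pytest.approx(18.82, rel=0.03)

    @given(s=st.floats(0.1, 2.0))
    @settings(max_examples=20, deadline=None)
    def test_quadratic_scaling(self, s):
        base = bcea(s, s, 0.0)
        assert bcea(2 * s, 2 * s, 0.0) == pytest.approx(4 * base, rel=1e-9)


class TestFixation:
    def test_planted_intrusion_rate_recovered(self, device_truth):
        truth = dataclasses.replace(device_truth, intrusion_rate_hz=0.5)
        spec = battery_spec("fixation")
        rec, log = simulate_gaze_recording(spec, truth, seed=21)
        rec = remove_artifacts(rec)
        settings = DetectionSettings()
        vel = estimate_velocity(rec, window=settings.velocity_window,
                                method=settings.velocity_method)
        events = detect_saccades(vel, settings, rec=rec)
        params = compute_fixation_params(rec, events, spec)
        n_planted = (log.kind == "intrusion").sum()
        planted_rate = n_planted / (5 * 6.5)
        # Poisson error on the planted count
        assert params.intrusion_rate == pytest.approx(
            planted_rate, abs=3 * np.sqrt(n_planted) / (5 * 6.5))
        assert params.bcea95 > 0


class TestProsaccadeGain:
    def test_gain_is_amplitude_over_eccentricity(self):
        spec = battery_spec("prosaccade")
        trial = spec.trials[0]
        ecc = trial.eccentricity
        # one fitted event landing exactly on target
        ev = SaccadeEvent(onset_s=trial.t_target_on + 0.2,
                          offset_s=trial.t_target_on + 0.25,
                          amplitude_deg=ecc, direction_deg=0.0,
                          peak_vel_dps=300.0)
        rec = make_recording(np.zeros(int(spec.duration_s * 60) + 1))
        params = metrics.compute_prosaccade_params(rec, [ev], spec)
        got = params.gain_short if trial.ecc_class == "short" \
            else params.gain_large
        assert got == pytest.approx(1.0)
        half = SaccadeEvent(onset_s=trial.t_target_on + 0.2,
                            offset_s=trial.t_target_on + 0.25,
                            amplitude_deg=ecc / 2, direction_deg=0.0,
                            peak_vel_dps=300.0)
        params = metrics.compute_prosaccade_params(rec, [half], spec)
        got = params.gain_short if trial.ecc_class == "short" \
            else params.gain_large
        assert got == pytest.approx(0.5)

    def test_no_saccade_in_window_gives_missing_class(self):
        spec = battery_spec("prosaccade")
        rec = make_recording(np.zeros(int(spec.duration_s * 60) + 1))
        params = metrics.compute_prosaccade_params(rec, [], spec)
        assert np.isnan(params.latency_short) and np.isnan(params.gain_large)


def make_anti_trial(side=-1, t_target=2.0):
    return AntisaccadeTrial(
        t_fix_on=0.0, t_target_on=t_target, side=side, t_blank_on=t_target + 0.1,
        t_arrow_on=t_target + 1.3, t_arrow_off=t_target + 1.7,
        t_answer_off=t_target + 6.7, arrow_dir="left")


def ev(onset, dx, offset=None):
    return SaccadeEvent(onset_s=onset, offset_s=offset or onset + 0.05,
                        amplitude_deg=abs(dx),
                        direction_deg=0.0 if dx > 0 else 180.0,
                        peak_vel_dps=300.0)


class TestAntisaccadeClassification:
    def setup_method(self):
        n = int(10 * 60)
        self.rec = make_recording(np.zeros(n))

    def test_saccade_toward_target_is_error(self):
        trial = make_anti_trial(side=-1)
        res = classify_antisaccade_trial(self.rec, [ev(2.25, -8.0)], trial)
        assert res.category == "uncorrected-error"

    def test_error_then_opposite_is_corrected_with_latency(self):
        trial = make_anti_trial(side=-1)
        events = [ev(2.25, -8.0), ev(2.48, +16.0)]
        res = classify_antisaccade_trial(self.rec, events, trial)
        assert res.category == "corrected-error"
        assert res.time_to_correct_ms == pytest.approx(230.0, abs=1e-6)

    def test_saccade_away_from_target_is_correct(self):
        trial = make_anti_trial(side=-1)
        res = classify_antisaccade_trial(self.rec, [ev(2.3, +8.0)], trial)
        assert res.category == "correct"

    def test_no_qualifying_saccade_is_invalid(self):
        trial = make_anti_trial(side=-1)
        res = classify_antisaccade_trial(self.rec, [], trial)
        assert res.category == "invalid"

    def test_classification_partitions_trials(self, device_truth):
        spec = battery_spec("antisaccade")
        truth = dataclasses.replace(device_truth, anti_error_prob=0.4)
        rec, _ = simulate_gaze_recording(spec, truth, seed=13)
        rec = remove_artifacts(rec)
        settings = DetectionSettings()
        vel = estimate_velocity(rec, window=settings.velocity_window,
                                method=settings.velocity_method)
        events = detect_saccades(vel, settings, rec=rec)
        cats = [classify_antisaccade_trial(rec, events, tr).category
                for tr in spec.trials]
        counts = {c: cats.count(c) for c in set(cats)}
        assert sum(counts.values()) == len(spec.trials)
        n_err = counts.get("corrected-error", 0) + counts.get(
            "uncorrected-error", 0)
        assert counts.get("corrected-error", 0) <= n_err


class TestAntisaccadeAggregation:
    def test_counting_example(self):
        results = (
            [AntisaccadeTrialResult("correct", latency_ms=300.0)] * 6
            + [AntisaccadeTrialResult("corrected-error", latency_ms=250.0,
                                      time_to_correct_ms=200.0)] * 3
            + [AntisaccadeTrialResult("uncorrected-error", latency_ms=240.0)]
            + [AntisaccadeTrialResult("invalid")] * 2)
        params = compute_antisaccade_params(results)
        assert params.error_rate == pytest.approx(0.4)
        assert params.correction_rate == pytest.approx(0.75)
        assert params.latency_correct == pytest.approx(300.0)
        assert params.time_to_correct == pytest.approx(200.0)

    def test_zero_errors_gives_structural_missing(self):
        results = [AntisaccadeTrialResult("correct", latency_ms=300.0)] * 5
        params = compute_antisaccade_params(results)
        assert np.isnan(params.correction_rate)
        assert np.isnan(params.time_to_correct)
        assert np.isnan(params.latency_incorrect)


class TestPursuit:
    def run_params(self, truth, seed=5, detect=True):
        spec = battery_spec("pursuit")
        rec, log = simulate_gaze_recording(spec, truth, seed=seed)
        rec = remove_artifacts(rec)
        vel = estimate_velocity(rec)
        if detect:  # realistic path; quiet traces exercise the pure metric
            settings = DetectionSettings()
            vel_det = estimate_velocity(rec, window=settings.velocity_window,
                                        method=settings.velocity_method)
            events = detect_saccades(vel_det, settings, rec=rec)
        else:
            events = []
        return compute_pursuit_params(rec, vel, events, spec), log

    def test_perfect_tracking(self, quiet_truth):
        truth = dataclasses.replace(quiet_truth, pursuit_gain=1.0,
                                    pursuit_lag_deg=0.0)
        params, _ = self.run_params(truth, detect=False)
        assert params.gain == pytest.approx(1.0, abs=0.02)
        assert params.lag < 0.6  # residual step offset only
        assert params.prop_pursuit == pytest.approx(1.0)
        assert params.catchup_count == 0

    def test_planted_gain_recovered_with_catchups(self, device_truth):
        truth = dataclasses.replace(device_truth, pursuit_gain=0.8)
        params, log = self.run_params(truth)
        assert (log.kind == "catchup").any()
        assert params.gain == pytest.approx(0.8, abs=0.05)
        assert params.prop_pursuit < 1.0

    def test_gain_ratio_definition(self, quiet_truth):
        truth = dataclasses.replace(quiet_truth, pursuit_gain=0.8,
                                    catchup_threshold_deg=50.0)
        params, _ = self.run_params(truth, detect=False)
        # eye at 6.92 deg/s on an 8.65 deg/s ramp
        assert params.gain == pytest.approx(0.8, abs=0.02)


class TestProfileAssembly:
    def full_parts(self):
        fx = FixationParams(1.0, 0.5, 2.0)
        ps = ProsaccadeParams(*(float(i) for i in range(1, 9)))
        an = AntisaccadeParams(0.3, 0.5, 300.0, 250.0, 200.0, 450.0)
        pu = PursuitParams(0.9, 0.5, 0.95, 3.0)
        return fx, ps, an, pu

    def test_all_tasks_present_fills_20_slots(self):
        fx, ps, an, pu = self.full_parts()
        prof = assemble_profile(fx, ps, an, pu)
        assert list(prof.index) == list(metrics.PROFILE_COLUMNS) + [
            metrics.OPTIONAL_PROFILE_COLUMN]
        assert prof[list(metrics.PROFILE_COLUMNS)].notna().all()

    def test_missing_task_leaves_slots_nan(self):
        fx, ps, _, pu = self.full_parts()
        prof = assemble_profile(fx, ps, None, pu)
        as_cols = [c for c in metrics.PROFILE_COLUMNS if c.startswith("as_")]
        assert prof[as_cols].isna().all()
        assert prof[["fix_bcea95", "sp_gain"]].notna().all()

    def test_profile_round_trips_through_csv(self, tmp_path):
        import pandas as pd

        from oculomet.io import read_profiles_csv, write_profiles_csv
        fx, ps, an, pu = self.full_parts()
        prof = assemble_profile(fx, ps, None, pu)
        df = pd.DataFrame({"P001": prof}).T
        df.index.name = "participant_id"
        write_profiles_csv(df, tmp_path / "p.csv")
        back = read_profiles_csv(tmp_path / "p.csv")
        pd.testing.assert_frame_equal(back, df)
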