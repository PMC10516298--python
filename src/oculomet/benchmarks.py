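"""Verification benchmarks: planted-truth recovery and oracle checks.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stage, and reports summary quantities.  The independent
oracles (step-up enumeration for the FDR procedure, rank enumeration
for the exact Mann-Whitney p, closed forms for the waveform and the
containment ellipse) are deliberately implemented here by brute force,
separate from the production code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import waveform
from .clinical import compute_composites
from .metrics import PROFILE_COLUMNS, bcea
from .pls import SearchSettings, exhaustive_feature_selection, fit_pls
from .preprocess import GazeRecording, estimate_velocity, remove_artifacts
from .saccades import (DetectionSettings, SaccadeEvent, detect_saccades,
                       fit_events, fit_saccade_waveform)
from .stats import bh_adjust, mannwhitney, spearman, spearman_with_fdr
from .synth import (PlantedOculomotorTruth, SyntheticCohortConfig,
                    simulate_cohort, simulate_saccade_sequence)
from .pipeline import extract_cohort_profiles


def _detection_velocity(rec, settings):
    return estimate_velocity(rec, window=settings.velocity_window,
                             method=settings.velocity_method)


def detection_benchmark(seed: int, n_trials: int = 100,
                        noise_sd: float = 0.33) -> dict:
    """Sensitivity / false alarms / onset error on planted saccades.

    Trials interleave fixation with saccades of 1-12 deg (one forced at
    exactly 1 deg per trial) under device-like noise.
    """
    settings = DetectionSettings()
    truth = PlantedOculomotorTruth(
        noise_sd_deg=noise_sd, fix_sigma_x_deg=0.15, fix_sigma_y_deg=0.15,
        intrusion_rate_hz=0.0, blink_rate_hz=0.0)
    tp = fn = fa = 0
    onset_errors = []
    fix_time = 0.0
    rng = np.random.default_rng(seed)
    for k in range(n_trials):
        amps = rng.uniform(1.0, 12.0, size=8)
        amps[0] = 1.0
        rec, log = simulate_saccade_sequence(
            truth, amps, seed=int(rng.integers(2 ** 31)))
        rec = remove_artifacts(rec)
        events = detect_saccades(_detection_velocity(rec, settings),
                                 settings, rec=rec)
        events = fit_events(rec, events)
        used: set[int] = set()
        for _, gt in log.iterrows():
            hit = next((i for i, e in enumerate(events) if i not in used
                        and e.onset_s < gt.t_offset + 0.05
                        and e.offset_s > gt.t_onset - 0.05), None)
            if hit is not None:
                used.add(hit)
                tp += 1
                onset_errors.append(abs(events[hit].best_onset_s
                                        - gt.t_onset))
            else:
                fn += 1
        fa += len(events) - len(used)
        fix_time += rec.t[-1] - 0.1 * len(log)
    return {
        "sensitivity": tp / (tp + fn),
        "false_alarms_per_s": fa / fix_time,
        "onset_error_median_ms": float(np.median(onset_errors)) * 1e3,
        "n_planted": tp + fn,
    }


def waveform_fit_benchmark(amplitudes=None, eta: float = 500.0,
                           c: float = 6.0) -> dict:
    """Noiseless template saccades: worst-case A and Vp recovery error."""
    if amplitudes is None:
        amplitudes = np.arange(2.0, 15.5, 0.5)
    amp_err = vp_err = 0.0
    for amp in amplitudes:
        vp_true = waveform.main_sequence(amp, eta, c)
        t = np.arange(60) / 60.0
        x = waveform.position(t, 0.45, amp, vp_true)
        rec = GazeRecording(t=t, x=x, y=np.zeros_like(t),
                            valid=np.ones_like(t, dtype=bool))
        ev = SaccadeEvent(
            onset_s=0.43, offset_s=0.45 + waveform.duration(amp, vp_true)
            + 0.02, amplitude_deg=amp, direction_deg=0.0,
            peak_vel_dps=vp_true)
        fit = fit_saccade_waveform(rec, ev, margin_s=0.1)
        amp_err = max(amp_err, abs(fit.amplitude_deg - amp) / amp)
        vp_err = max(vp_err, abs(fit.peak_vel_dps - vp_true) / vp_true)
    return {"amp_max_rel_err_pct": 100 * amp_err,
            "vp_max_rel_err_pct": 100 * vp_err,
            "n_amplitudes": len(list(amplitudes))}


def bcea_benchmark(seed: int, n_samples: int = 100_000) -> dict:
    """Monte-Carlo containment of the closed-form 95% ellipse."""
    rng = np.random.default_rng(seed)
    sx, sy, rho = 1.3, 0.7, 0.4
    cov = np.array([[sx ** 2, rho * sx * sy], [rho * sx * sy, sy ** 2]])
    pts = rng.multivariate_normal([0.0, 0.0], cov, size=n_samples)
    d2 = np.einsum("ij,jk,ik->i", pts, np.linalg.inv(cov), pts)
    containment = float(np.mean(d2 <= -2.0 * np.log(0.05)))
    area_formula = bcea(sx, sy, rho)
    area_contour = float(np.pi * (-2 * np.log(0.05)) * sx * sy
                         * np.sqrt(1 - rho ** 2))
    from .metrics import bcea_from_points
    degenerate = bcea_from_points(np.ones(50), np.ones(50))
    return {"containment": containment,
            "area_rel_err": abs(area_formula - area_contour) / area_contour,
            "degenerate_bcea": degenerate, "n_samples": n_samples}


def cohort_recovery_benchmark(seed: int, n_participants: int = 60) -> dict:
    """End-to-end recovery of planted cohort means.

    Simulates the full task battery for every participant, extracts the
    profile table, and compares extracted cohort means with the planted
    generative values (latency, amplitude gain, peak velocity, pursuit
    gain, intrusion rate, anti-saccade error rate).
    """
    cfg = SyntheticCohortConfig(n_participants=n_participants, seed=seed,
                                missing_task_prob=0.0)
    cohort = simulate_cohort(cfg)
    profiles = extract_cohort_profiles(cohort)
    truths = [cohort.truths[p] for p in profiles.index]

    planted_lat = float(np.mean([t.pro_latency_mean_s for t in truths])) * 1e3
    meas_lat = float(profiles[["ps_latency_short", "ps_latency_large"]]
                     .mean(axis=1).mean())
    planted_gain = float(np.mean([t.amplitude_gain for t in truths]))
    meas_gain = float(profiles[["ps_gain_short", "ps_gain_large"]]
                      .mean(axis=1).mean())
    planted_vp = float(np.mean([
        0.5 * (waveform.main_sequence(t.amplitude_gain * 10, t.eta_dps, t.c_deg)
               + waveform.main_sequence(t.amplitude_gain * 12, t.eta_dps,
                                        t.c_deg)) for t in truths]))
    meas_vp = float(profiles["ps_peak_velocity_large"].mean())
    planted_sp = float(np.mean([t.pursuit_gain for t in truths]))
    meas_sp = float(profiles["sp_gain"].mean())
    planted_intr = float(np.mean([t.intrusion_rate_hz for t in truths]))
    meas_intr = float(profiles["fix_intrusion_rate"].mean())
    planted_err = float(np.mean([t.anti_error_prob for t in truths]))
    meas_err = float(profiles["as_error_rate"].mean())
    return {
        "n": n_participants,
        "latency_err_ms": meas_lat - planted_lat,
        "gain_err": meas_gain - planted_gain,
        "peak_velocity_rel_err": (meas_vp - planted_vp) / planted_vp,
        "pursuit_gain_err": meas_sp - planted_sp,
        "intrusion_rate_err": meas_intr - planted_intr,
        "error_rate_err": meas_err - planted_err,
    }


# --- independent statistics oracles ---------------------------------------

def bh_stepup_bruteforce(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Step-up rejection set by direct enumeration of the largest k."""
    p = np.sort(np.asarray(pvals, float))
    m = len(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[k - 1] <= k * alpha / m + 1e-12:
            k_star = k
    thresh = p[k_star - 1] if k_star else -1.0
    return np.asarray(pvals) <= thresh


def stats_oracle_benchmark(seed: int, n_cases: int = 1000) -> dict:
    """FDR procedure vs brute force; exact Mann-Whitney; Spearman
    invariance under monotone transforms."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_cases):
        m = int(rng.integers(2, 15))
        p = rng.uniform(0, 1, m)
        alpha = float(rng.uniform(0.01, 0.2))
        if not np.array_equal(bh_adjust(p) <= alpha + 1e-12,
                              bh_stepup_bruteforce(p, alpha)):
            mismatches += 1
    _, mw_p = mannwhitney([1, 2, 3], [4, 5, 6])
    x = rng.normal(size=25)
    y = rng.normal(size=25)
    rho1, _, _ = spearman(x, y)
    rho2, _, _ = spearman(np.exp(x), y ** 3)
    return {"bh_mismatch_rate": mismatches / n_cases,
            "mannwhitney_exact_p": mw_p,
            "spearman_monotone_invariance_err": abs(rho1 - rho2),
            "n_cases": n_cases}


def composites_benchmark() -> dict:
    """Hand-computed 3-participant composite oracle."""
    cohort = pd.DataFrame({
        "participant_id": ["a", "b", "c"],
        "age": [40.0, 50.0, 60.0], "edss": [2.0, 3.0, 4.0],
        "sdmt": [40.0, 50.0, 60.0], "ravlt": [44.0, 54.0, 64.0],
        "bvmtr": [18.0, 24.0, 30.0], "t25fw": [4.0, 5.0, 6.0],
        "hpt9": [20.0, 22.0, 25.0]})
    out = compute_composites(cohort)
    bicams_err = float(np.max(np.abs(out["bicams"].values
                                     - np.array([-1.0, 0.0, 1.0]))))
    slower = cohort.copy()
    slower.loc[0, "t25fw"] += 5.0
    out2 = compute_composites(slower)
    msfc_drop = float(out.loc[0, "msfc"] - out2.loc[0, "msfc"])
    return {"bicams_max_abs_err": bicams_err,
            "msfc_drop_when_walk_slows": msfc_drop, "n": 3}


def pls_benchmark(seed: int, n_replicates: int = 100) -> dict:
    """PLS validity: OLS equivalence, planted-feature recovery, R^2."""
    rng = np.random.default_rng(seed)
    # full-component PLS vs normal-equations OLS
    X = rng.normal(size=(80, 6))
    y = X @ rng.normal(size=6) + rng.normal(0, 0.5, 80)
    model = fit_pls(X, y, n_components=6)
    X1 = np.column_stack([np.ones(len(X)), X])
    beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
    ols_diff = float(np.max(np.abs(model.coef_ - beta[1:])))

    recovered = 0
    r2_gaps = []
    settings = SearchSettings(mode="capped", cap_size=4, seed=seed)
    import warnings as _w
    for k in range(n_replicates):
        rep = np.random.default_rng(seed + 1000 + k)
        profiles = pd.DataFrame(rep.normal(size=(100, 12)),
                                columns=[f"par{j}" for j in range(12)])
        age = pd.DataFrame({"age": rep.uniform(30, 70, 100)})
        noise = rep.normal(0, 0.6, 100)
        signal = (1.5 * profiles["par0"] - 1.0 * profiles["par2"]
                  + 0.8 * profiles["par4"]).values
        yk = signal + noise
        planted_r2 = 1.0 - np.var(noise) / np.var(yk)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            res = exhaustive_feature_selection(profiles, yk, "score",
                                               settings, covariates=age)
        if {"par0", "par2", "par4"} <= set(res.features):
            recovered += 1
        r2_gaps.append(res.r2 - planted_r2)
    return {"pls_ols_max_abs_diff": ols_diff,
            "planted_recovery_rate": recovered / n_replicates,
            "r2_minus_planted_mean": float(np.mean(r2_gaps)),
            "n_replicates": n_replicates}


def null_calibration_benchmark(seed: int, n_replicates: int = 200,
                               n: int = 60) -> dict:
    """No planted effects: per-family FDP and selected-model CV-R^2."""
    rng = np.random.default_rng(seed)
    fdps = []
    cv_r2s = []
    settings = SearchSettings(mode="greedy", max_size=5, seed=seed)
    n_params = len(PROFILE_COLUMNS)
    for k in range(n_replicates):
        rep = np.random.default_rng(seed + 5000 + k)
        profiles = pd.DataFrame(rep.normal(size=(n, n_params)),
                                columns=PROFILE_COLUMNS)
        outcome = rep.normal(size=n)
        res = spearman_with_fdr(profiles, pd.DataFrame({"null": outcome}))
        rejections = int(res["significant"].sum())
        fdps.append(1.0 if rejections else 0.0)  # all discoveries are false
        if k < n_replicates // 2:  # model-selection half (costlier)
            sel = exhaustive_feature_selection(
                profiles, outcome, "null", settings,
                covariates=pd.DataFrame({"age": rep.uniform(30, 70, n)}))
            cv_r2s.append(sel.cv_r2)
    fdp_mean = float(np.mean(fdps))
    fdp_se = float(np.std(fdps, ddof=1) / np.sqrt(len(fdps)))
    return {"null_fdp": fdp_mean, "null_fdp_mc_se": fdp_se,
            "null_cv_r2_mean": float(np.mean(cv_r2s)),
            "n_replicates": n_replicates}
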