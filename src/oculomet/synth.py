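"""Synthetic cohort generator: gaze traces with planted oculomotor truth.

No patient gaze data are distributed, so every downstream stage is
exercised on simulated recordings whose generative parameters are known
exactly.  The generator plants

* saccades drawn from the same parametric waveform family the fitter
  uses (closed under fit, so parameters are exactly identifiable),
* latency distributions per task, amplitude (hypometria) gain,
* fixational scatter as a slow bivariate Ornstein-Uhlenbeck (AR(1))
  wander with stationary covariance (sigma_x, sigma_y, rho),
* square-wave-jerk intrusion pairs at Poisson times (outgoing plus a
  return saccade 200 ms later),
* anti-saccade direction errors/corrections as Bernoulli draws,
* step-ramp pursuit at gain x target velocity with catch-up saccades
  fired whenever the positional error exceeds a threshold,
* blink gaps (invalid samples) at Poisson times, and
* white Gaussian sensor noise (default 0.33 deg RMS, the precision of
  the tablet gaze tracker being emulated) plus an optional constant
  accuracy offset (default magnitude 0 here; the device figure is
  0.47 deg).

Clinical scores are monotone functions of a latent severity plus
truncated Gaussian noise, with signs matching the published direction
of each association (higher severity: longer latencies, lower peak
velocity, larger fixation scatter, more intrusions, more anti-saccade
errors, lower pursuit gain, worse clinical scores).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tasks as task_mod
from . import waveform
from .preprocess import GazeRecording
from .tasks import TaskSpec, make_task_battery

SCATTER_TAU_S = 0.3          # fixational-wander time constant
SWJ_RETURN_DELAY_S = 0.200   # square-wave-jerk inter-pair interval
PURSUIT_ONSET_LATENCY_S = 0.200
CORRECTIVE_LATENCY_S = 0.180
ANSWER_LATENCY_S = 0.300


class ConfigError(ValueError):
    """Raised for invalid cohort/effect-map configuration."""


@dataclass
class PlantedOculomotorTruth:
    """Per-participant generative oculomotor parameters."""

    pro_latency_mean_s: float = 0.200
    pro_latency_sd_s: float = 0.030
    anti_correct_latency_mean_s: float = 0.280
    anti_incorrect_latency_mean_s: float = 0.220
    anti_latency_sd_s: float = 0.040
    anti_time_to_correct_mean_s: float = 0.220
    anti_time_to_correct_sd_s: float = 0.050
    eta_dps: float = waveform.DEFAULT_ETA
    c_deg: float = waveform.DEFAULT_C
    amplitude_gain: float = 0.95
    fix_sigma_x_deg: float = 0.40
    fix_sigma_y_deg: float = 0.40
    fix_rho: float = 0.0
    intrusion_rate_hz: float = 0.3       # detected-event rate (pairs fire at half this)
    intrusion_amplitude_deg: float = 1.8
    anti_error_prob: float = 0.20
    anti_correction_prob: float = 0.80
    pursuit_gain: float = 0.95
    pursuit_lag_deg: float = 0.5
    catchup_threshold_deg: float = 1.8  # catch-ups land ~1-1.6 deg, as in practice
    blink_rate_hz: float = 0.05
    blink_dur_range_s: tuple = (0.100, 0.300)
    noise_sd_deg: float = 0.33
    bias_deg: float = 0.0

    def __post_init__(self):
        if min(self.intrusion_rate_hz, self.blink_rate_hz,
               self.pursuit_gain, self.amplitude_gain) < 0:
            raise ValueError("rates and gains must be non-negative")
        for p in (self.anti_error_prob, self.anti_correction_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.eta_dps <= 0 or self.c_deg <= 0:
            raise ValueError("main-sequence eta and c must be positive")
        if not abs(self.fix_rho) < 1.0:
            raise ValueError("|fixation scatter correlation| must be < 1")


class _TraceBuilder:
    """Accumulates a gaze trajectory as a superposition of primitives."""

    def __init__(self, duration_s: float, truth: PlantedOculomotorTruth,
                 rng: np.random.Generator, rate_hz: float = 60.0):
        if duration_s <= 0:
            raise ConfigError("spec duration must be positive")
        self.rate = rate_hz
        self.n = int(round(duration_s * rate_hz)) + 1
        self.t = np.arange(self.n) / rate_hz
        self.pos = np.zeros((self.n, 2))
        self.cur = np.zeros(2)
        self.truth = truth
        self.rng = rng
        self.events: list[dict] = []

    def saccade_to(self, t0: float, target, kind: str, trial: int,
                   gain: float = 1.0) -> float:
        """Plant a saccade from the current position toward ``target``.

        Amplitude is ``gain`` times the distance to the target; returns
        the saccade offset time.  Sub-resolution moves are skipped.
        """
        vec = gain * (np.asarray(target, float) - self.cur)
        amp = float(np.hypot(*vec))
        if amp < 0.05 or t0 >= self.t[-1]:
            return t0
        vp = waveform.main_sequence(amp, self.truth.eta_dps, self.truth.c_deg)
        dur = waveform.duration(amp, vp)
        i0 = np.searchsorted(self.t, t0)
        i1 = np.searchsorted(self.t, t0 + dur)
        unit = vec / amp
        if i1 > i0:
            prof = waveform.position(self.t[i0:i1], t0, amp, vp)
            self.pos[i0:i1] += prof[:, None] * unit[None, :]
        self.pos[i1:] += vec
        start = self.cur.copy()
        self.cur = self.cur + vec
        self.events.append(dict(
            kind=kind, trial=trial, t_onset=t0, t_offset=t0 + dur,
            amplitude_deg=amp, peak_vel_dps=vp,
            x0=start[0], y0=start[1], x1=self.cur[0], y1=self.cur[1]))
        return t0 + dur

    def ramp(self, t_start: float, t_end: float, velocity_vec) -> None:
        """Constant-velocity drift of the eye between two times."""
        v = np.asarray(velocity_vec, float)
        i0 = np.searchsorted(self.t, t_start)
        i1 = np.searchsorted(self.t, t_end)
        if i1 > i0:
            self.pos[i0:i1] += np.outer(self.t[i0:i1] - t_start, v)
        self.pos[i1:] += v * (t_end - t_start)
        self.cur = self.cur + v * (t_end - t_start)

    def _scatter(self) -> np.ndarray:
        tr = self.truth
        sx, sy, rho = tr.fix_sigma_x_deg, tr.fix_sigma_y_deg, tr.fix_rho
        if sx <= 0 and sy <= 0:
            return np.zeros((self.n, 2))
        cov = np.array([[sx ** 2, rho * sx * sy], [rho * sx * sy, sy ** 2]])
        # guard the Cholesky when one sigma is exactly zero
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
        from scipy.signal import lfilter

        a = np.exp(-1.0 / (self.rate * SCATTER_TAU_S))
        e = self.rng.standard_normal((self.n, 2)) @ L.T
        x = np.sqrt(1.0 - a * a) * e
        x[0] = e[0]  # stationary start
        return lfilter([1.0], [1.0, -a], x, axis=0)

    def finalize(self, participant_id: str = "", task_id: str = "") \
            -> tuple[GazeRecording, pd.DataFrame]:
        tr = self.truth
        pos = self.pos + self._scatter()
        if tr.noise_sd_deg > 0:
            pos = pos + self.rng.normal(0.0, tr.noise_sd_deg, size=pos.shape)
        if tr.bias_deg > 0:
            ang = self.rng.uniform(0, 2 * np.pi)
            pos = pos + tr.bias_deg * np.array([np.cos(ang), np.sin(ang)])
        valid = np.ones(self.n, dtype=bool)
        if tr.blink_rate_hz > 0:
            t_blink = self.t[-1] * np.sort(
                self.rng.uniform(size=self.rng.poisson(
                    tr.blink_rate_hz * self.t[-1])))
            for tb in t_blink:
                dur = self.rng.uniform(*tr.blink_dur_range_s)
                i0 = np.searchsorted(self.t, tb)
                i1 = np.searchsorted(self.t, tb + dur)
                valid[i0:i1] = False
        pos[~valid] = np.nan
        rec = GazeRecording(t=self.t, x=pos[:, 0], y=pos[:, 1], valid=valid,
                            rate_hz=self.rate, participant_id=participant_id,
                            task_id=task_id)
        log = pd.DataFrame(self.events, columns=[
            "kind", "trial", "t_onset", "t_offset", "amplitude_deg",
            "peak_vel_dps", "x0", "y0", "x1", "y1"])
        return rec, log


def _simulate_fixation(b: _TraceBuilder, spec: TaskSpec) -> None:
    tr, rng = b.truth, b.rng
    for idx, trial in enumerate(spec.trials):
        target = np.array([trial.x, trial.y])
        if np.hypot(*(target - b.cur)) > 0.3:
            lat = max(0.08, rng.normal(tr.pro_latency_mean_s, tr.pro_latency_sd_s))
            b.saccade_to(trial.t_on + lat, target, "acquisition", idx)
        if tr.intrusion_rate_hz > 0:
            lo, hi = trial.t_on + 0.8, trial.t_off - SWJ_RETURN_DELAY_S - 0.1
            n_pairs = rng.poisson(0.5 * tr.intrusion_rate_hz * max(hi - lo, 0))
            for tp in np.sort(rng.uniform(lo, hi, size=n_pairs)):
                amp = tr.intrusion_amplitude_deg * rng.uniform(0.8, 1.2)
                ang = rng.uniform(0, 2 * np.pi)
                dest = b.cur + amp * np.array([np.cos(ang), np.sin(ang)])
                back = b.cur.copy()
                b.saccade_to(tp, dest, "intrusion", idx)
                b.saccade_to(tp + SWJ_RETURN_DELAY_S, back, "intrusion", idx)


def _simulate_prosaccade(b: _TraceBuilder, spec: TaskSpec) -> None:
    tr, rng = b.truth, b.rng
    for idx, trial in enumerate(spec.trials):
        if np.hypot(*b.cur) > 0.3:  # re-acquire the central fixation point
            lat = max(0.08, rng.normal(tr.pro_latency_mean_s, tr.pro_latency_sd_s))
            b.saccade_to(trial.t_fix_on + lat, (0.0, 0.0), "refixation", idx)
        target = np.array([trial.target_x, trial.target_y])
        lat = max(0.08, rng.normal(tr.pro_latency_mean_s, tr.pro_latency_sd_s))
        t_end = b.saccade_to(trial.t_target_on + lat, target, "primary", idx,
                             gain=tr.amplitude_gain)
        if np.hypot(*(target - b.cur)) > 0.5:
            b.saccade_to(t_end + CORRECTIVE_LATENCY_S, target, "corrective",
                         idx, gain=0.9)


def _simulate_antisaccade(b: _TraceBuilder, spec: TaskSpec) -> None:
    tr, rng = b.truth, b.rng
    ecc = task_mod.ANTISACCADE_ECC_DEG
    for idx, trial in enumerate(spec.trials):
        if np.hypot(*b.cur) > 0.3:
            lat = max(0.08, rng.normal(tr.pro_latency_mean_s, tr.pro_latency_sd_s))
            b.saccade_to(trial.t_fix_on + lat, (0.0, 0.0), "refixation", idx)
        anti_target = np.array([-trial.side * ecc, 0.0])
        pro_target = np.array([trial.side * ecc, 0.0])
        if rng.uniform() < tr.anti_error_prob:
            lat = max(0.08, rng.normal(tr.anti_incorrect_latency_mean_s,
                                       tr.anti_latency_sd_s))
            t_end = b.saccade_to(trial.t_target_on + lat, pro_target,
                                 "anti_error", idx, gain=tr.amplitude_gain)
            if rng.uniform() < tr.anti_correction_prob:
                ttc = max(0.08, rng.normal(tr.anti_time_to_correct_mean_s,
                                           tr.anti_time_to_correct_sd_s))
                b.saccade_to(trial.t_target_on + lat + ttc, anti_target,
                             "anti_correction", idx, gain=tr.amplitude_gain)
        else:
            lat = max(0.08, rng.normal(tr.anti_correct_latency_mean_s,
                                       tr.anti_latency_sd_s))
            b.saccade_to(trial.t_target_on + lat, anti_target, "anti_correct",
                         idx, gain=tr.amplitude_gain)
        # perceptual answer: orient toward the reported arrow direction
        offsets = {"left": (-8.0, 0.0), "right": (8.0, 0.0),
                   "up": (0.0, 8.0), "down": (0.0, -8.0)}
        b.saccade_to(trial.t_arrow_off + ANSWER_LATENCY_S,
                     offsets[trial.arrow_dir], "answer", idx)


def _simulate_pursuit(b: _TraceBuilder, spec: TaskSpec) -> None:
    tr, rng = b.truth, b.rng
    for idx, trial in enumerate(spec.trials):
        if np.hypot(*b.cur) > 0.3:
            lat = max(0.08, rng.normal(tr.pro_latency_mean_s, tr.pro_latency_sd_s))
            b.saccade_to(trial.t_fix_on + lat, (0.0, 0.0), "refixation", idx)
        d = np.array([trial.dir_x, trial.dir_y])
        v_t, g = trial.velocity_dps, tr.pursuit_gain
        t_on = trial.t_ramp_on + PURSUIT_ONSET_LATENCY_S
        t_end = trial.t_ramp_off
        if t_on >= t_end:
            continue
        # walk the ramp in continuous time, firing a catch-up saccade
        # whenever the along-track error exceeds the planted threshold
        eye_r = float(b.cur @ d)
        t_now = t_on
        err_rate = (1.0 - g) * v_t
        while t_now < t_end:
            target_r = -trial.step_deg + v_t * (t_now - trial.t_ramp_on)
            err = target_r - eye_r
            if err_rate <= 1e-9:
                t_hit = np.inf
            else:
                # never step backwards: if already past threshold, fire now
                t_hit = max(t_now + 1e-3,
                            t_now + (tr.catchup_threshold_deg - err) / err_rate)
            if t_hit >= t_end:
                b.ramp(t_now, t_end, g * v_t * d)
                eye_r += g * v_t * (t_end - t_now)
                break
            b.ramp(t_now, t_hit, g * v_t * d)
            eye_r += g * v_t * (t_hit - t_now)
            target_hit = -trial.step_deg + v_t * (t_hit - trial.t_ramp_on)
            dest_r = target_hit - tr.pursuit_lag_deg
            b.saccade_to(t_hit, dest_r * d + b.cur - (b.cur @ d) * d,
                         "catchup", idx)
            eye_r = float(b.cur @ d)
            t_now = t_hit


_SIMULATORS = {
    "fixation": _simulate_fixation,
    "prosaccade": _simulate_prosaccade,
    "antisaccade": _simulate_antisaccade,
    "pursuit": _simulate_pursuit,
}


def simulate_gaze_recording(spec: TaskSpec, truth: PlantedOculomotorTruth,
                            seed: int, rate_hz: float = 60.0,
                            participant_id: str = "") \
        -> tuple[GazeRecording, pd.DataFrame]:
    """Simulate one 60 Hz task run; returns (recording, ground-truth log).

    The log records every generated saccade with its exact continuous
    onset/offset/amplitude, before sampling and noise.
    """
    if spec.task_kind not in _SIMULATORS:
        raise ConfigError(f"unknown task kind {spec.task_kind!r}")
    rng = np.random.default_rng(seed)
    b = _TraceBuilder(spec.duration_s, truth, rng, rate_hz=rate_hz)
    _SIMULATORS[spec.task_kind](b, spec)
    return b.finalize(participant_id=participant_id, task_id=spec.task_kind)


def simulate_saccade_sequence(truth: PlantedOculomotorTruth, amplitudes,
                              seed: int, interval_s: float = 1.0,
                              settle_s: float = 1.0, rate_hz: float = 60.0) \
        -> tuple[GazeRecording, pd.DataFrame]:
    """Fixation interleaved with planted saccades of given amplitudes.

    A plain benchmark trace for detector evaluation: the eye rests at
    the center, makes one saccade of each requested amplitude (out and
    back alternately, random direction) every ``interval_s``.
    """
    rng = np.random.default_rng(seed)
    amplitudes = np.asarray(amplitudes, float)
    duration = settle_s + interval_s * len(amplitudes) + settle_s
    b = _TraceBuilder(duration, truth, rng, rate_hz=rate_hz)
    for i, amp in enumerate(amplitudes):
        t0 = settle_s + i * interval_s
        r = float(np.hypot(*b.cur))
        if r > 3.0:  # pull back toward center, amplitude exactly as requested
            unit = -b.cur / r
        else:
            ang = rng.uniform(0, 2 * np.pi)
            unit = np.array([np.cos(ang), np.sin(ang)])
        b.saccade_to(t0, b.cur + amp * unit, "planted", i)
    return b.finalize(task_id="benchmark")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# severity -> truth-field effects: value = base + slope * severity
# (+ between-subject jitter).  Signs follow the published directions.
DEFAULT_TRUTH_EFFECTS: dict[str, tuple[float, float]] = {
    "pro_latency_mean_s": (0.190, 0.100),
    "anti_correct_latency_mean_s": (0.260, 0.120),
    "anti_incorrect_latency_mean_s": (0.200, 0.080),
    "anti_time_to_correct_mean_s": (0.200, 0.150),
    "eta_dps": (560.0, -160.0),
    "amplitude_gain": (1.00, -0.120),
    "fix_sigma_x_deg": (0.30, 0.45),
    "fix_sigma_y_deg": (0.30, 0.45),
    "intrusion_rate_hz": (0.20, 0.80),
    "intrusion_amplitude_deg": (1.50, 1.00),
    "anti_error_prob": (0.10, 0.45),
    "anti_correction_prob": (0.95, -0.35),
    "pursuit_gain": (0.97, -0.25),
    "pursuit_lag_deg": (0.20, 0.60),
}

# severity -> clinical score: (base, slope, noise_sd, lo, hi)
DEFAULT_CLINICAL_EFFECTS: dict[str, tuple] = {
    "age": (45.0, 12.0, 9.0, 26.0, 74.0),
    "sdmt": (62.0, -25.0, 6.0, 10.0, 80.0),
    "ravlt": (63.0, -18.0, 6.0, 15.0, 75.0),
    "bvmtr": (30.0, -12.0, 3.5, 5.0, 36.0),
    "t25fw": (3.5, 14.0, 1.5, 2.8, 180.0),
    "hpt9": (19.0, 28.0, 2.0, 17.0, 170.0),
}


@dataclass
class SyntheticCohortConfig:
    """Study conditions for a synthetic cohort."""

    n_participants: int = 60
    seed: int = 0
    severities: np.ndarray | None = None   # explicit latent values, else U(0,1)
    truth_effects: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH_EFFECTS))
    clinical_effects: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS))
    edss_base: float = 1.0
    edss_slope: float = 6.5
    edss_noise_sd: float = 0.4
    between_subject_sd_frac: float = 0.15
    truth_overrides: dict = field(default_factory=dict)
    missing_task_prob: float = 0.03
    simulate_gaze: bool = True
    rate_hz: float = 60.0
    antisaccade_trials: int = task_mod.ANTISACCADE_N_TRIALS
    pursuit_velocity_dps: float = task_mod.PURSUIT_VELOCITY_DPS

    def __post_init__(self):
        if self.n_participants < 2:
            raise ConfigError("need at least 2 participants")
        valid_fields = {f.name for f in dataclasses.fields(PlantedOculomotorTruth)}
        for key in list(self.truth_effects) + list(self.truth_overrides):
            if key not in valid_fields:
                raise ConfigError(f"effect map references unknown truth "
                                  f"parameter {key!r}")


_TRUTH_CLIPS = {
    "amplitude_gain": (0.3, 1.2), "pursuit_gain": (0.05, 1.2),
    "anti_error_prob": (0.0, 1.0), "anti_correction_prob": (0.0, 1.0),
    "fix_sigma_x_deg": (0.05, 3.0), "fix_sigma_y_deg": (0.05, 3.0),
    "intrusion_rate_hz": (0.0, 3.0), "intrusion_amplitude_deg": (0.6, 5.0),
    "eta_dps": (100.0, 1100.0),
}


def _quantize_edss(value: np.ndarray) -> np.ndarray:
    return np.clip(np.round(np.asarray(value) * 2.0) / 2.0, 0.0, 10.0)


def truth_for_severity(severity: float, config: SyntheticCohortConfig,
                       rng: np.random.Generator) -> PlantedOculomotorTruth:
    """Map a latent severity to a participant's planted truth."""
    values = {}
    for name, (base, slope) in config.truth_effects.items():
        v = base + slope * severity
        if config.between_subject_sd_frac > 0 and slope != 0:
            v += rng.normal(0.0, config.between_subject_sd_frac * abs(slope))
        if name in _TRUTH_CLIPS:
            v = float(np.clip(v, *_TRUTH_CLIPS[name]))
        values[name] = v
    values.update(config.truth_overrides)
    return PlantedOculomotorTruth(**values)


@dataclass
class SyntheticCohort:
    clinical: pd.DataFrame
    truths: dict
    severities: pd.Series
    recordings: dict  # pid -> task_kind -> (spec, recording, truth log)


def simulate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic per master seed."""
    master = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    n = config.n_participants
    if config.severities is not None:
        sev = np.asarray(config.severities, float)
        if len(sev) != n:
            raise ConfigError("severities length must equal n_participants")
    else:
        sev = rng.uniform(0.0, 1.0, size=n)

    rows, truths, recordings = [], {}, {}
    child_seeds = master.spawn(n)
    for i in range(n):
        pid = f"P{i + 1:03d}"
        prng = np.random.default_rng(child_seeds[i])
        row = {"participant_id": pid}
        edss = config.edss_base + config.edss_slope * sev[i]
        if config.edss_noise_sd > 0:
            edss += prng.normal(0.0, config.edss_noise_sd)
        row["edss"] = float(_quantize_edss(edss))
        for name, (base, slope, sd, lo, hi) in config.clinical_effects.items():
            v = base + slope * sev[i]
            if sd > 0:
                v += prng.normal(0.0, sd)
            row[name] = float(np.clip(v, lo, hi))
        rows.append(row)
        truth = truth_for_severity(sev[i], config, prng)
        truths[pid] = truth
        if config.simulate_gaze:
            battery = make_task_battery(
                int(prng.integers(2 ** 31)),
                pursuit_velocity_dps=config.pursuit_velocity_dps,
                antisaccade_trials=config.antisaccade_trials)
            per_task = {}
            for spec in battery:
                if prng.uniform() < config.missing_task_prob:
                    continue
                rec, log = simulate_gaze_recording(
                    spec, truth, int(prng.integers(2 ** 31)),
                    rate_hz=config.rate_hz, participant_id=pid)
                per_task[spec.task_kind] = (spec, rec, log)
            recordings[pid] = per_task

    cols = ["participant_id", "age", "edss", "sdmt", "ravlt", "bvmtr",
            "t25fw", "hpt9"]
    clinical = pd.DataFrame(rows)[cols]
    return SyntheticCohort(clinical=clinical, truths=truths,
                           severities=pd.Series(sev, index=clinical["participant_id"].values),
                           recordings=recordings)
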