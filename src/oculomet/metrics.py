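"""Per-task oculomotor parameters: the canonical 20(+1)-slot profile.

Fixation (3): BCEA95, saccadic-intrusion rate, intrusion amplitude.
Pro-saccade (8): latency, time-to-target, peak velocity, amplitude gain
    -- each averaged separately over short- and large-eccentricity targets.
Anti-saccade (5 + optional): direction error rate, correction rate,
    correct/incorrect-direction latency, time-to-correct (plus an
    optional time-to-target slot).
Pursuit (4): velocity gain, lag, proportion of time in pursuit,
    catch-up saccade count.

Missingness is structural (e.g., no error trials -> no correction
rate) and always explicit as NaN; the profile never silently drops a
slot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import GazeRecording, VelocityTrace
from .saccades import SaccadeEvent
from .tasks import TaskSpec

BCEA_COVERAGE = 0.95
BCEA_K = -np.log(1.0 - BCEA_COVERAGE)  # chi^2_2 quantile / 2 ~ 2.9957

LATENCY_WINDOW_S = (0.080, 0.800)
TARGET_RADIUS_DEG = 2.0
TARGET_DWELL_S = 0.100
MIN_SACCADE_AMP_DEG = 1.0   # qualifying response saccade
FIX_ACQUIRE_S = 0.5         # settle time excluded at each fixation-trial start
MIN_FIX_VALID_S = 1.0
PURSUIT_SETTLE_S = 0.25     # open-loop onset excluded from the ramp window

PROFILE_COLUMNS: tuple[str, ...] = (
    "fix_bcea95",
    "fix_intrusion_rate",
    "fix_intrusion_amplitude",
    "ps_latency_short",
    "ps_latency_large",
    "ps_time_to_target_short",
    "ps_time_to_target_large",
    "ps_peak_velocity_short",
    "ps_peak_velocity_large",
    "ps_gain_short",
    "ps_gain_large",
    "as_error_rate",
    "as_correction_rate",
    "as_latency_correct",
    "as_latency_incorrect",
    "as_time_to_correct",
    "sp_gain",
    "sp_lag",
    "sp_prop_pursuit",
    "sp_catchup_count",
)
OPTIONAL_PROFILE_COLUMN = "as_time_to_target"


def bcea(sigma_x: float, sigma_y: float, rho: float,
         coverage: float = BCEA_COVERAGE) -> float:
    """Bivariate contour ellipse area (deg^2) at the given coverage.

    Under a bivariate Gaussian, the squared Mahalanobis distance is
    chi^2 with 2 df, so the ellipse containing fraction P has area
    2*pi*k*sx*sy*sqrt(1-rho^2) with k = -ln(1-P).
    """
    if sigma_x < 0 or sigma_y < 0 or not -1.0 <= rho <= 1.0:
        raise ValueError("invalid scatter parameters")
    k = -np.log(1.0 - coverage)
    return float(2.0 * np.pi * k * sigma_x * sigma_y * np.sqrt(1.0 - rho ** 2))


def bcea_from_points(x: np.ndarray, y: np.ndarray,
                     coverage: float = BCEA_COVERAGE,
                     robust: bool = False) -> float:
    """BCEA of a gaze point cloud (Gaussian assumption by default).

    ``robust=True`` replaces moments with a rank-based empirical
    ellipse: axes from MAD-scaled spreads of the principal components.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        return float("nan")
    if robust:
        pts = np.column_stack([x - np.median(x), y - np.median(y)])
        _, _, vt = np.linalg.svd(pts - pts.mean(0), full_matrices=False)
        pc = pts @ vt.T
        s = 1.4826 * np.median(np.abs(pc - np.median(pc, 0)), 0)
        return bcea(float(s[0]), float(s[1]), 0.0, coverage)
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    rho = float(np.corrcoef(x, y)[0, 1])
    if not np.isfinite(rho):
        rho = 0.0
    return bcea(sx, sy, rho, coverage)


def _nanmean(values) -> float:
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)],
                     dtype=float)
    return float(arr.mean()) if arr.size else float("nan")


def _events_in(events: list[SaccadeEvent], t0: float, t1: float,
               min_amp: float = 0.0) -> list[SaccadeEvent]:
    return [e for e in events
            if t0 <= e.onset_s <= t1 and e.amplitude_deg >= min_amp]


def _saccade_mask(rec_t: np.ndarray, events: list[SaccadeEvent],
                  pad_s: float = 0.0) -> np.ndarray:
    mask = np.zeros(len(rec_t), dtype=bool)
    for e in events:
        i0 = np.searchsorted(rec_t, e.onset_s - pad_s)
        i1 = np.searchsorted(rec_t, e.offset_s + pad_s, side="right")
        mask[i0:i1] = True
    return mask


# ---------------------------------------------------------------------------
# fixation
# ---------------------------------------------------------------------------

@dataclass
class FixationParams:
    bcea95: float
    intrusion_rate: float
    intrusion_amplitude: float

    def to_dict(self) -> dict:
        return {"fix_bcea95": self.bcea95,
                "fix_intrusion_rate": self.intrusion_rate,
                "fix_intrusion_amplitude": self.intrusion_amplitude}


def compute_fixation_params(rec: GazeRecording, events: list[SaccadeEvent],
                            spec: TaskSpec, robust_bcea: bool = False,
                            min_intrusion_amp: float = 0.5) -> FixationParams:
    """BCEA95 and intrusion statistics averaged over the fixation trials.

    Trials contribute only if they retain >= 1 s of usable data after
    artifact masking; intrusion amplitudes are pooled over all events.
    """
    mask = rec.analysis_mask()
    if rec.interpolated is not None:
        mask = mask & ~rec.interpolated
    dt = rec.dt
    bceas, rates, amps = [], [], []
    for trial in spec.trials:
        t0, t1 = trial.t_on + FIX_ACQUIRE_S, trial.t_off
        sel = (rec.t >= t0) & (rec.t <= t1) & mask
        valid_time = float(sel.sum()) * dt
        if valid_time < MIN_FIX_VALID_S:
            continue
        intr = _events_in(events, t0, t1, min_amp=min_intrusion_amp)
        rates.append(len(intr) / valid_time)
        amps.extend(e.amplitude_deg for e in intr)
        quiet = sel & ~_saccade_mask(rec.t, intr, pad_s=dt)
        if quiet.sum() >= 10:
            bceas.append(bcea_from_points(rec.x[quiet], rec.y[quiet],
                                          robust=robust_bcea))
    return FixationParams(
        bcea95=_nanmean(bceas),
        intrusion_rate=_nanmean(rates),
        intrusion_amplitude=_nanmean(amps) if amps else
        (0.0 if rates and np.nanmean(rates) == 0.0 else float("nan")),
    )


# ---------------------------------------------------------------------------
# pro-saccade
# ---------------------------------------------------------------------------

@dataclass
class ProsaccadeParams:
    latency_short: float
    latency_large: float
    time_to_target_short: float
    time_to_target_large: float
    peak_velocity_short: float
    peak_velocity_large: float
    gain_short: float
    gain_large: float

    def to_dict(self) -> dict:
        return {"ps_latency_short": self.latency_short,
                "ps_latency_large": self.latency_large,
                "ps_time_to_target_short": self.time_to_target_short,
                "ps_time_to_target_large": self.time_to_target_large,
                "ps_peak_velocity_short": self.peak_velocity_short,
                "ps_peak_velocity_large": self.peak_velocity_large,
                "ps_gain_short": self.gain_short,
                "ps_gain_large": self.gain_large}


def _time_to_target(rec: GazeRecording, t_start: float, t_stop: float,
                    target_xy, radius: float = TARGET_RADIUS_DEG,
                    dwell_s: float = TARGET_DWELL_S) -> float:
    """First time gaze enters the target radius and stays >= dwell_s."""
    mask = rec.analysis_mask()
    sel = (rec.t >= t_start) & (rec.t <= t_stop)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        return float("nan")
    d = np.hypot(rec.x[idx] - target_xy[0], rec.y[idx] - target_xy[1])
    inside = (d <= radius) & mask[idx]
    need = max(1, int(np.ceil(dwell_s * rec.rate_hz)))
    run = 0
    for j, flag in enumerate(inside):
        run = run + 1 if flag else 0
        if run >= need:
            return float(rec.t[idx[j - need + 1]])
    return float("nan")


def compute_prosaccade_params(rec: GazeRecording, events: list[SaccadeEvent],
                              spec: TaskSpec) -> ProsaccadeParams:
    """Latency, time-to-target, peak velocity and gain per eccentricity class."""
    per_class: dict[str, dict[str, list]] = {
        "short": {"lat": [], "ttt": [], "vp": [], "gain": []},
        "large": {"lat": [], "ttt": [], "vp": [], "gain": []},
    }
    for trial in spec.trials:
        w0 = trial.t_target_on + LATENCY_WINDOW_S[0]
        w1 = trial.t_target_on + LATENCY_WINDOW_S[1]
        cands = _events_in(events, w0, w1, min_amp=MIN_SACCADE_AMP_DEG)
        if not cands:
            continue  # trial invalid
        primary = cands[0]
        acc = per_class[trial.ecc_class]
        acc["lat"].append((primary.best_onset_s - trial.t_target_on) * 1e3)
        acc["vp"].append(primary.peak_vel_dps)
        acc["gain"].append(primary.amplitude_deg / trial.eccentricity)
        t_in = _time_to_target(rec, primary.onset_s, trial.t_target_off + 0.5,
                               (trial.target_x, trial.target_y))
        if np.isfinite(t_in):
            acc["ttt"].append((t_in - trial.t_target_on) * 1e3)
    c = {k: {m: _nanmean(v) for m, v in d.items()} for k, d in per_class.items()}
    return ProsaccadeParams(
        latency_short=c["short"]["lat"], latency_large=c["large"]["lat"],
        time_to_target_short=c["short"]["ttt"],
        time_to_target_large=c["large"]["ttt"],
        peak_velocity_short=c["short"]["vp"],
        peak_velocity_large=c["large"]["vp"],
        gain_short=c["short"]["gain"], gain_large=c["large"]["gain"])


# ---------------------------------------------------------------------------
# anti-saccade
# ---------------------------------------------------------------------------

@dataclass
class AntisaccadeTrialResult:
    category: str                     # correct|corrected-error|uncorrected-error|invalid
    latency_ms: float = float("nan")
    time_to_correct_ms: float = float("nan")
    time_to_target_ms: float = float("nan")


def _gaze_at(rec: GazeRecording, t: float) -> tuple[float, float]:
    i = int(np.clip(np.searchsorted(rec.t, t), 0, len(rec.t) - 1))
    return float(rec.x[i]), float(rec.y[i])


def classify_antisaccade_trial(rec: GazeRecording,
                               events: list[SaccadeEvent],
                               trial) -> AntisaccadeTrialResult:
    """Score one anti-saccade trial from its detected saccades.

    The first horizontal saccade >= 1 deg in the response window
    defines the trial: toward the flashed target is a direction error;
    away is correct.  An error followed by an opposite saccade before
    the answer screen is a corrected error.  Time-to-target is measured
    to the offset of the final saccade landing in the correct
    (anti) hemifield before the arrow cue.
    """
    w0 = trial.t_target_on + LATENCY_WINDOW_S[0]
    w1 = trial.t_target_on + LATENCY_WINDOW_S[1]
    cands = [e for e in _events_in(events, w0, w1, MIN_SACCADE_AMP_DEG)
             if abs(np.cos(np.radians(e.direction_deg))) * e.amplitude_deg >= 0.5]
    if not cands:
        return AntisaccadeTrialResult("invalid")
    first = cands[0]
    latency = (first.best_onset_s - trial.t_target_on) * 1e3
    toward_target = np.cos(np.radians(first.direction_deg)) * trial.side > 0

    # time-to-target: offset of the final saccade landing in the anti hemifield
    ttt = float("nan")
    landers = [e for e in _events_in(events, w0, trial.t_arrow_on,
                                     MIN_SACCADE_AMP_DEG)
               if _gaze_at(rec, min(e.offset_s + rec.dt, rec.t[-1]))[0]
               * trial.side < -1.0]
    if landers:
        ttt = (landers[-1].best_offset_s - trial.t_target_on) * 1e3

    if not toward_target:
        return AntisaccadeTrialResult("correct", latency_ms=latency,
                                      time_to_target_ms=ttt)
    correction = [e for e in _events_in(events, first.offset_s,
                                        trial.t_arrow_off, MIN_SACCADE_AMP_DEG)
                  if np.cos(np.radians(e.direction_deg)) * trial.side < 0]
    if correction:
        ttc = (correction[0].best_onset_s - first.best_onset_s) * 1e3
        return AntisaccadeTrialResult("corrected-error", latency_ms=latency,
                                      time_to_correct_ms=ttc,
                                      time_to_target_ms=ttt)
    return AntisaccadeTrialResult("uncorrected-error", latency_ms=latency,
                                  time_to_target_ms=ttt)


@dataclass
class AntisaccadeParams:
    error_rate: float
    correction_rate: float
    latency_correct: float
    latency_incorrect: float
    time_to_correct: float
    time_to_target: float

    def to_dict(self, include_time_to_target: bool = True) -> dict:
        d = {"as_error_rate": self.error_rate,
             "as_correction_rate": self.correction_rate,
             "as_latency_correct": self.latency_correct,
             "as_latency_incorrect": self.latency_incorrect,
             "as_time_to_correct": self.time_to_correct}
        if include_time_to_target:
            d["as_time_to_target"] = self.time_to_target
        return d


def compute_antisaccade_params(results: list[AntisaccadeTrialResult]) \
        -> AntisaccadeParams:
    """Aggregate trial scores; empty denominators yield structural NaN."""
    scored = [r for r in results if r.category != "invalid"]
    errors = [r for r in scored if r.category.endswith("error")]
    corrected = [r for r in errors if r.category == "corrected-error"]
    correct = [r for r in scored if r.category == "correct"]
    n = len(scored)
    return AntisaccadeParams(
        error_rate=len(errors) / n if n else float("nan"),
        correction_rate=len(corrected) / len(errors) if errors else float("nan"),
        latency_correct=_nanmean([r.latency_ms for r in correct]),
        latency_incorrect=_nanmean([r.latency_ms for r in errors]),
        time_to_correct=_nanmean([r.time_to_correct_ms for r in corrected]),
        time_to_target=_nanmean([r.time_to_target_ms for r in scored]),
    )


# ---------------------------------------------------------------------------
# pursuit
# ---------------------------------------------------------------------------

@dataclass
class PursuitParams:
    gain: float
    lag: float
    prop_pursuit: float
    catchup_count: float

    def to_dict(self) -> dict:
        return {"sp_gain": self.gain, "sp_lag": self.lag,
                "sp_prop_pursuit": self.prop_pursuit,
                "sp_catchup_count": self.catchup_count}


def compute_pursuit_params(rec: GazeRecording, vel: VelocityTrace,
                           events: list[SaccadeEvent],
                           spec: TaskSpec) -> PursuitParams:
    """Desaccaded velocity gain, lag, time-in-pursuit and catch-up count.

    Saccadic samples (detected events, padded one sample) are excised
    before the velocity gain is averaged; catch-up saccades are events
    during the ramp whose displacement is co-directional with the
    target motion.
    """
    gains, lags, props = [], [], []
    n_catchup = 0
    for trial in spec.trials:
        t0 = trial.t_ramp_on + PURSUIT_SETTLE_S
        t1 = trial.t_ramp_off
        sel = (rec.t >= t0) & (rec.t <= t1)
        if not sel.any():
            continue
        d = np.array([trial.dir_x, trial.dir_y])
        ramp_events = [e for e in _events_in(events, trial.t_ramp_on, t1)]
        catchups = [e for e in ramp_events
                    if (np.cos(np.radians(e.direction_deg)) * d[0]
                        + np.sin(np.radians(e.direction_deg)) * d[1]) > 0.5]
        n_catchup += len(catchups)
        sacc = _saccade_mask(rec.t, ramp_events, pad_s=rec.dt)
        smooth = sel & ~sacc & vel.valid
        if smooth.sum() >= 5:
            v_along = vel.vx[smooth] * d[0] + vel.vy[smooth] * d[1]
            # second-stage desaccading: undetected (sub-threshold)
            # catch-ups leak into the mean, so clip symmetrically
            # around the trial median before averaging
            med = np.median(v_along)
            mad = 1.4826 * np.median(np.abs(v_along - med))
            keep = np.abs(v_along - med) <= 3.5 * max(mad, 1e-9)
            gains.append(float(np.mean(v_along[keep])) / trial.velocity_dps)
        quiet = sel & ~sacc & rec.analysis_mask()
        if quiet.sum() >= 5:
            tx, ty = trial.target_position(rec.t[quiet])
            lags.append(float(np.mean(np.hypot(rec.x[quiet] - tx,
                                               rec.y[quiet] - ty))))
        total = float((sel & rec.analysis_mask()).sum())
        if total > 0:
            sacc_time = float((sel & sacc & rec.analysis_mask()).sum())
            props.append((total - sacc_time) / total)
    if not gains and not lags:
        return PursuitParams(float("nan"), float("nan"), float("nan"),
                             float("nan"))
    return PursuitParams(gain=_nanmean(gains), lag=_nanmean(lags),
                         prop_pursuit=_nanmean(props),
                         catchup_count=float(n_catchup))


# ---------------------------------------------------------------------------
# profile assembly
# ---------------------------------------------------------------------------

def assemble_profile(fixation: FixationParams | None = None,
                     prosaccade: ProsaccadeParams | None = None,
                     antisaccade: AntisaccadeParams | None = None,
                     pursuit: PursuitParams | None = None,
                     include_time_to_target: bool = True) -> pd.Series:
    """Flatten per-task parameters into the canonical profile vector.

    Absent tasks leave their slots NaN; duplicate names are an error.
    """
    values: dict[str, float] = {}
    parts = [p.to_dict() if not isinstance(p, AntisaccadeParams)
             else p.to_dict(include_time_to_target)
             for p in (fixation, prosaccade, antisaccade, pursuit)
             if p is not None]
    for d in parts:
        for k, v in d.items():
            if k in values:
                raise ValueError(f"duplicate parameter name {k!r}")
            values[k] = v
    cols = list(PROFILE_COLUMNS)
    if include_time_to_target:
        cols.append(OPTIONAL_PROFILE_COLUMN)
    return pd.Series({c: values.get(c, float("nan")) for c in cols},
                     dtype=float)[cols]
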