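"""Gaze-trace conditioning: artifact (blink) handling and velocity estimation.

Traces arrive as timestamped samples of gaze position in degrees of
visual angle with a per-sample sensor validity flag.  Conditioning

* masks invalid runs (with a guard margin, since samples bordering a
  blink are unreliable) when they are long,
* linearly interpolates runs short enough to be dropped frames rather
  than blinks, flagging the filled samples, and
* differentiates position with a local-polynomial (Savitzky-Golay)
  filter, which is exact on linear ramps and attenuates sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter


class EmptyRecordingError(ValueError):
    """Raised when a recording has no usable samples."""


class TooShortRecordingError(ValueError):
    """Raised when a recording is too short to differentiate."""


DEFAULT_GUARD_MARGIN_S = 0.050
DEFAULT_INTERP_LIMIT_S = 0.075
DEFAULT_VELOCITY_WINDOW = 5
DEFAULT_VELOCITY_ORDER = 2


@dataclass
class GazeRecording:
    """One task run: gaze samples in degrees at a nominal rate.

    ``valid`` is the sensor flag as recorded; ``usable`` and
    ``interpolated`` are produced by :func:`remove_artifacts` and are
    derived purely from ``valid``, so artifact removal is idempotent.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate_hz: float = 60.0
    participant_id: str = ""
    task_id: str = ""
    usable: np.ndarray | None = None
    interpolated: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("t, x, y, valid must have equal length")
        if n == 0:
            raise EmptyRecordingError("recording has no samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"timestamps not strictly increasing at sample {i}")
        if n >= 2:
            med = float(np.median(dt))
            if not (0.8 / self.rate_hz <= med <= 1.2 / self.rate_hz):
                raise ValueError(
                    f"median sampling interval {med:.4f}s inconsistent with "
                    f"nominal rate {self.rate_hz} Hz")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate_hz

    def analysis_mask(self) -> np.ndarray:
        """Samples fit for analysis: usable if conditioned, else valid."""
        return self.usable if self.usable is not None else self.valid


@dataclass
class VelocityTrace:
    """Smoothed gaze velocity (deg/s) with a validity mask."""

    t: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray
    speed: np.ndarray = field(init=False)

    def __post_init__(self):
        self.speed = np.hypot(self.vx, self.vy)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def remove_artifacts(rec: GazeRecording,
                     guard_margin_s: float = DEFAULT_GUARD_MARGIN_S,
                     interp_limit_s: float = DEFAULT_INTERP_LIMIT_S) -> GazeRecording:
    """Mask blink-like invalid runs; interpolate dropped-frame gaps.

    Invalid runs no longer than ``interp_limit_s`` are linearly
    interpolated from the bracketing valid samples and flagged
    ``interpolated``; longer runs are masked together with a
    ``guard_margin_s`` margin on each side.  Values are never invented
    beyond linear interpolation.
    """
    if not rec.valid.any():
        raise EmptyRecordingError("all samples invalid")
    t, dt = rec.t, rec.dt
    x, y = rec.x.copy(), rec.y.copy()
    usable = rec.valid.copy()
    interpolated = np.zeros(len(rec), dtype=bool)

    valid_idx = np.flatnonzero(rec.valid)
    for start, stop in _bool_runs(~rec.valid):
        gap = t[stop - 1] - t[start] + dt  # run duration incl. one interval
        left_ok = start > 0 and rec.valid[start - 1]
        right_ok = stop < len(rec) and rec.valid[stop]
        if gap <= interp_limit_s and left_ok and right_ok:
            idx = np.arange(start, stop)
            x[idx] = np.interp(t[idx], [t[start - 1], t[stop]],
                               [x[start - 1], x[stop]])
            y[idx] = np.interp(t[idx], [t[start - 1], t[stop]],
                               [y[start - 1], y[stop]])
            usable[idx] = True
            interpolated[idx] = True
        else:
            lo = np.searchsorted(t, t[start] - guard_margin_s, side="left")
            hi = np.searchsorted(t, t[stop - 1] + guard_margin_s, side="right")
            usable[lo:hi] = False
    # positions must be finite wherever usable
    bad = usable & ~(np.isfinite(x) & np.isfinite(y))
    usable[bad] = False
    if not usable.any():
        raise EmptyRecordingError("no usable samples after artifact removal")
    out = replace(rec)
    out.x, out.y = x, y
    out.usable, out.interpolated = usable, interpolated
    return out


def _boxcar_slope(z: np.ndarray, h: int, dt: float) -> np.ndarray:
    """Moving-average difference slope: (mean of next h - mean of
    previous h) / ((h+1) dt).  Exact on linear ramps; for step-like
    inputs it is the matched estimator, which is why detection prefers
    it over polynomial weights at low sampling rates."""
    m = len(z)
    cz = np.concatenate([[0.0], np.cumsum(z)])
    v = np.full(m, np.nan)
    i = np.arange(h, m - h)
    after = (cz[i + 1 + h] - cz[i + 1]) / h
    before = (cz[i] - cz[i - h]) / h
    v[i] = (after - before) / ((h + 1) * dt)
    return v


def estimate_velocity(rec: GazeRecording,
                      window: int = DEFAULT_VELOCITY_WINDOW,
                      order: int = DEFAULT_VELOCITY_ORDER,
                      method: str = "savgol") -> VelocityTrace:
    """Local differentiation per contiguous usable segment.

    ``method='savgol'`` is Savitzky-Golay local-polynomial
    differentiation (exact on polynomials up to ``order``);
    ``method='boxcar'`` is the moving-average difference over
    half-width window//2, better matched to step-like saccades at
    60 Hz.  Masked samples and the half-window adjacent to every gap
    propagate to masked velocity.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if method not in ("savgol", "boxcar"):
        raise ValueError(f"unknown velocity method {method!r}")
    mask = rec.analysis_mask()
    n = len(rec)
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    vvalid = np.zeros(n, dtype=bool)
    half = window // 2
    any_segment = False
    for start, stop in _bool_runs(mask):
        seg = stop - start
        if seg < max(window, 5):
            continue
        any_segment = True
        dt = float(np.median(np.diff(rec.t[start:stop])))
        if method == "savgol":
            vx[start:stop] = savgol_filter(rec.x[start:stop], window, order,
                                           deriv=1, delta=dt, mode="interp")
            vy[start:stop] = savgol_filter(rec.y[start:stop], window, order,
                                           deriv=1, delta=dt, mode="interp")
        else:
            vx[start:stop] = _boxcar_slope(rec.x[start:stop], half, dt)
            vy[start:stop] = _boxcar_slope(rec.y[start:stop], half, dt)
        vvalid[start:stop] = True
        vvalid[start:start + half] = False
        vvalid[stop - half:stop] = False
    if not any_segment:
        raise TooShortRecordingError(
            f"no contiguous usable segment of >= {max(window, 5)} samples")
    vvalid &= np.isfinite(vx) & np.isfinite(vy)
    return VelocityTrace(t=rec.t, vx=vx, vy=vy, valid=vvalid)
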