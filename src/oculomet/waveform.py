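"""Parametric saccadic waveform obeying the main sequence.

Saccades are modelled as a smooth logistic ramp in position along the
saccade axis.  The template is parameterized by onset time ``t0``,
amplitude ``A`` (deg) and peak angular velocity ``Vp`` (deg/s); the main
sequence ties ``Vp`` to ``A`` through the saturating law

    Vp = eta * (1 - exp(-A / c))

with ``eta`` the velocity ceiling (deg/s) and ``c`` the amplitude scale
(deg).  The same template is used by the synthetic generator and the
least-squares fitter, so planted parameters are exactly identifiable.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

# Fitter bounds for the main-sequence parameters.
ETA_BOUNDS = (50.0, 1200.0)
C_BOUNDS = (1.0, 20.0)

# Default human-typical main-sequence constants.
DEFAULT_ETA = 500.0
DEFAULT_C = 6.0

# Logistic units spanned on each side of the waveform midpoint.  The
# template is truncated (and renormalized) at +/- _SUPPORT, which makes
# the saccade strictly zero outside a finite duration.
_SUPPORT = 3.5
_EDGE = float(expit(-_SUPPORT))
_NORM = 1.0 - 2.0 * _EDGE


def main_sequence(amplitude, eta: float = DEFAULT_ETA, c: float = DEFAULT_C):
    """Peak velocity (deg/s) of a saccade of ``amplitude`` deg.

    Saturates at ``eta`` for large amplitudes; ~0.632*eta at A == c.
    """
    a = np.asarray(amplitude, dtype=float)
    if np.any(a < 0):
        raise ValueError("saccade amplitude must be non-negative")
    if eta <= 0 or c <= 0:
        raise ValueError("main-sequence parameters eta and c must be positive")
    out = eta * -np.expm1(-a / c)
    return float(out) if np.isscalar(amplitude) else out


def invert_main_sequence(amplitude: float, peak_velocity: float,
                         c: float = DEFAULT_C) -> tuple[float, float]:
    """Recover (eta, c) consistent with a fitted (A, Vp) pair.

    A single waveform constrains eta and c only through Vp, so c is held
    at its default and eta solved; if the solved eta falls outside
    ETA_BOUNDS it is clipped and c re-solved to preserve the identity
    Vp = eta*(1-exp(-A/c)).
    """
    if amplitude <= 0 or peak_velocity <= 0:
        return DEFAULT_ETA, c
    eta = peak_velocity / -np.expm1(-amplitude / c)
    if ETA_BOUNDS[0] <= eta <= ETA_BOUNDS[1]:
        return float(eta), float(c)
    eta = float(np.clip(eta, *ETA_BOUNDS))
    ratio = peak_velocity / eta
    if 0.0 < ratio < 1.0:
        c = float(np.clip(-amplitude / np.log1p(-ratio), *C_BOUNDS))
    return eta, c


def rate_constant(amplitude: float, peak_velocity: float) -> float:
    """Logistic rate k (1/s) giving the requested analytic peak velocity."""
    if amplitude <= 0 or peak_velocity <= 0:
        raise ValueError("amplitude and peak velocity must be positive")
    return 4.0 * _NORM * peak_velocity / amplitude


def duration(amplitude: float, peak_velocity: float) -> float:
    """Total saccade duration (s) of the truncated template."""
    return 2.0 * _SUPPORT / rate_constant(amplitude, peak_velocity)


def position(t, t0: float, amplitude: float, peak_velocity: float):
    """Displacement (deg) along the saccade axis at times ``t``.

    0 before onset ``t0``; exactly ``amplitude`` after ``t0 + duration``.
    """
    k = rate_constant(amplitude, peak_velocity)
    tm = t0 + _SUPPORT / k
    u = np.clip(k * (np.asarray(t, dtype=float) - tm), -_SUPPORT, _SUPPORT)
    return amplitude * (expit(u) - _EDGE) / _NORM


def velocity(t, t0: float, amplitude: float, peak_velocity: float):
    """Analytic velocity (deg/s) of the template; 0 outside its support."""
    k = rate_constant(amplitude, peak_velocity)
    tm = t0 + _SUPPORT / k
    u = k * (np.asarray(t, dtype=float) - tm)
    s = expit(u)
    v = amplitude * k * s * (1.0 - s) / _NORM
    return np.where(np.abs(u) <= _SUPPORT, v, 0.0)
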