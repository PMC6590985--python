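"""Stimulus generation: naturalistic noise, sinusoids and static tilts.

The naturalistic translational self-motion stimulus is low-pass filtered
Gaussian white noise (20 Hz cutoff) with zero mean and SD 0.1 G, delivered
as a frozen 10 s realization repeated across trials.  Sinusoidal translation
covers 1-10 Hz at 0.2 G peak.  Static head tilt by an angle theta exposes
the afferent to a constant gravity shear of g0*sin(theta).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.signal import filtfilt, firwin

from .errors import DataError, InvalidParameterError
from .types import AfferentModelParams, StimulusTrace

#: Reference acceleration (G) mapping acceleration to model current: an
#: acceleration trace with SD equal to A_REF drives a signal current with SD
#: sigma_signal.  Equal to the naturalistic stimulus SD, so the naturalistic
#: signal current is exactly unit-variance times sigma_signal.
A_REF = 0.1


def generate_noise_stimulus(
    duration: float,
    cutoff: float = 20.0,
    sd: float = 0.1,
    seed: Optional[int] = None,
    fs: float = 1000.0,
) -> StimulusTrace:
    """Low-pass Gaussian noise acceleration with exact zero mean and SD ``sd``.

    A windowed-sinc FIR filter applied with ``filtfilt`` (zero phase, so the
    stimulus is not delayed relative to the analyses that assume alignment)
    removes power above ``cutoff``; the filtered series is re-standardized so
    the sample mean/SD are exactly 0/``sd``.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    if not 0 < cutoff < fs / 2:
        raise InvalidParameterError("cutoff must lie in (0, Nyquist)")
    if sd < 0:
        raise InvalidParameterError("sd must be >= 0")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    numtaps = min(1001, (n - 2) // 3)  # filtfilt pads by 3*numtaps samples
    if numtaps % 2 == 0:
        numtaps -= 1
    if numtaps < 3:
        raise InvalidParameterError("duration too short for the low-pass filter")
    taps = firwin(numtaps, cutoff, fs=fs)
    x = filtfilt(taps, [1.0], white)
    x = x - x.mean()
    s = x.std()
    x = np.zeros(n) if (sd == 0 or s == 0) else x * (sd / s)
    return StimulusTrace(
        x,
        dt=1.0 / fs,
        kind="acceleration",
        meta={"generator": "noise", "cutoff_hz": cutoff, "sd": sd, "seed": seed},
    )


def generate_sinusoid(
    freq: float, peak: float = 0.2, duration: float = 10.0, fs: float = 1000.0
) -> StimulusTrace:
    """Sinusoidal acceleration ``a(t) = peak * sin(2 pi f t)``."""
    if freq <= 0:
        raise InvalidParameterError("frequency must be positive")
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    t = np.arange(int(round(duration * fs))) / fs
    return StimulusTrace(
        peak * np.sin(2 * np.pi * freq * t),
        dt=1.0 / fs,
        kind="acceleration",
        meta={"generator": "sinusoid", "freq_hz": freq, "peak": peak},
    )


def orientation_offset(angle_deg: float, g0: float = 1.0) -> float:
    """Gravity shear (G) along the preferred direction for a static tilt.

    The angle is clamped to [-90, 90] degrees; returns ``g0 * sin(angle)``.
    """
    a = float(np.clip(angle_deg, -90.0, 90.0))
    return g0 * float(np.sin(np.deg2rad(a)))


class DynamicsFilter:
    """One-parameter high-pass-plus-constant response dynamics filter.

    ``H(f) = 1 + alpha * (i f / corner) / (1 + i f / corner)`` -- flat at DC,
    approaching ``1 + alpha`` well above the corner.  ``alpha = 0`` is the
    identity, the package default (the response dynamics that shape real
    afferent gains are not part of the model's printed constants).
    """

    def __init__(self, alpha: float = 0.0, corner_hz: float = 5.0):
        if corner_hz <= 0 or not np.isfinite(alpha) or not np.isfinite(corner_hz):
            raise InvalidParameterError("invalid dynamics-filter parameters")
        self.alpha = alpha
        self.corner_hz = corner_hz

    def response(self, freqs: np.ndarray) -> np.ndarray:
        s = 1j * freqs / self.corner_hz
        return 1.0 + self.alpha * s / (1.0 + s)


IDENTITY_FILTER = DynamicsFilter(0.0)


def filter_stimulus_dynamics(
    stim: StimulusTrace,
    params: AfferentModelParams,
    dyn_filter: Optional[DynamicsFilter] = None,
    a_ref: float = A_REF,
) -> StimulusTrace:
    """Convert an acceleration trace to the model's signal current (nA).

    Acceleration is expressed in units of ``a_ref`` (default 0.1 G, the SD of
    the naturalistic stimulus) and scaled by ``sigma_signal``, so the frozen
    naturalistic stimulus drives a current with SD exactly ``sigma_signal``.
    An optional LTI dynamics filter is applied in the frequency domain before
    scaling.
    """
    if stim.kind != "acceleration":
        raise InvalidParameterError("expected an acceleration stimulus")
    if a_ref <= 0:
        raise InvalidParameterError("a_ref must be positive")
    if not np.all(np.isfinite(stim.values)):
        raise DataError("stimulus contains non-finite values")
    x = stim.values / a_ref
    if dyn_filter is not None and dyn_filter.alpha != 0.0:
        X = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(x.size, stim.dt)
        x = np.fft.irfft(X * dyn_filter.response(freqs), n=x.size)
    cur = params.sigma_signal * x
    meta = dict(stim.meta)
    meta.update({"sigma_signal": params.sigma_signal, "a_ref": a_ref})
    return StimulusTrace(cur, dt=stim.dt, t0=stim.t0, kind="current", meta=meta)
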