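"""Core containers: stimuli, spike trains and afferent model parameters.

Units convention used throughout the package:

* time in seconds at the container level (spike times, durations, ``dt``),
* membrane dynamics in (mV, nA, nF, uS, ms) -- the natural units of the
  afferent model, where ``tau_m = Cm/g_leak`` comes out in milliseconds,
* linear acceleration in units of G (1 G = 9.81 m/s^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidParameterError


@dataclass
class StimulusTrace:
    """A uniformly sampled stimulus: acceleration (G) or injected current (nA).

    Parameters
    ----------
    values : ndarray
        Sample values, acceleration in G or current in nA depending on ``kind``.
    dt : float
        Sampling interval in seconds (default 1 ms).
    t0 : float
        Time of the first sample, seconds.
    kind : {"acceleration", "current"}
    meta : dict
        Generator parameters (cutoff, sd, frequency, seed, ...).
    """

    values: np.ndarray
    dt: float = 0.001
    t0: float = 0.0
    kind: str = "acceleration"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidParameterError("stimulus values must be 1-D")
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be positive, got {self.dt}")
        if self.kind not in ("acceleration", "current"):
            raise InvalidParameterError(f"unknown stimulus kind {self.kind!r}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("stimulus contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.dt

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


@dataclass
class SpikeTrain:
    """Ordered spike times of one unit in one trial.

    ``spike_times`` are in seconds, strictly increasing, within
    ``[0, duration]``.
    """

    spike_times: np.ndarray
    duration: float
    unit_id: str = ""
    trial_id: int = 0
    afferent_class: str = "unknown"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.duration <= 0:
            raise InvalidParameterError("duration must be positive")
        t = self.spike_times
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise InvalidParameterError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise InvalidParameterError("spike times must lie in [0, duration]")
        if self.afferent_class not in ("regular", "irregular", "unknown"):
            raise InvalidParameterError(
                f"unknown afferent class {self.afferent_class!r}"
            )

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def rate(self) -> float:
        """Mean firing rate over the record, spk/s."""
        return self.n_spikes / self.duration

    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)

    def slice(self, t_start: float, t_stop: float, rezero: bool = True) -> "SpikeTrain":
        """Spikes in ``[t_start, t_stop)``, optionally re-zeroed to ``t_start``."""
        t = self.spike_times
        sel = t[(t >= t_start) & (t < t_stop)]
        if rezero:
            sel = sel - t_start
        return SpikeTrain(
            sel,
            duration=t_stop - t_start if rezero else t_stop,
            unit_id=self.unit_id,
            trial_id=self.trial_id,
            afferent_class=self.afferent_class,
        )


@dataclass
class AfferentModelParams:
    """Constants of the leaky integrate-and-fire afferent model.

    The membrane potential is treated as the deviation from rest: the unit
    fires when ``V >= V_threshold`` (mV, positive) and resets to
    ``V_reset = 0``.  ``sigma_noise`` is the standard deviation of the
    intrinsic noise current accumulated over a 1 ms reference window;
    ``sigma_signal`` scales the (unit-variance) stimulus current.
    """

    Cm: float = 1.0            # membrane capacitance, nF
    g_leak: float = 0.22       # leak conductance, uS
    I_bias: float = 3.53       # bias current, nA
    sigma_noise: float = 0.14  # intrinsic noise current SD, nA (1 ms reference)
    sigma_signal: float = 0.14  # stimulus current scale, nA
    V_threshold: float = 14.85  # spike threshold above rest, mV
    V_reset: float = 0.0       # post-spike reset, mV
    dt_integration: float = 0.025  # Euler-Maruyama step, ms

    def __post_init__(self) -> None:
        if self.Cm <= 0 or self.g_leak <= 0 or self.dt_integration <= 0:
            raise InvalidParameterError("Cm, g_leak and dt_integration must be > 0")
        if self.sigma_noise < 0 or self.sigma_signal < 0:
            raise InvalidParameterError("noise/signal scales must be >= 0")
        if self.V_reset >= self.V_threshold:
            raise InvalidParameterError("V_reset must be below V_threshold")

    @property
    def tau_m(self) -> float:
        """Membrane time constant Cm/g_leak, ms."""
        return self.Cm / self.g_leak

    @property
    def V_inf(self) -> float:
        """Steady-state voltage I_bias/g_leak for the unstimulated cell, mV."""
        return self.I_bias / self.g_leak

    def replace(self, **kwargs) -> "AfferentModelParams":
        d = self.__dict__.copy()
        d.update(kwargs)
        return AfferentModelParams(**d)


#: Printed model constants for the two afferent classes.  The threshold
#: defaults are deterministic first guesses; :func:`otokit.lif.calibrate_threshold`
#: refines them so the resting rate matches the target (85 / 71 spk/s).
REGULAR_SIGMA = 0.14
IRREGULAR_SIGMA = 1.9
REGULAR_RESTING_RATE = 85.0
IRREGULAR_RESTING_RATE = 71.0
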