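"""Synthetic populations of model afferents run through the stimulus protocol.

This is the data-generating stage that stands in for the in-vivo recordings:
every unit is a seeded LIF afferent (regular or irregular) driven through the
full experimental protocol -- resting discharge, repeats of a frozen
naturalistic stimulus, a sinusoidal frequency series, and static tilt
epochs.  Sensitivity (sigma_signal) and variability (sigma_noise) are
co-varied with their ratio held at 1, mirroring the covariation used to match
the two afferent classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import InvalidParameterError
from .lif import calibrate_threshold, simulate_lif
from .stimulus import (
    filter_stimulus_dynamics,
    generate_noise_stimulus,
    generate_sinusoid,
    orientation_offset,
)
from .types import (
    IRREGULAR_RESTING_RATE,
    IRREGULAR_SIGMA,
    REGULAR_RESTING_RATE,
    REGULAR_SIGMA,
    AfferentModelParams,
    SpikeTrain,
    StimulusTrace,
)

#: Conversion from gravity shear (G) to injected tilt current (nA).  Tilt is
#: a physically identical gravito-inertial force across units, so it enters
#: as a constant current offset NOT scaled by per-unit sensitivity.
TILT_GAIN_NA_PER_G = 1.0


@dataclass
class ProtocolConfig:
    """Stimulation protocol: durations, repeats and stimulus parameters."""

    resting_duration: float = 100.0
    naturalistic_duration: float = 10.0
    naturalistic_repeats: int = 10
    naturalistic_cutoff: float = 20.0
    naturalistic_sd: float = 0.1
    sinusoid_freqs: Sequence[float] = field(default_factory=lambda: list(range(1, 11)))
    sinusoid_peak: float = 0.2
    sinusoid_duration: float = 10.0
    tilt_angles: Sequence[float] = field(default_factory=lambda: [0.0, 3.0, 6.0, 9.0, 15.0])
    tilt_duration: float = 10.0
    tilt_gain: float = TILT_GAIN_NA_PER_G
    include_sinusoids: bool = True
    include_tilts: bool = True

    def stages(self) -> List[str]:
        out = ["resting", "naturalistic"]
        if self.include_sinusoids:
            out.append("sinusoid")
        if self.include_tilts:
            out.append("tilt")
        return out


@dataclass
class UnitRecord:
    unit_id: str
    afferent_class: str
    params: AfferentModelParams
    resting: Optional[SpikeTrain] = None
    naturalistic: List[SpikeTrain] = field(default_factory=list)
    sinusoids: Dict[float, SpikeTrain] = field(default_factory=dict)
    tilts: Dict[float, SpikeTrain] = field(default_factory=dict)


@dataclass
class PopulationBundle:
    units: List[UnitRecord]
    protocol: ProtocolConfig
    seed: int
    frozen_stimulus: Optional[StimulusTrace] = None

    def by_class(self, afferent_class: str) -> List[UnitRecord]:
        return [u for u in self.units if u.afferent_class == afferent_class]


def _child_seeds(ss: np.random.SeedSequence, n: int) -> List[int]:
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def class_params(
    afferent_class: str,
    seed: int = 0,
    calibrate: bool = True,
    sigma: Optional[float] = None,
    target_rate: Optional[float] = None,
) -> AfferentModelParams:
    """Model parameters for one afferent class, threshold calibrated by rate.

    ``sigma``/``target_rate`` override the class defaults (used by the
    covariation sweep).
    """
    from .lif import threshold_for_rate_deterministic

    if afferent_class == "regular":
        sig = REGULAR_SIGMA if sigma is None else sigma
        rate = REGULAR_RESTING_RATE if target_rate is None else target_rate
    elif afferent_class == "irregular":
        sig = IRREGULAR_SIGMA if sigma is None else sigma
        rate = IRREGULAR_RESTING_RATE if target_rate is None else target_rate
    else:
        raise InvalidParameterError(f"unknown class {afferent_class!r}")
    p = AfferentModelParams(sigma_noise=sig, sigma_signal=sig)
    p = p.replace(V_threshold=threshold_for_rate_deterministic(p, rate))
    if calibrate:
        p = p.replace(V_threshold=calibrate_threshold(p, rate, seed=seed))
    return p


def simulate_unit(
    unit_id: str,
    afferent_class: str,
    params: AfferentModelParams,
    protocol: ProtocolConfig,
    seed: int,
    frozen_stimulus: Optional[StimulusTrace] = None,
) -> UnitRecord:
    """Run one unit through every protocol stage with stage-derived seeds."""
    ss = np.random.SeedSequence(seed)
    n_stage = (
        1
        + protocol.naturalistic_repeats
        + len(protocol.sinusoid_freqs)
        + len(protocol.tilt_angles)
    )
    seeds = _child_seeds(ss, n_stage)
    it = iter(seeds)
    rec = UnitRecord(unit_id=unit_id, afferent_class=afferent_class, params=params)
    rec.resting = simulate_lif(
        params, duration=protocol.resting_duration, seed=next(it),
        unit_id=unit_id, afferent_class=afferent_class,
    )
    if frozen_stimulus is not None:
        cur = filter_stimulus_dynamics(frozen_stimulus, params)
        for r in range(protocol.naturalistic_repeats):
            rec.naturalistic.append(
                simulate_lif(
                    params, input_current=cur, seed=next(it),
                    unit_id=unit_id, trial_id=r, afferent_class=afferent_class,
                )
            )
    else:
        for _ in range(protocol.naturalistic_repeats):
            next(it)
    if protocol.include_sinusoids:
        for f in protocol.sinusoid_freqs:
            stim = generate_sinusoid(
                f, peak=protocol.sinusoid_peak, duration=protocol.sinusoid_duration
            )
            cur = filter_stimulus_dynamics(stim, params)
            rec.sinusoids[f] = simulate_lif(
                params, input_current=cur, seed=next(it),
                unit_id=unit_id, afferent_class=afferent_class,
            )
    else:
        for _ in protocol.sinusoid_freqs:
            next(it)
    if protocol.include_tilts:
        for ang in protocol.tilt_angles:
            di = protocol.tilt_gain * orientation_offset(ang)
            p = params.replace(I_bias=params.I_bias + di)
            rec.tilts[ang] = simulate_lif(
                p, duration=protocol.tilt_duration, seed=next(it),
                unit_id=unit_id, afferent_class=afferent_class,
            )
    return rec


def generate_population(
    n_regular: int,
    n_irregular: int,
    protocol: Optional[ProtocolConfig] = None,
    seed: int = 0,
    signal_noise_ratio: float = 1.0,
) -> PopulationBundle:
    """Simulate a population of regular/irregular model afferents.

    The frozen naturalistic stimulus is shared by all units (as in the
    experiment); each unit gets its own intrinsic-noise seeds.  The
    sensitivity/variability grid keeps ``sigma_signal / sigma_noise``
    equal to ``signal_noise_ratio`` (default 1).
    """
    if n_regular < 0 or n_irregular < 0:
        raise InvalidParameterError("unit counts must be >= 0")
    if protocol is None:
        protocol = ProtocolConfig()
    if not protocol.stages():
        raise InvalidParameterError("empty protocol")
    master = np.random.SeedSequence(seed)
    stim_seed, cal_seed, *unit_seeds = _child_seeds(
        master, 2 + n_regular + n_irregular
    )
    frozen = (
        generate_noise_stimulus(
            protocol.naturalistic_duration,
            cutoff=protocol.naturalistic_cutoff,
            sd=protocol.naturalistic_sd,
            seed=stim_seed,
        )
        if protocol.naturalistic_repeats > 0
        else None
    )
    units: List[UnitRecord] = []
    for cls, count in (("regular", n_regular), ("irregular", n_irregular)):
        if count == 0:
            continue
        base = class_params(cls, seed=cal_seed)
        if signal_noise_ratio != 1.0:
            base = base.replace(sigma_signal=signal_noise_ratio * base.sigma_noise)
        for k in range(count):
            uid = f"{cls[:3]}{k:02d}"
            units.append(
                simulate_unit(uid, cls, base, protocol, unit_seeds.pop(0), frozen)
            )
    return PopulationBundle(
        units=units, protocol=protocol, seed=seed, frozen_stimulus=frozen
    )
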