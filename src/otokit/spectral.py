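"""Multitaper spectral analysis of stimulus-response coding.

All spectral quantities are multitaper estimates over the whole record
(default 8 Slepian tapers, time-bandwidth NW = 4.5), so a 10 s record gives
a 0.1 Hz frequency grid.  The module covers:

* transfer function ``H(f) = P_S,fr(f) / P_SS(f)`` and response gain |H|,
* the linear firing-rate prediction (impulse response convolved with the
  stimulus plus the baseline rate) and its residual,
* stimulus-response coherence ``C_SR = |P_SR|^2 / (P_SS P_RR)`` of the 1 ms
  binary sequence,
* response-response coherence across k repeats of a frozen stimulus,
  ``C_RR = |<P_RiRj>_{j<i}|^2 / <P_RiRi>_i^2``,
* the nonlinearity index comparing integrated SR and RR coherence over
  0-100 Hz, and
* the mutual information rate density ``-log2(1 - C_RR)/FR`` integrated over
  0-15 Hz to give a rate in bits per spike.

For a perfectly linear encoder the SR coherence equals the *square root* of
the RR coherence, so the nonlinearity index defaults to

    NI = 100 * (1 - int C_SR df / int sqrt(C_RR) df)

which is zero for a linear response and grows towards 100% with increasing
nonlinearity.  The non-rooted variant (C_RR in the denominator integrand) is
available via ``sqrt_rr=False`` but can go negative for nearly linear
responses and is not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.signal.windows import dpss

from .discharge import RateTrace
from .errors import DataError, InsufficientDataError, InvalidParameterError
from .types import SpikeTrain, StimulusTrace

DEFAULT_N_TAPERS = 8
DEFAULT_NW = 4.5


@dataclass
class BinarySequence:
    """Spike train binarized at 1 ms: 1 if the bin holds a spike, else 0."""

    bits: np.ndarray
    dt: float = 0.001
    n_spikes: int = 0
    n_collisions: int = 0

    @property
    def n(self) -> int:
        return self.bits.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def rate(self) -> float:
        """Mean firing rate (spk/s) of the binarized train."""
        return float(self.bits.sum()) / self.duration


@dataclass
class TransferFunction:
    freqs: np.ndarray
    H: np.ndarray          # complex, masked entries are nan
    n_tapers: int
    n_samples: int

    @property
    def gain(self) -> np.ndarray:
        return np.abs(self.H)


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    values: np.ndarray
    kind: str              # "SR" | "RR"
    k_trials: int = 1
    n_tapers: int = DEFAULT_N_TAPERS
    n_clipped: int = 0


def binary_sequence(train: SpikeTrain, dt: float = 0.001) -> BinarySequence:
    """Binarize a spike train; bins are ``[k dt, (k+1) dt)``.

    Multiple spikes in one bin collapse to a single 1; the number of such
    collisions is reported.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    n = int(round(train.duration / dt))
    bits = np.zeros(n)
    idx = np.minimum(np.floor(train.spike_times / dt).astype(int), n - 1)
    uniq, counts = np.unique(idx, return_counts=True) if idx.size else (idx, idx)
    if idx.size:
        bits[uniq] = 1.0
    collisions = int((counts - 1).sum()) if idx.size else 0
    return BinarySequence(
        bits, dt=dt, n_spikes=train.n_spikes, n_collisions=collisions
    )


@lru_cache(maxsize=8)
def _tapers(n: int, nw: float, k: int) -> np.ndarray:
    return dpss(n, nw, Kmax=k)


def _tapered_fft(x: np.ndarray, nw: float, k: int) -> np.ndarray:
    """(k, n_freq) tapered FFTs of the mean-subtracted series."""
    w = _tapers(x.size, nw, k)
    return np.fft.rfft(w * (x - x.mean()), axis=1)


def multitaper_cross_spectrum(
    x: np.ndarray,
    y: np.ndarray,
    dt: float = 0.001,
    n_tapers: int = DEFAULT_N_TAPERS,
    nw: float = DEFAULT_NW,
):
    """Taper-averaged cross- and auto-spectra of two equal-length series.

    Returns ``(freqs, Pxy, Pxx, Pyy)``; auto-spectra are real and >= 0.
    Scaling is ``dt * mean_k X_k conj(Y_k)`` (density per Hz with unit-energy
    tapers); every ratio formed in this module is scale-free.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("series must be 1-D and equal length")
    X = _tapered_fft(x, nw, n_tapers)
    Y = X if y is x else _tapered_fft(y, nw, n_tapers)
    freqs = np.fft.rfftfreq(x.size, dt)
    Pxy = (X * np.conj(Y)).mean(axis=0) * dt
    Pxx = (np.abs(X) ** 2).mean(axis=0) * dt
    Pyy = (np.abs(Y) ** 2).mean(axis=0) * dt
    return freqs, Pxy, Pxx, Pyy


def transfer_function(
    stim: StimulusTrace,
    rate: RateTrace,
    n_tapers: int = DEFAULT_N_TAPERS,
    nw: float = DEFAULT_NW,
    mask_rel: float = 1e-4,
) -> TransferFunction:
    """``H(f) = P_S,fr(f) / P_SS(f)``; gain |H| in (spk/s) per stimulus unit.

    Frequencies where the stimulus power is below ``mask_rel`` times its peak
    carry no stimulus energy; H is undefined (nan) there.
    """
    if abs(stim.dt - rate.dt) > 1e-12:
        raise DataError("stimulus and rate must share the sampling interval")
    if stim.n != rate.n:
        raise DataError("stimulus and rate must have equal length")
    freqs, Psf, Pss, _ = multitaper_cross_spectrum(
        stim.values, rate.values, stim.dt, n_tapers, nw
    )
    H = np.conj(Psf) / Pss  # conj: convention H maps S -> fr
    H = np.where(Pss > mask_rel * Pss.max(), H, np.nan + 0j)
    return TransferFunction(freqs=freqs, H=H, n_tapers=n_tapers, n_samples=stim.n)


def linear_prediction(
    tf: TransferFunction,
    stim: StimulusTrace,
    baseline: float,
    max_lag: float = 1.0,
) -> RateTrace:
    """Linear firing-rate estimate: impulse response (*) stimulus + baseline.

    The impulse response comes from the inverse FFT of H on the estimation
    grid, truncated to lags within ``+-max_lag`` seconds to avoid wrap-around
    of the circular transform.
    """
    if stim.n != tf.n_samples:
        raise DataError("stimulus length must match the H estimation grid")
    H = np.where(np.isnan(tf.H), 0.0, tf.H)
    h = np.fft.irfft(H, n=tf.n_samples) / stim.dt  # response per unit stimulus*s
    L = min(int(round(max_lag / stim.dt)), tf.n_samples // 2 - 1)
    kern = np.concatenate([h[-L:], h[: L + 1]])  # lags -L..L
    x = stim.values - stim.values.mean()
    y = np.convolve(x, kern, mode="full")[L : L + stim.n] * stim.dt
    return RateTrace(y + baseline, dt=stim.dt, kernel_sigma=float("nan"))


def residual(
    actual: RateTrace,
    predicted: RateTrace,
    n_tapers: int = DEFAULT_N_TAPERS,
    nw: float = DEFAULT_NW,
):
    """Residual N(t) = actual - predicted, with its multitaper power spectrum.

    Returns ``(residual_trace, freqs, power)``.
    """
    if actual.n != predicted.n or abs(actual.dt - predicted.dt) > 1e-12:
        raise DataError("rate traces must be aligned")
    diff = actual.values - predicted.values
    freqs, _, Pxx, _ = multitaper_cross_spectrum(diff, diff, actual.dt, n_tapers, nw)
    return RateTrace(diff, dt=actual.dt, kernel_sigma=float("nan")), freqs, Pxx


def _stack(responses: Sequence[BinarySequence]) -> np.ndarray:
    n = responses[0].n
    dt = responses[0].dt
    for r in responses:
        if r.n != n or abs(r.dt - dt) > 1e-12:
            raise DataError("all binary sequences must share length and dt")
    return np.stack([r.bits for r in responses])


def sr_coherence(
    stim: StimulusTrace,
    responses: BinarySequence | Sequence[BinarySequence],
    n_tapers: int = DEFAULT_N_TAPERS,
    nw: float = DEFAULT_NW,
) -> CoherenceSpectrum:
    """Stimulus-response coherence ``|P_SR|^2 / (P_SS P_RR)`` in [0, 1].

    With several repeats of the frozen stimulus, cross- and auto-spectra are
    first averaged over trials.
    """
    if isinstance(responses, BinarySequence):
        responses = [responses]
    R = _stack(responses)
    if R.shape[1] != stim.n:
        raise DataError("stimulus and responses must have equal length")
    if abs(stim.dt - responses[0].dt) > 1e-12:
        raise DataError("stimulus and responses must share dt")
    S = _tapered_fft(stim.values, nw, n_tapers)
    freqs = np.fft.rfftfreq(stim.n, stim.dt)
    Pss = (np.abs(S) ** 2).mean(axis=0)
    Psr = np.zeros_like(S[0])
    Prr = np.zeros(S.shape[1])
    for bits in R:
        F = _tapered_fft(bits, nw, n_tapers)
        Psr += (S * np.conj(F)).mean(axis=0)
        Prr += (np.abs(F) ** 2).mean(axis=0)
    Psr /= len(R)
    Prr /= len(R)
    denom = Pss * Prr
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, np.abs(Psr) ** 2 / denom, 0.0)
    return CoherenceSpectrum(
        freqs=freqs, values=C, kind="SR", k_trials=len(R), n_tapers=n_tapers
    )


def rr_coherence(
    responses: Sequence[BinarySequence],
    n_tapers: int = DEFAULT_N_TAPERS,
    nw: float = DEFAULT_NW,
) -> CoherenceSpectrum:
    """Response-response coherence across k >= 2 repeats of a frozen stimulus.

    ``C_RR = |mean_{j<i} P_RiRj|^2 / (mean_i P_RiRi)^2`` -- the pairwise
    cross-spectrum averaged over all k(k-1)/2 unordered pairs, normalized by
    the squared mean auto-spectrum.  The estimate is clipped to [0, 1]; the
    number of clipped frequencies is reported.
    """
    if len(responses) < 2:
        raise InsufficientDataError("RR coherence needs at least 2 repeats")
    R = _stack(responses)
    k, n = R.shape
    F = np.stack([_tapered_fft(bits, nw, n_tapers) for bits in R])
    freqs = np.fft.rfftfreq(n, responses[0].dt)
    Pauto = (np.abs(F) ** 2).mean(axis=1).mean(axis=0)
    acc = np.zeros(F.shape[2], dtype=complex)
    for i in range(1, k):
        for j in range(i):
            acc += (F[i] * np.conj(F[j])).mean(axis=0)
    acc /= k * (k - 1) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(Pauto > 0, np.abs(acc) ** 2 / Pauto**2, 0.0)
    n_clip = int(np.sum(C > 1.0))
    return CoherenceSpectrum(
        freqs=freqs,
        values=np.clip(C, 0.0, 1.0),
        kind="RR",
        k_trials=k,
        n_tapers=n_tapers,
        n_clipped=n_clip,
    )


def _band_mask(freqs: np.ndarray, band: tuple) -> np.ndarray:
    lo, hi = band
    if lo < freqs[0] - 1e-9 or hi > freqs[-1] + 1e-9 or hi <= lo:
        raise InvalidParameterError(f"band {band} outside the frequency grid")
    return (freqs >= lo) & (freqs <= hi)


def nonlinearity_index(
    csr: CoherenceSpectrum,
    crr: CoherenceSpectrum,
    band: tuple = (0.0, 100.0),
    sqrt_rr: bool = True,
) -> float:
    """Percent shortfall of integrated SR coherence vs the RR benchmark.

    ``100 * (1 - int C_SR / int sqrt(C_RR))`` over ``band`` (trapezoidal);
    ``sqrt_rr=False`` integrates C_RR itself instead of its square root.
    """
    if csr.freqs.shape != crr.freqs.shape or not np.allclose(csr.freqs, crr.freqs):
        raise DataError("coherences must share the frequency grid")
    m = _band_mask(csr.freqs, band)
    bench = np.sqrt(crr.values[m]) if sqrt_rr else crr.values[m]
    denom = np.trapezoid(bench, csr.freqs[m])
    if denom == 0:
        raise DataError("RR coherence integrates to zero; NI undefined")
    num = np.trapezoid(csr.values[m], csr.freqs[m])
    return 100.0 * (1.0 - num / denom)


def mi_density(
    crr: CoherenceSpectrum, firing_rate: float, eps: float = 1e-9
):
    """Mutual information rate density ``-log2(1 - C_RR(f)) / FR``.

    ``firing_rate`` is the mean rate during stimulation (spk/s); the density
    is in bits per spike per Hz.  C_RR values at 1 are clipped to ``1 - eps``;
    returns ``(freqs, density, n_clipped)``.
    """
    if firing_rate <= 0:
        raise InvalidParameterError("firing rate must be positive")
    C = crr.values
    n_clip = int(np.sum(C >= 1.0 - eps))
    C = np.clip(C, 0.0, 1.0 - eps)
    return crr.freqs, -np.log2(1.0 - C) / firing_rate, n_clip


def mi_rate(
    freqs: np.ndarray, density: np.ndarray, band: tuple = (0.0, 15.0)
) -> float:
    """Mutual information rate: trapezoidal integral of the density over band.

    With the density in bits/spike/Hz the result is in bits per spike.
    """
    m = _band_mask(np.asarray(freqs), band)
    return float(np.trapezoid(np.asarray(density)[m], np.asarray(freqs)[m]))
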