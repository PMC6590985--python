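"""Spike-train distances and template classification of stimulus segments.

Victor-Purpura (VP) distance: minimum cost of editing one train into the
other, with insertion/deletion cost 1 and a time shift by dt costing q*dt
(q in 1/s); 1/q is the temporal resolution of the metric.  van Rossum (VR)
distance: each train is convolved with a causal exponential kernel of time
constant tau and the distance is ``(1/tau) * int (f_a - f_b)^2 dt``,
evaluated in closed form over spike pairs.  (The conventional rooted form is
available via ``sqrt_distance=True``.)

Classification protocol: a 10 s frozen-noise epoch is trimmed by 500 ms at
each end and split into nine 1 s segments (nine stimulus categories).  Per
draw, one train per category is a template and every remaining train is
assigned to the category of its nearest template; 30 template draws are
averaged into a 9x9 confusion matrix.  Percent correct is the mean of the
diagonal of the row-normalized matrix (chance = 1/9).  Sweeping the metric
timescale yields a performance curve whose peak frequency (1/tau at maximum
performance) is the spike-timing precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from numba import njit

from .errors import InsufficientDataError, InvalidParameterError
from .types import SpikeTrain


@dataclass
class SegmentedResponses:
    """Per-category spike-time arrays (re-zeroed to segment onset)."""

    segments: List[List[np.ndarray]]  # [category][trial] -> spike times
    segment_length: float
    n_repeats: int

    @property
    def n_categories(self) -> int:
        return len(self.segments)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray          # (true, assigned), summed over draws
    n_template_draws: int

    @property
    def normalized(self) -> np.ndarray:
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(rows > 0, self.counts / rows, 0.0)

    @property
    def percent_correct(self) -> float:
        return 100.0 * float(np.mean(np.diag(self.normalized)))


@dataclass
class PerformanceCurve:
    timescales: np.ndarray      # s
    percent_correct: np.ndarray
    metric: str                 # "vp" | "vr"


@njit(cache=False)
def _vp_dp(a, b, q):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for j in range(m + 1):
        prev[j] = j
    for i in range(1, n + 1):
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, m + 1):
            shift = prev[j - 1] + q * abs(ai - b[j - 1])
            dele = prev[j] + 1.0
            ins = cur[j - 1] + 1.0
            c = shift
            if dele < c:
                c = dele
            if ins < c:
                c = ins
            cur[j] = c
        prev, cur = cur, prev
    return prev[m]


def vp_distance(a: SpikeTrain | np.ndarray, b: SpikeTrain | np.ndarray, q: float) -> float:
    """Victor-Purpura edit distance with shift cost q (1/s) per second."""
    if q < 0:
        raise InvalidParameterError("q must be >= 0")
    ta = a.spike_times if isinstance(a, SpikeTrain) else np.asarray(a, float)
    tb = b.spike_times if isinstance(b, SpikeTrain) else np.asarray(b, float)
    if ta.size == 0 or tb.size == 0:
        return float(ta.size + tb.size)
    return float(_vp_dp(ta, tb, q))


def vr_distance(
    a: SpikeTrain | np.ndarray,
    b: SpikeTrain | np.ndarray,
    tau: float,
    sqrt_distance: bool = False,
) -> float:
    """van Rossum distance with exponential kernel time constant ``tau`` (s).

    Closed form: with kernel ``exp(-t/tau)`` for t >= 0, the integral
    ``int_0^inf k(t-ti) k(t-tj) dt = (tau/2) exp(-|ti-tj|/tau)``, so

        D = (1/tau) int (f_a - f_b)^2
          = 0.5 * (sum_aa + sum_bb - 2 sum_ab) of exp(-|dt|/tau).
    """
    if tau <= 0:
        raise InvalidParameterError("tau must be positive")
    ta = a.spike_times if isinstance(a, SpikeTrain) else np.asarray(a, float)
    tb = b.spike_times if isinstance(b, SpikeTrain) else np.asarray(b, float)

    def cross(u, v):
        if u.size == 0 or v.size == 0:
            return 0.0
        return float(np.exp(-np.abs(u[:, None] - v[None, :]) / tau).sum())

    d = 0.5 * (cross(ta, ta) + cross(tb, tb) - 2.0 * cross(ta, tb))
    d = max(d, 0.0)  # guard tiny negative round-off
    return math.sqrt(d) if sqrt_distance else d


def segment_responses(
    trials: Sequence[SpikeTrain],
    epoch: float = 10.0,
    trim: float = 0.5,
    n_segments: int = 9,
    segment_length: float = 1.0,
) -> SegmentedResponses:
    """Split repeat trials of a frozen epoch into per-category spike trains.

    Discards ``trim`` seconds at each end of the epoch and cuts the remainder
    into ``n_segments`` categories of ``segment_length`` seconds, re-zeroing
    spike times to each segment onset.
    """
    if len(trials) < 2:
        raise InsufficientDataError("need at least 2 repeat trials")
    if len(trials) < 6:
        warnings.warn("fewer than 6 repeats; classification will be noisy")
    if epoch < 2 * trim + n_segments * segment_length - 1e-9:
        raise InvalidParameterError("epoch too short for trims plus segments")
    segments: List[List[np.ndarray]] = []
    for k in range(n_segments):
        lo = trim + k * segment_length
        cat = []
        for tr in trials:
            t = tr.spike_times
            cat.append(t[(t >= lo) & (t < lo + segment_length)] - lo)
        segments.append(cat)
    return SegmentedResponses(
        segments=segments, segment_length=segment_length, n_repeats=len(trials)
    )


def _distance_matrix(seg: SegmentedResponses, metric: str, param: float) -> np.ndarray:
    trains = [t for cat in seg.segments for t in cat]
    T = len(trains)
    D = np.zeros((T, T))
    for i in range(T):
        for j in range(i):
            if metric == "vp":
                d = vp_distance(trains[i], trains[j], param)
            else:
                d = vr_distance(trains[i], trains[j], param)
            D[i, j] = D[j, i] = d
    return D


def template_classify(
    seg: SegmentedResponses,
    metric: str = "vp",
    param: float = 100.0,
    n_draws: int = 30,
    seed: Optional[int] = 0,
    _D: Optional[np.ndarray] = None,
):
    """Nearest-template classification of stimulus segments.

    ``param`` is q (1/s) for VP or tau (s) for VR.  Each draw picks one
    random template per category (without replacement within the category)
    and assigns every non-template train to the category of the nearest
    template; distance ties break uniformly at random.  Returns
    ``(ConfusionMatrix, percent_correct)``.
    """
    if metric not in ("vp", "vr"):
        raise InvalidParameterError(f"unknown metric {metric!r}")
    nc = seg.n_categories
    R = seg.n_repeats
    for cat in seg.segments:
        if len(cat) < 2:
            raise InsufficientDataError("every category needs >= 2 trains")
    D = _distance_matrix(seg, metric, param) if _D is None else _D
    rng = np.random.default_rng(seed)
    counts = np.zeros((nc, nc))
    flat = lambda c, r: c * R + r
    for _ in range(n_draws):
        tmpl = [flat(c, rng.integers(len(seg.segments[c]))) for c in range(nc)]
        tmpl_set = set(tmpl)
        for c in range(nc):
            for r in range(R):
                i = flat(c, r)
                if i in tmpl_set:
                    continue
                d = D[i, tmpl]
                winners = np.flatnonzero(d == d.min())
                counts[c, rng.choice(winners)] += 1
    cm = ConfusionMatrix(counts=counts, n_template_draws=n_draws)
    return cm, cm.percent_correct


def default_timescale_grid(n: int = 30) -> np.ndarray:
    """Log-spaced metric timescales, 1 ms to 2000 ms, in seconds."""
    return np.geomspace(0.001, 2.0, n)


def performance_curve(
    seg: SegmentedResponses,
    metric: str = "vp",
    timescales: Optional[np.ndarray] = None,
    n_draws: int = 30,
    seed: Optional[int] = 0,
) -> PerformanceCurve:
    """Percent correct as a function of metric timescale tau.

    For VP the cost parameter is ``q = 1/tau``; for VR tau is the kernel time
    constant.
    """
    if timescales is None:
        timescales = default_timescale_grid()
    timescales = np.asarray(timescales, float)
    if timescales.size == 0:
        raise InvalidParameterError("empty timescale grid")
    pc = np.empty(timescales.size)
    for k, tau in enumerate(timescales):
        param = 1.0 / tau if metric == "vp" else tau
        _, pc[k] = template_classify(
            seg, metric=metric, param=param, n_draws=n_draws, seed=seed
        )
    return PerformanceCurve(timescales=timescales, percent_correct=pc, metric=metric)


def timing_precision(curve: PerformanceCurve, chance_margin: float = 1e-9):
    """Spike-timing precision: 1/tau* at the performance maximum (Hz).

    Ties resolve to the largest tau (lowest frequency).  A flat curve (no
    timescale beats the rest by more than ``chance_margin``) has undefined
    precision; returns ``(frequency_hz, defined)``.
    """
    pc = curve.percent_correct
    if pc.size == 0:
        raise InsufficientDataError("empty performance curve")
    best = pc.max()
    if best - pc.min() <= chance_margin:
        return float("nan"), False
    idx = np.flatnonzero(pc >= best - 1e-12)
    tau_star = curve.timescales[idx].max()
    return 1.0 / float(tau_star), True
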