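# Methods

## The scientific question

Vestibular otolith afferents fall into two classes by the regularity of
their resting discharge: *regular* units (low normalized ISI coefficient of
variation, CV\*) and *irregular* units (high CV\*).  The package implements
the full analysis chain used to ask how the two classes encode linear
self-motion: through slow firing-rate modulations (rate coding, gain,
linear systems analysis), through precisely timed spikes (spike-distance
classification, phase locking), and through static rate offsets (ideal
observer discrimination of head tilt).  Because the package is
simulation-driven, every analysis runs against spike trains from a
stochastic leaky integrate-and-fire (LIF) afferent model rather than
recordings.

## The afferent model

Membrane dynamics, with V the deviation from rest (mV):

    Cm dV/dt = -g V + I_bias + sigma_signal * S(t) + sigma_noise * xi(t)

with Cm = 1 nF, g = 0.22 uS (tau_m = Cm/g ~ 4.55 ms), I_bias = 3.53 nA.  A
spike is recorded when V crosses the threshold from below, and V resets to
0 mV.  Integration is Euler–Maruyama at dt = 0.025 ms; the noise increment
per step is `sigma_noise * sqrt(dt_ms) * N(0,1)`, i.e. `sigma_noise` is the
standard deviation of the noise current accumulated over a 1 ms reference
window.  This convention is configurable because the physical bandwidth of
the intrinsic noise is a modelling choice; the 1 ms reference is the one
that reproduces the intended resting regularity of both classes at their
calibrated rates.

The two classes differ only in the co-varied sensitivity and variability
scales, with their ratio fixed at one:

* regular:  sigma_noise = sigma_signal = 0.14 nA, resting rate 85 spk/s
* irregular: sigma_noise = sigma_signal = 1.9 nA, resting rate 71 spk/s

**Threshold.**  A threshold voltage stated jointly with a reset *above* it
is dynamically impossible, so the threshold is treated as the free
parameter of the model and calibrated by bisection so that the simulated
resting rate matches the class target (85 / 71 spk/s).  The calibration
reuses one noise realization across trial thresholds (common random
numbers), which makes the simulated rate monotone in the threshold and the
bisection deterministic under a seed.  For the noiseless model the
closed-form ISI `tau_m * ln(V_inf/(V_inf - theta))`, `V_inf = I_bias/g`,
doubles as an oracle: simulated deterministic ISIs match it to <0.5%.

With these conventions the calibrated regular model rests at CV\* ~ 0.066
and the irregular model at CV\* ~ 0.50.  The irregular threshold calibrates
*above* V_inf, i.e. the irregular model fires only by noise excursions —
the mechanism that produces its high ISI variability.

**Stimulus-to-current conversion.**  The naturalistic stimulus is
acceleration in G; the model needs current.  The package divides
acceleration by a reference of 0.1 G (the naturalistic stimulus SD) and
multiplies by `sigma_signal`, so the frozen naturalistic stimulus drives a
signal current whose SD is exactly `sigma_signal`.  This is the only
convention under which `sigma_signal` *is* the signal strength and the
ratio constraint sigma_signal/sigma_noise = 1 is literal.  It makes the
model's in-band signal-to-noise ratio higher than that of real afferents
(see Limitations).  The reference acceleration is configurable
(`stimulus.A_REF` / the `a_ref` argument).  An optional one-parameter
high-pass-plus-constant filter stands in for class-specific response
dynamics; the default is the identity.

**Tilt.**  A static tilt by angle theta exposes the afferent to a gravity
shear `g0 sin(theta)`.  Because this is the same physical force for every
unit, it enters the model as a constant current offset *not* scaled by
`sigma_signal`, at a configurable 1 nA per G.  The regular-vs-irregular
d' ordering does not depend on this scale, since both classes receive the
identical offset and differ only in rate variance.

## Stimuli

* Naturalistic translation: Gaussian white noise, zero-phase FIR low-pass
  (windowed sinc, cutoff 20 Hz), re-standardized to exact mean 0 / SD 0.1 G;
  one frozen 10 s realization repeated 10 times per unit.
* Sinusoidal translation: 1–10 Hz, 0.2 G peak, sine phase zero at onset.
* Static tilt: 3, 6, 9, 15 degrees plus the upright reference, >= 10 s
  epochs.

## Analyses

**Regularity.**  CV = SD/mean of the ISIs; CV\* maps CV to a reference mean
ISI of 15 ms through a configurable power law `CV* = CV (ISI_ref/ISI)^beta`
with beta = 0 by default (the model's resting ISIs of 12–14 ms sit at the
reference, so CV ~ CV\*).  Classification boundary: 0.15 (midpoint of the
exemplar class values 0.06 and 0.29), ties to irregular.

**Rate coding.**  Firing rates are spike density functions (Gaussian
kernel, SD 10 ms, 1 kHz sampling; kernels truncated at record edges without
renormalization).  All spectra are multitaper estimates with 8 Slepian
tapers; the time–bandwidth product NW = 4.5 follows K = 2NW − 1 = 8, with
whole-record (10 s) estimation and a 0.1 Hz grid.  The transfer function is
H(f) = P_S,fr / P_SS (gain |H| in (spk/s)/G, masked where stimulus power is
< 1e-4 of its peak); the linear prediction is the impulse response of H
(truncated to ±1 s lags to avoid circular wrap-around) convolved with the
stimulus plus the baseline rate, and the residual is the pointwise
difference.

**Coherence and information.**  Spike trains are binarized at 1 ms (bin
[k, k+1) ms; multiple spikes per bin collapse and are counted).  SR
coherence: |P_SR|^2 / (P_SS P_RR), trial-averaged.  RR coherence across k
repeats: |mean over pairs j<i of P_RiRj|^2 / (mean auto-spectrum)^2,
clipped to [0,1] with a clip count.  Mutual information rate density:
−log2(1 − C_RR)/FR with FR the mean stimulated rate; the MI rate is its
trapezoidal integral over 0–15 Hz, in bits per spike.

**Nonlinearity index.**  A linear encoder satisfies C_SR = sqrt(C_RR), so
the package defaults to

    NI = 100 * (1 − ∫ C_SR df / ∫ sqrt(C_RR) df),   band 0–100 Hz.

The variant without the square root is available (`sqrt_rr=False`,
CLI `--no-sqrt-rr`) but is *not* the default: for near-linear responses it
goes negative (the regular model measures ~ −13% under it), which is
inconsistent with NI being a nonnegative nonlinearity percentage and with
the ~20% regular-class values the rooted form reproduces.

**Spike-timing metrics.**  Victor–Purpura distance by the standard O(nm)
dynamic program (insert/delete cost 1, shift cost q·dt); q = 0 reduces to
the spike-count difference; the implementation is tested against an
exhaustive matching oracle on small trains.  van Rossum distance in closed
form over spike pairs, `0.5 Σ ± exp(−|Δt|/tau)`, equal to (1/tau)·∫(f_a −
f_b)² for causal exponential filtered trains (no square root, matching the
squared-distance convention; a rooted variant exists and is what the metric
property tests use for the triangle inequality).  Classification: 10 s
epochs are trimmed by 500 ms per end and cut into nine 1 s categories; per
draw one random template per category, nearest-template assignment of all
non-templates, distance ties broken uniformly at random; 30 draws average
into a 9×9 confusion matrix; percent correct is the mean diagonal of the
row-normalized matrix (chance 1/9).  Performance curves sweep 30 log-spaced
timescales in 1–2000 ms (q = 1/tau for VP); spike-timing precision is
1/tau* at the performance maximum, ties resolving to the *largest* timescale
(lowest frequency).

**Phase locking.**  PLI1 vector strength; PLI2 = 1 − E0/Emax from a
32-bin cycle histogram (bin count configurable; with 16/32/64 bins the
model indices change by < 0.03 because the histograms are smooth at these
spike counts); PLI3 = 1 − rho·N/mu_ISI from the OLS slope rho of first-spike
latency vs. latency-ordered cycle index, cycles without spikes excluded,
clipped to [0,1] with a flag.  Class comparisons use the 10 Hz response.

**Tilt discriminability.**  Rates from the SDF, first/last 2 s trimmed,
histogrammed at 4 spk/s for reporting; d' = |mu_theta − mu_0| /
sqrt((var_theta + var_0)/2) computed from the sample moments (not histogram
midpoints).  Identical zero-variance distributions give 0; differing means
with zero variance give +inf.

## Determinism and seeding

Every stochastic stage takes a seed; population and pipeline stages derive
child seeds from the master seed through `numpy.random.SeedSequence`
spawning, so stages are independently re-runnable and whole runs are
byte-reproducible (the pipeline regression test compares summary files
byte-for-byte).

## Problem sizes

Defaults mirror the experimental protocol: 10 s × 10 naturalistic repeats,
100 s resting records, >= 10 s tilt epochs.  The test suite and the
reproduction script use 10–20 seeded replicates per class for stochastic
quantities, 100 s resting simulations for CV\*, and 12-point timescale
grids with 15 template draws for the classification sweeps inside
replicated ordering checks (the standalone analysis default remains 30
points × 30 draws).

## What the generator does and does not emulate

The generator reproduces: the two-class regularity split at matched resting
rates, stimulus-locked rate modulation, trial-to-trial variability driven
by intrinsic noise, tilt-induced rate offsets, and phase locking.  It does
not emulate: hair-cell/synaptic dynamics, class-specific response dynamics
(gain growing with frequency is only available through the optional
high-pass filter), efferent effects, 3-D kinematics, or inter-unit
heterogeneity beyond the two parameter sets.  Consequently, passing tests
establish the correctness and internal consistency of the estimators and
the direction of the class contrasts, not quantitative agreement with any
particular recorded afferent.

## Known limitations

* With the unit-variance signal convention the model's in-band SNR, and
  hence its RR coherence (~0.87 in 0–15 Hz) and MI rate (~0.5 bits/spk for
  both classes), sit above typical real-afferent values; the MI class
  difference, while in the right direction, is small.
* The irregular model's segment discrimination saturates at 100% over a
  wide range of timescales; under the documented largest-timescale
  tie-break its measured "precision" is then *lower* than the regular
  model's, inverting the expected class ordering of peak frequencies.  The
  performance ordering itself (irregular above regular at matched
  timescales, by a large margin) is robust.
* The irregular model's resting CV\* (~0.50) overshoots the intended 0.42;
  at a calibrated 71 spk/s with the 1 ms noise reference there is no free
  parameter left to move it without changing a printed constant.
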