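# otokit

Spike-train information-coding analysis for vestibular **otolith
afferents**, driven by a stochastic leaky integrate-and-fire (LIF) afferent
simulator.  Otolith afferents split into *regular* and *irregular* classes
by the normalized coefficient of variation (CV\*) of their resting
interspike intervals, and the two classes encode linear self-motion
differently.  `otokit` is for computational neuroscientists who want the
complete analysis chain behind that comparison — with synthetic data, so
nothing needs to be downloaded or recorded:

* **Afferent model** — LIF membrane `Cm dV/dt = -gV + I_bias +
  sigma_signal*S(t) + sigma_noise*xi(t)` (Euler–Maruyama, dt = 0.025 ms),
  threshold calibrated to the class resting rate; sensitivity and
  variability co-varied at ratio 1 (regular 0.14 nA, irregular 1.9 nA).
* **Stimuli** — frozen 10 s naturalistic translation (20 Hz low-pass
  Gaussian noise, SD 0.1 G), sinusoids (1–10 Hz, 0.2 G), static tilts.
* **Rate coding** — Gaussian spike-density rates (SD 10 ms), multitaper
  (8 Slepian tapers) transfer function and gain, linear rate prediction
  and residual.
* **Information** — SR coherence `|P_SR|^2/(P_SS P_RR)` of the 1 ms binary
  sequence, RR coherence across repeats, nonlinearity index
  `NI = 100(1 - ∫C_SR/∫sqrt(C_RR))` over 0–100 Hz, mutual information rate
  `∫ -log2(1-C_RR)/FR df` over 0–15 Hz in bits/spike.
* **Spike timing** — Victor–Purpura (dynamic program) and van Rossum
  (closed form) distances, nine-category nearest-template classification,
  performance curves over 1–2000 ms timescales, spike-timing precision.
* **Phase locking** — vector strength (PLI1), cycle-histogram entropy
  (PLI2), first-spike latency dispersion (PLI3).
* **Static orientation** — firing-rate distributions (4 spk/s bins, 2 s
  trims) and signal-detection `d' = |Δμ|/sqrt((σ²_θ+σ²_0)/2)` per tilt
  angle.

See `docs/methods.md` for the model conventions, estimator choices and
known limitations.

## Worked example

```python
import numpy as np
from otokit import (class_params, simulate_lif, isi_statistics,
                    classify_regularity, generate_noise_stimulus,
                    filter_stimulus_dynamics, binary_sequence, rr_coherence,
                    sr_coherence, mi_density, mi_rate, nonlinearity_index)

# irregular model afferent, threshold calibrated to a 71 spk/s resting rate
params = class_params("irregular", seed=0)

rest = simulate_lif(params, duration=100.0, seed=1)
stats = isi_statistics(rest)
print(f"resting rate {rest.rate:.1f} spk/s, CV* {stats.cv_star:.3f} ->",
      classify_regularity(stats.cv_star))

# ten repeats of a frozen naturalistic stimulus
stim = generate_noise_stimulus(10.0, cutoff=20.0, sd=0.1, seed=2)
current = filter_stimulus_dynamics(stim, params)
trains = [simulate_lif(params, input_current=current, seed=10 + r)
          for r in range(10)]

seqs = [binary_sequence(t) for t in trains]
crr = rr_coherence(seqs)                 # repeat-to-repeat coherence
csr = sr_coherence(stim, seqs)           # stimulus-response coherence
fr = float(np.mean([t.rate for t in trains]))
freqs, dens, _ = mi_density(crr, fr)
print(f"MI rate {mi_rate(freqs, dens):.3f} bits/spk")
print(f"NI {nonlinearity_index(csr, crr):.1f} %")
```

prints

```
resting rate 71.5 spk/s, CV* 0.517 -> irregular
MI rate 0.537 bits/spk
NI 29.7 %
```

The resting CV\* (0.52) lands in the irregular class; the repeat-to-repeat
coherence of this strongly driven unit yields about half a bit of stimulus
information per spike over the naturalistic band, and the SR coherence
falls ~30% short of the linear-encoder benchmark `sqrt(C_RR)` — the
irregular class transmits a sizable share of its information through
nonlinear (spike-timing) structure.  Running the same code with
`class_params("regular", ...)` gives CV\* ≈ 0.066 and a smaller
nonlinearity index, and `otokit discriminate` shows the reverse ordering
for static-tilt d' (regular above irregular).

## Command line

```bash
otokit simulate --seed 1 --out runs/sim          # population -> CSV bundles
otokit coherence --stimulus runs/sim/stimulus.csv --spikes nat.csv --out runs/coh
otokit timing --spikes nat.csv --metric vp --out runs/timing
otokit phaselock --afferent-class irregular --freqs 1:10 --out runs/pli
otokit discriminate --angles 3,6,9,15 --out dprime.csv
otokit run-all --seed 1 --out runs/full          # everything, one report
otokit sweep --sigmas 0.14,0.5,1.9 --out sweep.csv
```

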