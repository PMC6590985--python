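import numpy as np
import pytest

from otokit.discharge import RateTrace, sdf_firing_rate
from otokit.errors import (
    DataError,
    InsufficientDataError,
    InvalidParameterError,
)
from otokit.spectral import (
    BinarySequence,
    CoherenceSpectrum,
    binary_sequence,
    linear_prediction,
    mi_density,
    mi_rate,
    multitaper_cross_spectrum,
    nonlinearity_index,
    residual,
    rr_coherence,
    sr_coherence,
    transfer_function,
)
from otokit.stimulus import generate_noise_stimulus
from otokit.types import SpikeTrain, StimulusTrace


class TestBinarySequence:
    def test_empty_train(self):
        b = binary_sequence(SpikeTrain([], duration=0.1))
        assert b.n == 100 and b.bits.sum() == 0

    def test_bin_convention(self):
        b = binary_sequence(SpikeTrain([0.0015, 0.0035], duration=0.01))
        assert list(np.flatnonzero(b.bits)) == [1, 3]
        assert b.n_collisions == 0

    def test_collision_collapses_and_counts(self):
        b = binary_sequence(SpikeTrain([0.0012, 0.0019], duration=0.01))
        assert b.bits.sum() == 1 and b.n_collisions == 1


class TestMultitaper:
    def test_autospectrum_real_nonnegative(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        f, Pxy, Pxx, Pyy = multitaper_cross_spectrum(x, x.copy())
        assert np.allclose(Pxy.imag, 0, atol=1e-12)
        assert np.all(Pxx >= 0) and np.allclose(Pxx, Pyy)

    def test_sinusoid_concentrates_within_bandwidth(self):
        t = np.arange(10_000) * 0.001
        x = np.sin(2 * np.pi * 2.0 * t)
        f, _, Pxx, _ = multitaper_cross_spectrum(x, x)
        bw = 4.5 / 10.0  # NW / T
        inband = Pxx[np.abs(f - 2.0) <= 2 * bw].sum()
        assert inband / Pxx.sum() > 0.99

    def test_independent_noise_low_cross(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(50_000), rng.standard_normal(50_000)
        f, Pxy, Pxx, Pyy = multitaper_cross_spectrum(x, y)
        coh = np.abs(Pxy) ** 2 / (Pxx * Pyy)
        assert np.median(coh) < 0.3  # chance level ~1/8 for 8 tapers

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            multitaper_cross_spectrum(np.zeros(10), np.zeros(11))


class TestTransferFunction:
    def test_scaled_stimulus_gain(self):
        stim = generate_noise_stimulus(10.0, 20.0, 0.1, seed=2)
        rate = RateTrace(2.0 * stim.values + 50.0)
        tf = transfer_function(stim, rate)
        band = (tf.freqs > 0.5) & (tf.freqs < 15)
        assert np.nanmedian(tf.gain[band]) == pytest.approx(2.0, rel=1e-6)

    def test_delay_phase_slope(self):
        stim = generate_noise_stimulus(10.0, 20.0, 0.1, seed=3)
        d = 10  # samples = 10 ms
        rate = RateTrace(np.roll(stim.values, d))
        tf = transfer_function(stim, rate)
        band = (tf.freqs > 0.5) & (tf.freqs < 10)
        assert np.nanmedian(tf.gain[band]) == pytest.approx(1.0, rel=0.05)
        phase = np.unwrap(np.angle(tf.H[band]))
        slope = np.polyfit(tf.freqs[band], phase, 1)[0]
        assert slope == pytest.approx(-2 * np.pi * 0.010, rel=0.05)

    def test_out_of_band_masked(self):
        stim = generate_noise_stimulus(10.0, 20.0, 0.1, seed=4)
        rate = RateTrace(stim.values.copy())
        tf = transfer_function(stim, rate)
        assert np.isnan(tf.H[tf.freqs > 100]).mean() > 0.9


class TestLinearPrediction:
    def test_zero_stimulus_gives_baseline(self):
        stim = generate_noise_stimulus(4.0, 20.0, 0.1, seed=5)
        rate = RateTrace(1.5 * stim.values + 80.0)
        tf = transfer_function(stim, rate)
        zero = StimulusTrace(np.zeros(stim.n), dt=stim.dt)
        pred = linear_prediction(tf, zero, baseline=80.0)
        assert np.allclose(pred.values, 80.0)

    def test_self_consistency_on_linear_system(self):
        stim = generate_noise_stimulus(10.0, 20.0, 0.1, seed=6)
        rate = RateTrace(3.0 * stim.values + 70.0)
        tf = transfer_function(stim, rate)
        pred = linear_prediction(tf, stim, baseline=70.0)
        sl = slice(1000, -1000)  # interior, away from convolution edges
        ss_res = np.sum((rate.values[sl] - pred.values[sl]) ** 2)
        ss_tot = np.sum((rate.values[sl] - rate.values[sl].mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_residual_of_perfect_prediction_is_zero(self):
        rt = RateTrace(np.full(5000, 60.0))
        diff, f, p = residual(rt, rt)
        assert np.all(diff.values == 0) and np.all(p == 0)

    def test_residual_power_irregular_exceeds_regular(self, naturalistic_pair, frozen_stimulus):
        powers = {}
        for rec in naturalistic_pair:
            rates = [sdf_firing_rate(t) for t in rec.naturalistic]
            mean_rate = RateTrace(np.mean([r.values for r in rates], axis=0))
            tf = transfer_function(frozen_stimulus, mean_rate)
            pred = linear_prediction(
                tf, frozen_stimulus, baseline=float(mean_rate.values.mean())
            )
            tot = 0.0
            for r in rates:
                diff, f, p = residual(r, pred)
                tot += p[(f > 0) & (f <= 100)].sum()
            powers[rec.afferent_class] = tot
        assert powers["irregular"] > powers["regular"]


def _spectrum(freqs, values, kind="RR", k=10):
    return CoherenceSpectrum(freqs=freqs, values=values, kind=kind, k_trials=k)


class TestCoherence:
    def test_sr_of_identical_series_is_one(self):
        stim = generate_noise_stimulus(5.0, 20.0, 0.1, seed=7)
        resp = BinarySequence(bits=stim.values.copy())
        c = sr_coherence(stim, resp)
        band = (c.freqs > 0.5) & (c.freqs < 15)
        assert np.allclose(c.values[band], 1.0, atol=1e-9)

    def test_sr_bounded_and_below_sqrt_rr(self, naturalistic_pair, frozen_stimulus):
        rec = naturalistic_pair[1]
        seqs = [binary_sequence(t) for t in rec.naturalistic]
        csr = sr_coherence(frozen_stimulus, seqs)
        crr = rr_coherence(seqs)
        assert np.all(csr.values <= 1.0) and np.all(csr.values >= 0.0)
        band = (csr.freqs >= 0.5) & (csr.freqs <= 15.0)
        # linearity bound: SR coherence cannot beat sqrt(RR) except by estimator noise
        assert np.mean(
            csr.values[band] <= np.sqrt(crr.values[band]) + 0.05
        ) > 0.95

    def test_rr_identical_repeats_is_one(self):
        rng = np.random.default_rng(8)
        bits = (rng.random(4000) < 0.08).astype(float)
        seqs = [BinarySequence(bits=bits.copy()) for _ in range(4)]
        c = rr_coherence(seqs)
        assert np.allclose(c.values[1:], 1.0, atol=1e-9)

    def test_rr_independent_trains_near_zero(self):
        rng = np.random.default_rng(9)
        seqs = [
            BinarySequence(bits=(rng.random(20_000) < 0.08).astype(float))
            for _ in range(8)
        ]
        c = rr_coherence(seqs)
        assert c.values.mean() < 0.02

    def test_rr_two_repeats_reduces_to_single_pair(self):
        rng = np.random.default_rng(10)
        a = (rng.random(2000) < 0.1).astype(float)
        b = (rng.random(2000) < 0.1).astype(float)
        c = rr_coherence([BinarySequence(bits=a), BinarySequence(bits=b)])
        from otokit.spectral import multitaper_cross_spectrum as mt
        f, Pab, Paa, Pbb = mt(a, b)
        manual = np.abs(Pab) ** 2 / ((Paa + Pbb) / 2) ** 2
        np.testing.assert_allclose(c.values, np.clip(manual, 0, 1), atol=1e-9)

    def test_rr_requires_two_repeats(self):
        with pytest.raises(InsufficientDataError):
            rr_coherence([BinarySequence(bits=np.zeros(100))])


class TestNonlinearityIndex:
    freqs = np.linspace(0.0, 100.0, 1001)

    def test_equal_curves_zero(self):
        c = np.full_like(self.freqs, 0.6)
        ni = nonlinearity_index(
            _spectrum(self.freqs, c, "SR"), _spectrum(self.freqs, c), sqrt_rr=False
        )
        assert ni == pytest.approx(0.0, abs=1e-9)

    def test_zero_sr_is_total_nonlinearity(self):
        ni = nonlinearity_index(
            _spectrum(self.freqs, np.zeros_like(self.freqs), "SR"),
            _spectrum(self.freqs, np.full_like(self.freqs, 0.5)),
        )
        assert ni == pytest.approx(100.0)

    def test_half_ratio_gives_fifty_percent(self):
        c = np.full_like(self.freqs, 0.8)
        ni = nonlinearity_index(
            _spectrum(self.freqs, 0.5 * c, "SR"), _spectrum(self.freqs, c),
            sqrt_rr=False,
        )
        assert ni == pytest.approx(50.0)

    def test_sqrt_benchmark_zero_for_linear_encoder(self):
        c = np.full_like(self.freqs, 0.49)
        ni = nonlinearity_index(
            _spectrum(self.freqs, np.sqrt(c), "SR"), _spectrum(self.freqs, c),
            sqrt_rr=True,
        )
        assert ni == pytest.approx(0.0, abs=1e-9)

    def test_zero_rr_undefined(self):
        with pytest.raises(DataError):
            nonlinearity_index(
                _spectrum(self.freqs, np.zeros_like(self.freqs), "SR"),
                _spectrum(self.freqs, np.zeros_like(self.freqs)),
            )


class TestMutualInformation:
    freqs = np.linspace(0.0, 50.0, 501)

    def test_zero_coherence_zero_density(self):
        f, d, nc = mi_density(_spectrum(self.freqs, np.zeros_like(self.freqs)), 80.0)
        assert np.all(d == 0) and nc == 0

    def test_half_coherence_unit_rate(self):
        f, d, _ = mi_density(
            _spectrum(self.freqs, np.full_like(self.freqs, 0.5)), 1.0
        )
        assert np.allclose(d, 1.0)

    def test_saturated_coherence_clipped_with_flag(self):
        c = np.full_like(self.freqs, 1.0)
        f, d, nc = mi_density(_spectrum(self.freqs, c), 10.0)
        assert nc == self.freqs.size and np.all(np.isfinite(d))

    def test_rate_must_be_positive(self):
        with pytest.raises(InvalidParameterError):
            mi_density(_spectrum(self.freqs, np.zeros_like(self.freqs)), 0.0)

    def test_mi_rate_integrates_density(self):
        d = np.full_like(self.freqs, 0.02)
        assert mi_rate(self.freqs, d, (0.0, 15.0)) == pytest.approx(0.3)
        assert mi_rate(self.freqs, np.zeros_like(d)) == 0.0

    def test_band_outside_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            mi_rate(self.freqs, np.zeros_like(self.freqs), (0.0, 200.0))
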