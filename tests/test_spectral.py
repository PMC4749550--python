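"""Spectral estimation: wavelet/filter-Hilbert power, dB baseline,
cluster mask, zero-phase filtering."""

import numpy as np
import pytest

from postdecision import spectral as sp
from conftest import make_epochs

FS = 256.0


def sine(freq, n=1024, amp=1.0, fs=FS):
    t = (np.arange(n) - n // 2) / fs
    return amp * np.sin(2 * np.pi * freq * t), t


class TestMorlet:
    def test_peak_at_input_frequency(self):
        x, _ = sine(6.0)
        tf = sp.morlet_tf(make_epochs(x), "FCtheta")
        peak = tf.freqs[np.argmax(tf.power[0].mean(axis=1))]
        assert abs(peak - 6.0) < 0.5

    def test_power_scales_quadratically(self):
        x, _ = sine(6.0)
        tf1 = sp.morlet_tf(make_epochs(x), "FCtheta")
        tf2 = sp.morlet_tf(make_epochs(2 * x), "FCtheta")
        mid = slice(300, 700)
        np.testing.assert_allclose(tf2.power[0][:, mid],
                                   4 * tf1.power[0][:, mid], rtol=1e-6)

    def test_zero_signal_zero_power(self):
        tf = sp.morlet_tf(make_epochs(np.zeros(600)), "FCtheta")
        assert np.allclose(tf.power, 0.0)

    def test_above_nyquist_rejected(self):
        x, _ = sine(6.0)
        with pytest.raises(ValueError):
            sp.morlet_tf(make_epochs(x), "FCtheta",
                         freqs=np.array([10.0, 200.0]))

    def test_cycle_rule_endpoints(self):
        c = sp.cycle_rule(np.linspace(1, 30, 90))
        assert c[0] == pytest.approx(2.0)
        assert c[-1] == pytest.approx(12.0)


class TestHilbertBandPower:
    def test_in_band_unit_sine_power_near_one(self):
        x, t = sine(5.0)
        hp = sp.hilbert_band_power(make_epochs(x), "FCtheta")
        mid = (t > -1) & (t < 1)
        assert hp.power[0, mid].mean() == pytest.approx(1.0, rel=0.10)

    def test_stopband_attenuation(self):
        x, t = sine(20.0)
        hp = sp.hilbert_band_power(make_epochs(x), "FCtheta")
        mid = (t > -1) & (t < 1)
        assert hp.power[0, mid].mean() < 0.01  # >= 20 dB down

    def test_superposition(self):
        x5, t = sine(5.0)
        x20, _ = sine(20.0)
        hp = sp.hilbert_band_power(make_epochs(x5 + x20), "FCtheta")
        mid = (t > -1) & (t < 1)
        assert hp.power[0, mid].mean() == pytest.approx(1.0, rel=0.10)

    def test_band_outside_nyquist_rejected(self):
        x, _ = sine(5.0)
        with pytest.raises(ValueError):
            sp.hilbert_band_power(make_epochs(x), "FCtheta", band=(2.0, 200.0))

    def test_agrees_with_wavelet_on_burst(self):
        # a theta burst measured by both estimators gives time courses
        # that correlate strongly
        n = 1024
        t = (np.arange(n) - n // 2) / FS
        rng = np.random.default_rng(0)
        x = (np.exp(-t ** 2 / (2 * 0.15 ** 2)) * np.sin(2 * np.pi * 5.0 * t)
             + 0.05 * rng.standard_normal(n))
        ep = make_epochs(x)
        hp = sp.hilbert_band_power(ep, "FCtheta")
        tf = sp.morlet_tf(ep, "FCtheta")
        sel = (tf.freqs >= 2) & (tf.freqs <= 7)
        wav = tf.power[0][sel].mean(axis=0)
        mid = (t > -1.5) & (t < 1.5)
        r = np.corrcoef(hp.power[0, mid], wav[mid])[0, 1]
        assert r > 0.9


class TestDbNormalize:
    def test_baseline_maps_to_zero_db(self):
        power = np.full((4, 100), 3.0)
        tf = sp.TFPower(power=power, times=np.linspace(-0.5, 0.5, 100))
        out = sp.db_normalize(tf, (-0.4, -0.1))
        assert np.allclose(out.power, 0.0)
        assert out.normalization == "dB"

    def test_tenfold_power_is_ten_db(self):
        times = np.linspace(-0.5, 0.5, 100)
        power = np.where(times >= 0, 10.0, 1.0)[None, :].repeat(3, axis=0)
        tf = sp.TFPower(power=power, times=times)
        out = sp.db_normalize(tf, (-0.4, -0.1))
        assert np.allclose(out.power[:, times >= 0], 10.0)

    def test_groupwise_baselines_are_independent(self):
        times = np.linspace(-0.5, 0.5, 50)
        power = np.vstack([np.full((2, 50), 1.0), np.full((2, 50), 4.0)])
        tf = sp.TFPower(power=power, times=times)
        groups = np.array([0, 0, 1, 1])
        out = sp.db_normalize(tf, (-0.4, -0.1), groups=groups)
        assert np.allclose(out.power, 0.0)  # each condition vs its own baseline
        pooled = sp.db_normalize(tf, (-0.4, -0.1))
        assert not np.allclose(pooled.power, 0.0)

    def test_nonpositive_baseline_fails(self):
        tf = sp.TFPower(power=np.zeros((2, 50)),
                        times=np.linspace(-0.5, 0.5, 50))
        with pytest.raises(ValueError):
            sp.db_normalize(tf, (-0.4, -0.1))


class TestSignificanceMask:
    def _null_subjects(self, rng, n_subj=8, n_f=20, n_t=120):
        return rng.standard_normal((n_subj, n_f, n_t)) * 0.1 + 1.0

    def test_null_data_yields_empty_mask(self, rng):
        times = np.linspace(-0.5, 1.5, 120)
        freqs = np.linspace(1, 30, 20)
        p = self._null_subjects(rng)
        mask = sp.tf_significance_mask(p, times, freqs, (-0.4, -0.1))
        assert mask.mean() < 0.01

    def test_injected_burst_detected_as_cluster(self, rng):
        times = np.linspace(-0.5, 1.5, 120)
        freqs = np.linspace(1, 30, 20)
        p = self._null_subjects(rng)
        burst_t = (times > 0.0) & (times < 0.6)
        burst_f = slice(2, 8)
        p[:, burst_f, :][:, :, burst_t] += 2.0
        mask = sp.tf_significance_mask(p, times, freqs, (-0.4, -0.1))
        assert mask[burst_f, :][:, burst_t].mean() > 0.8
        assert mask[15:, :].mean() < 0.05

    def test_min_duration_longer_than_epoch_empties_mask(self, rng):
        times = np.linspace(-0.5, 1.5, 120)
        freqs = np.linspace(1, 30, 20)
        p = self._null_subjects(rng)
        p[:, 2:8, 60:] += 2.0
        mask = sp.tf_significance_mask(p, times, freqs, (-0.4, -0.1),
                                       min_duration=10.0)
        assert not mask.any()

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            sp.tf_significance_mask(np.ones((2, 5, 10)), np.arange(10.0),
                                    np.arange(5.0), (0, 2))


class TestLowpass:
    def test_dc_preserved(self):
        x = np.full((1, 512), 2.5)
        out = sp.lowpass(x, FS, 6.0)
        np.testing.assert_allclose(out, 2.5, rtol=1e-6)

    def test_attenuation_and_passband(self):
        x20, t = sine(20.0)
        assert np.abs(sp.lowpass(x20[None], FS, 6.0)[0, 200:800]).max() < 0.1
        x1, _ = sine(1.0)
        kept = sp.lowpass(x1[None], FS, 10.0)[0, 200:800]
        assert np.abs(kept).max() == pytest.approx(1.0, rel=0.05)

    def test_zero_phase_preserves_peak_latency(self):
        n = 1024
        t = (np.arange(n) - n // 2) / FS
        x = np.exp(-t ** 2 / (2 * 0.1 ** 2))
        out = sp.lowpass(x[None], FS, 6.0)[0]
        assert abs(int(np.argmax(out)) - int(np.argmax(x))) <= 1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            sp.lowpass(np.zeros((1, 100)), FS, 200.0)
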