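"""Single-trial metric extraction: amplitudes, build-up rates, peak
latencies, RT binning and bin contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from postdecision import metrics as M

FS = 256.0


def grid(t0=-0.5, t1=1.0):
    n = int(round((t1 - t0) * FS)) + 1
    return t0 + np.arange(n) / FS


class TestAmplitude:
    def test_constant_signal(self):
        t = grid()
        data = np.full((3, t.size), 2.0)
        np.testing.assert_allclose(M.window_mean(data, t, (-0.1, 0.4)), 2.0)

    def test_linear_ramp_mean_is_midpoint(self):
        t = grid(0.0, 1.0)
        data = t[None, :].copy()  # ramp 0 -> 1 over 1 s
        assert M.window_mean(data, t, (0.0, 1.0))[0] == pytest.approx(0.5, abs=1e-3)

    def test_window_outside_epoch_fails(self):
        t = grid()
        with pytest.raises(ValueError):
            M.window_mean(np.zeros((1, t.size)), t, (5.0, 6.0))


class TestBuildup:
    def test_exact_ramp_slope(self):
        t = grid()
        for k in (-1.3, 0.0, 2.7):
            data = (k * t)[None, :]
            assert M.window_slope(data, t, (0.1, 0.3))[0] == pytest.approx(k, abs=1e-9)

    def test_constant_gives_zero(self):
        t = grid()
        assert M.window_slope(np.full((1, t.size), 5.0), t, (0.0, 0.2))[0] == 0.0


class TestLatency:
    def test_unimodal_bump(self):
        t = grid()
        data = np.exp(-(t - 0.3) ** 2 / (2 * 0.05 ** 2))[None, :]
        lat, _ = M.single_trial_latency(data, t, 0.1, np.array([0.5]))
        assert lat[0] == pytest.approx(0.3, abs=1 / FS)

    def test_edge_peak_triggers_start_adjustment(self):
        # highest value sits at the window edge and decreases from there;
        # the true (lower) peak at 0.4 must be found after the start is
        # advanced to the first positive-going sample
        t = grid()
        data = (np.clip(1.0 - 5 * (t - 0.1), 0.0, 1.0) * (t < 0.3)
                + 0.5 * np.exp(-(t - 0.4) ** 2 / (2 * 0.04 ** 2)))[None, :]
        lat, starts = M.single_trial_latency(data, t, 0.1, np.array([0.5]))
        assert lat[0] == pytest.approx(0.4, abs=2 / FS)
        assert starts[0] > 0.1

    def test_window_bound_excludes_late_peak(self):
        t = grid()
        data = (np.exp(-(t - 0.8) ** 2 / (2 * 0.03 ** 2))
                + 0.5 * np.exp(-(t - 0.2) ** 2 / (2 * 0.03 ** 2)))[None, :]
        lat, _ = M.single_trial_latency(data, t, 0.1, np.array([0.3]))
        # peak after rt_d + 0.15 is out of bounds; the in-window bump wins
        assert lat[0] == pytest.approx(0.2, abs=2 / FS)

    def test_monotone_decreasing_flagged_nan(self):
        t = grid()
        data = (-t)[None, :]
        lat, _ = M.single_trial_latency(data, t, 0.1, np.array([0.5]))
        assert np.isnan(lat[0])


class TestBinByRt:
    def test_nine_values_three_even_bins(self):
        labels = M.bin_by_rt(np.arange(1.0, 10.0), 3)
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1, 1, 2, 2, 2])

    def test_remainder_goes_to_fastest_bins(self):
        labels = M.bin_by_rt(np.arange(10.0), 3)
        sizes = np.bincount(labels)
        np.testing.assert_array_equal(sizes, [4, 3, 3])

    def test_single_bin(self):
        assert set(M.bin_by_rt(np.arange(5.0), 1)) == {0}

    def test_labels_monotone_in_rt(self):
        rng = np.random.default_rng(0)
        rts = rng.random(20)
        labels = M.bin_by_rt(rts, 3)
        order = np.argsort(rts)
        assert np.all(np.diff(labels[order]) >= 0)

    @settings(deadline=None, max_examples=50)
    @given(n=st.integers(3, 60), k=st.integers(1, 5))
    def test_bin_sizes_never_differ_by_more_than_one(self, n, k):
        if n < k:
            return
        rng = np.random.default_rng(n * 13 + k)
        sizes = np.bincount(M.bin_by_rt(rng.random(n), k), minlength=k)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == n


class TestContrasts:
    def _bin_waveforms(self, effect=0.0, seed=0, n_subj=8, n_t=256):
        rng = np.random.default_rng(seed)
        t = grid(-0.5, -0.5 + (n_t - 1) / FS)
        base = rng.standard_normal((n_subj, 3, n_t)) * 0.3
        for b in range(3):
            base[:, b, :] += effect * (1 - b) * np.clip(t, 0, None)
        return base, t

    def test_identical_bins_flag_near_alpha(self):
        waves, t = self._bin_waveforms(effect=0.0, seed=1)
        res = M.sliding_slope_contrast(waves, t)
        assert res.significant.mean() < 0.12

    def test_graded_slopes_flagged_in_buildup(self):
        waves, t = self._bin_waveforms(effect=2.0, seed=2)
        res = M.sliding_slope_contrast(waves, t)
        post = res[res.center > 0.1]
        assert post.significant.mean() > 0.8

    def test_reversed_bin_order_flips_sign(self):
        waves, t = self._bin_waveforms(effect=2.0, seed=3)
        fwd = M.sliding_slope_contrast(waves, t)
        rev = M.sliding_slope_contrast(waves[:, ::-1, :], t)
        np.testing.assert_allclose(rev.tstat, -fwd.tstat, atol=1e-9)

    def test_offset_confined_to_span_localized_flags(self):
        rng = np.random.default_rng(4)
        t = grid(-0.5, 0.5)
        waves = rng.standard_normal((10, 3, t.size)) * 0.1
        span = (t >= 0.0) & (t <= 0.2)
        for b in range(3):
            waves[:, b, span] += b * 1.0
        res = M.samplewise_amplitude_contrast(waves, t)
        inside = res[(res.time >= 0.0) & (res.time <= 0.2)]
        outside = res[(res.time < -1 / FS) | (res.time > 0.2 + 1 / FS)]
        assert inside.significant.all()
        assert outside.significant.mean() < 0.12

    def test_constant_offset_flags_everything(self):
        rng = np.random.default_rng(5)
        t = grid(-0.5, 0.5)
        waves = rng.standard_normal((10, 3, t.size)) * 0.05
        for b in range(3):
            waves[:, b, :] += b
        res = M.samplewise_amplitude_contrast(waves, t)
        assert res.significant.all()


class TestGoExclusion:
    def test_cutoff_and_count(self):
        trials = pd.DataFrame({
            "trial_type": ["go", "go", "go", "nogo"],
            "primary_rt": [0.2, 0.35, 0.6, 0.4],
        })
        keep, n = M.go_rt_exclusion(trials)
        assert n == 2  # 0.2 and the boundary 0.35 are excluded
        assert keep.tolist() == [False, False, True, False]


class TestSamplingRateInvariance:
    def test_metrics_stable_across_rates(self):
        # band-limited bump measured at 256 vs 512 Hz
        for window, fn in ((( -0.1, 0.4), M.window_mean),
                           ((0.0, 0.2), M.window_slope)):
            vals = []
            for fs in (256.0, 512.0):
                n = int(1.5 * fs) + 1
                t = -0.5 + np.arange(n) / fs
                data = np.exp(-(t - 0.25) ** 2 / (2 * 0.1 ** 2))[None, :]
                vals.append(fn(data, t, window)[0])
            assert vals[0] == pytest.approx(vals[1], rel=0.02)
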