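"""Spectral estimation for the fronto-central theta signal.

Two complementary power estimators are provided: complex Morlet wavelet
convolution across a 1-30 Hz grid (2 to 12 cycles, increasing linearly
with frequency) and a filter-Hilbert band-power estimate (zero-phase FIR
band-pass followed by the analytic-signal envelope).  Power is expressed
in dB relative to a condition-specific, trial-averaged pre-stimulus
baseline, which preserves single-trial baseline fluctuations.  A
cluster-pruned paired-t mask identifies time-frequency regions that
deviate from baseline for a sustained extent in both time and frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats

from .cohort import EpochSet

__all__ = ["TFPower", "morlet_tf", "hilbert_band_power", "db_normalize",
           "tf_significance_mask", "lowpass", "lowpass_epochs"]

DB_FLOOR = 1e-12


@dataclass
class TFPower:
    """Time-frequency (or band) power with its normalization state."""

    power: np.ndarray          # (n_trials, n_freqs, n_times) or (n_trials, n_times)
    times: np.ndarray
    freqs: np.ndarray | None = None
    normalization: str = "raw"           # "raw" | "dB"
    baseline_window: tuple[float, float] | None = None


def default_freq_grid(n: int = 90, fmin: float = 1.0, fmax: float = 30.0
                      ) -> np.ndarray:
    return np.linspace(fmin, fmax, n)


def cycle_rule(freqs: np.ndarray, c_lo: float = 2.0, c_hi: float = 12.0
               ) -> np.ndarray:
    """Cycles per wavelet, increasing linearly from 2 to 12 across the grid."""
    freqs = np.asarray(freqs, dtype=float)
    lo, hi = freqs.min(), freqs.max()
    if hi == lo:
        return np.full_like(freqs, c_lo)
    return c_lo + (freqs - lo) * (c_hi - c_lo) / (hi - lo)


def morlet_tf(epochs: EpochSet, channel: str = "FCtheta",
              freqs: np.ndarray | None = None,
              n_cycles: np.ndarray | None = None) -> TFPower:
    """Single-trial Morlet wavelet power.

    Epochs are reflection-padded by half the longest wavelet before the
    convolution so edge samples stay usable, then cropped back.
    """
    from mne.time_frequency import tfr_array_morlet

    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    if n_cycles is None:
        n_cycles = cycle_rule(freqs)
    fs = epochs.sampling_rate
    if freqs.max() >= fs / 2:
        raise ValueError("requested frequency at or above Nyquist")
    x = epochs.channel(channel)
    n_pad = int(np.ceil(fs * float(np.max(n_cycles / freqs)) / 2)) + 1
    n_pad = min(n_pad, x.shape[1] - 1)
    xp = np.pad(x, ((0, 0), (n_pad, n_pad)), mode="reflect")
    power = tfr_array_morlet(xp[:, None, :], sfreq=fs, freqs=freqs,
                             n_cycles=n_cycles, output="power", verbose="error")
    power = power[:, 0, :, n_pad:power.shape[-1] - n_pad]
    return TFPower(power=power, times=epochs.times, freqs=freqs)


def _bandpass_kernel(fs: float, band: tuple[float, float],
                     transition: float = 0.2) -> np.ndarray:
    """Least-squares FIR band-pass, order = 3 cycles of the low cut."""
    lo, hi = band
    nyq = fs / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} must lie within (0, Nyquist)")
    numtaps = int(round(3 * fs / lo)) | 1
    bands = [0.0, lo * (1 - transition), lo, hi, min(hi * (1 + transition), nyq * 0.99), nyq]
    desired = [0, 0, 1, 1, 0, 0]
    return signal.firls(numtaps, bands, desired, fs=fs)


def _filtfilt(b: np.ndarray, x: np.ndarray) -> np.ndarray:
    n = x.shape[-1]
    padlen = min(3 * len(b), n - 1)
    if padlen < len(b):
        raise ValueError("epoch too short for the filter order")
    return signal.filtfilt(b, [1.0], x, axis=-1, padlen=padlen)


def hilbert_band_power(epochs: EpochSet, channel: str = "FCtheta",
                       band: tuple[float, float] = (2.0, 7.0)) -> TFPower:
    """Band power from a zero-phase FIR band-pass and the analytic signal."""
    b = _bandpass_kernel(epochs.sampling_rate, band)
    filt = _filtfilt(b, epochs.channel(channel))
    power = np.abs(signal.hilbert(filt, axis=-1)) ** 2
    return TFPower(power=power, times=epochs.times)


def db_normalize(tf: TFPower, baseline_window: tuple[float, float],
                 groups: np.ndarray | None = None,
                 baseline_from: TFPower | None = None) -> TFPower:
    """dB-normalize power by a condition-specific trial-averaged baseline.

    ``dB = 10 * log10(power / baseline)`` where the baseline is the
    across-trial average power inside ``baseline_window``, computed
    separately per condition label in ``groups`` (single-trial baseline
    variation is thereby preserved).  ``baseline_from`` allows the
    baseline to come from differently aligned epochs of the same trials
    (e.g. a pre-stimulus window on stimulus-aligned epochs).
    """
    src = baseline_from if baseline_from is not None else tf
    mask = (src.times >= baseline_window[0]) & (src.times <= baseline_window[1])
    if not mask.any():
        raise ValueError("baseline window lies outside the epoch")
    base_trials = src.power[..., mask].mean(axis=-1)   # (n_trials[, n_freqs])
    n = tf.power.shape[0]
    if groups is None:
        groups = np.zeros(n, dtype=int)
    groups = np.asarray(groups)
    out = np.empty_like(tf.power, dtype=float)
    for g in np.unique(groups):
        sel = groups == g
        base = base_trials[sel].mean(axis=0)
        if np.any(base <= 0):
            raise ValueError("nonpositive baseline average")
        denom = base[..., None] if np.ndim(base) else base
        out[sel] = 10.0 * np.log10(np.clip(tf.power[sel], DB_FLOOR, None) / denom)
    return TFPower(power=out, times=tf.times, freqs=tf.freqs,
                   normalization="dB", baseline_window=baseline_window)


def tf_significance_mask(subject_power: np.ndarray, times: np.ndarray,
                         freqs: np.ndarray,
                         baseline_window: tuple[float, float],
                         alpha: float = 0.01,
                         min_duration: float = 0.4,
                         min_freq_bins: int = 5) -> np.ndarray:
    """Cluster-pruned mask of time-frequency deviation from baseline.

    ``subject_power``: (n_subjects, n_freqs, n_times) per-subject average
    power.  Each pixel is compared against that subject's own baseline
    (mean over ``baseline_window`` at the same frequency) with a paired t
    test; pixels with p < alpha are kept only within contiguous clusters
    extending at least ``min_duration`` seconds and ``min_freq_bins``
    frequency bins.
    """
    p = np.asarray(subject_power, dtype=float)
    if p.ndim != 3 or p.shape[0] < 3:
        raise ValueError("need per-subject averages for >= 3 subjects")
    mask_t = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if not mask_t.any():
        raise ValueError("baseline window lies outside the epoch")
    base = p[:, :, mask_t].mean(axis=2)               # (n_subj, n_freqs)
    diff = p - base[:, :, None]
    tstat, pval = stats.ttest_1samp(diff, 0.0, axis=0)
    sig = pval < alpha
    labels, n_lab = ndimage.label(sig)
    dt = float(np.mean(np.diff(times))) if times.size > 1 else np.inf
    out = np.zeros_like(sig)
    for lab in range(1, n_lab + 1):
        fr, ti = np.nonzero(labels == lab)
        duration = (ti.max() - ti.min() + 1) * dt
        fspan = fr.max() - fr.min() + 1
        if duration >= min_duration and fspan >= min_freq_bins:
            out[labels == lab] = True
    return out


def lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Zero-phase FIR low-pass with unit DC gain, applied on the last axis."""
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    numtaps = int(round(3.3 * fs / cutoff)) | 1
    numtaps = min(numtaps, (int(np.shape(x)[-1]) - 2) | 1)
    b = signal.firwin(numtaps, cutoff, fs=fs)
    return _filtfilt(b, np.asarray(x, dtype=float))


def lowpass_epochs(epochs: EpochSet, cutoff: float,
                   channels: tuple[str, ...] | None = None) -> EpochSet:
    """Return a copy of ``epochs`` with selected channels low-pass filtered."""
    data = epochs.data.copy()
    for ch in (channels or epochs.channels):
        i = epochs.channels.index(ch)
        data[:, i, :] = lowpass(data[:, i, :], epochs.sampling_rate, cutoff)
    return EpochSet(data=data, times=epochs.times, channels=epochs.channels,
                    alignment=epochs.alignment, sampling_rate=epochs.sampling_rate,
                    trial_index=epochs.trial_index)
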