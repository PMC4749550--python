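"""Single-trial and bin-averaged decision-signal metrics.

Measurement conventions (all windows in seconds):

* FC-theta single-trial amplitude: mean band power in [-0.1, +0.4]
  relative to the erroneous action.
* CPP single-trial amplitude: mean signal in the 0.2 s preceding the
  error-detection report (report-aligned epochs).
* Build-up rate: slope of a straight line fitted to the waveform within
  [0, +0.2] for FC-theta and [+0.1, +0.3] for the CPP, relative to the
  error; the mediation analysis instead measures the CPP slope in
  [-0.3, -0.1] relative to the report to reduce temporal overlap with
  the theta measure.
* Peak latency: time of the within-window maximum between a per-signal
  start (-0.1 s theta, +0.1 s CPP) and the trial's RT_d + 0.15 s.  If
  the maximum falls on the first window sample, the start is advanced to
  the earliest subsequent time at which the waveform turns
  positive-going and the maximum is recomputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "WINDOWS", "GO_RT_CUTOFF",
    "window_mean", "window_slope", "single_trial_latency", "bin_by_rt",
    "sliding_slope_contrast", "samplewise_amplitude_contrast",
    "go_rt_exclusion", "build_single_trial_metrics",
]

#: default measurement windows (s)
WINDOWS = {
    "fctheta_amp": (-0.1, 0.4),          # re error, on band power
    "cpp_amp": (-0.2, 0.0),              # re report
    "fctheta_buildup": (0.0, 0.2),       # re error
    "cpp_buildup": (0.1, 0.3),           # re error
    "cpp_buildup_mediation": (-0.3, -0.1),  # re report
    "fctheta_latency_start": -0.1,       # re error
    "cpp_latency_start": 0.1,            # re error
    "latency_end_pad": 0.15,             # added to the trial's RT_d
}

#: Go-trial analyses exclude primary RTs at or below this (s)
GO_RT_CUTOFF = 0.35


def _win_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError(f"window {window} lies outside the epoch")
    return mask


def window_mean(data: np.ndarray, times: np.ndarray,
                window: tuple[float, float]) -> np.ndarray:
    """Per-trial mean of ``data`` (n_trials, n_times) inside ``window``."""
    return data[:, _win_mask(times, window)].mean(axis=1)


def window_slope(data: np.ndarray, times: np.ndarray,
                 window: tuple[float, float]) -> np.ndarray:
    """Per-trial least-squares slope (units/s) inside ``window``."""
    mask = _win_mask(times, window)
    t = times[mask]
    x = data[:, mask]
    tc = t - t.mean()
    denom = np.sum(tc ** 2)
    if denom == 0:
        raise ValueError("slope window contains a single sample")
    return (x - x.mean(axis=1, keepdims=True)) @ tc / denom


def single_trial_latency(data: np.ndarray, times: np.ndarray,
                         start: float, rt_d: np.ndarray,
                         end_pad: float = WINDOWS["latency_end_pad"]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial peak latency within [start, rt_d + end_pad].

    Returns (latencies, window_starts); latency is NaN (and logged) when
    the waveform decreases monotonically throughout the window.  The
    per-trial window actually used is needed downstream by the latency
    permutation test.
    """
    n = data.shape[0]
    lat = np.full(n, np.nan)
    starts = np.full(n, start)
    n_flagged = 0
    for i in range(n):
        end = rt_d[i] + end_pad
        mask = (times >= start) & (times <= end)
        if not mask.any():
            n_flagged += 1
            continue
        idx = np.flatnonzero(mask)
        seg = data[i, idx]
        k = int(np.argmax(seg))
        if k == 0:
            # peak pinned to the window edge: advance the start to where
            # the waveform next turns positive-going
            d = np.diff(seg)
            rising = np.flatnonzero(d > 0)
            if rising.size == 0:
                n_flagged += 1
                continue
            j = rising[0] + 1
            starts[i] = times[idx[j]]
            k = j + int(np.argmax(seg[j:]))
        lat[i] = times[idx[k]]
    if n_flagged:
        logger.info("single_trial_latency: %d trials without a defined peak",
                    n_flagged)
    return lat, starts


def bin_by_rt(rts: np.ndarray, k: int = 3) -> np.ndarray:
    """Equal-sized RT bins (0 = fastest); remainder trials go to the
    fastest bins so bin sizes never differ by more than one."""
    rts = np.asarray(rts, dtype=float)
    n = rts.size
    if n < k:
        raise ValueError(f"need at least {k} trials for {k} bins")
    order = np.argsort(rts, kind="stable")   # ties broken by trial order
    base, rem = divmod(n, k)
    sizes = [base + (1 if b < rem else 0) for b in range(k)]
    labels = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes):
        labels[order[start:start + size]] = b
        start += size
    return labels


def _ols_slopes(waves: np.ndarray, t: np.ndarray) -> np.ndarray:
    tc = t - t.mean()
    return waves @ tc / np.sum(tc ** 2)


def _contrast_weights(k: int) -> np.ndarray:
    w = np.arange(k, dtype=float)
    return w - w.mean()


def sliding_slope_contrast(bin_waveforms: np.ndarray, times: np.ndarray,
                           window: float = 0.150, alpha: float = 0.05
                           ) -> pd.DataFrame:
    """Linear RT-bin contrast on sliding-window build-up rates.

    ``bin_waveforms``: (n_subjects, n_bins, n_times) bin-averaged
    waveforms with bin 0 the fastest.  For every 150 ms window the slope
    is measured per subject and bin, a linear contrast across bins is
    formed, and a one-tailed group t test flags windows where the slope
    decreases with RT (steeper build-up on faster trials).
    """
    n_subj, n_bins, n_t = bin_waveforms.shape
    if n_subj < 3:
        raise ValueError("need >= 3 subjects")
    dt = float(np.mean(np.diff(times)))
    half = int(round(window / dt / 2))
    rows = []
    w = _contrast_weights(n_bins)
    for c in range(half, n_t - half):
        sl = slice(c - half, c + half + 1)
        slopes = _ols_slopes(bin_waveforms[:, :, sl], times[sl])  # (subj, bins)
        contrast = slopes @ w
        t, p_two = stats.ttest_1samp(contrast, 0.0)
        p = p_two / 2 if t < 0 else 1 - p_two / 2   # one-tailed: negative
        rows.append((times[c], float(t), float(p), p < alpha))
    return pd.DataFrame(rows, columns=["center", "tstat", "p", "significant"])


def samplewise_amplitude_contrast(bin_waveforms: np.ndarray, times: np.ndarray,
                                  alpha: float = 0.05) -> pd.DataFrame:
    """Two-tailed linear RT-bin contrast on amplitude, per temporal sample."""
    n_subj, n_bins, n_t = bin_waveforms.shape
    if n_subj < 3:
        raise ValueError("need >= 3 subjects")
    w = _contrast_weights(n_bins)
    contrast = np.tensordot(bin_waveforms, w, axes=([1], [0]))  # (subj, time)
    t, p = stats.ttest_1samp(contrast, 0.0, axis=0)
    return pd.DataFrame({"time": times, "tstat": t, "p": p,
                         "significant": p < alpha})


def go_rt_exclusion(trials: pd.DataFrame, cutoff: float = GO_RT_CUTOFF
                    ) -> tuple[pd.Series, int]:
    """Mask of Go trials admissible for first-order analyses (RT > cutoff)."""
    is_go = trials["trial_type"] == "go"
    keep = is_go & (trials["primary_rt"] > cutoff)
    n_excluded = int((is_go & ~keep).sum())
    logger.info("go_rt_exclusion: removed %d Go trials with RT <= %g s",
                n_excluded, cutoff)
    return keep, n_excluded


def build_single_trial_metrics(trials: pd.DataFrame,
                               theta_power_resp, cpp_resp, cpp_report,
                               windows: dict | None = None) -> pd.DataFrame:
    """Assemble the per-trial metric table for detected errors.

    Parameters
    ----------
    trials : behavioral table (see ``cohort.generate_behavior``)
    theta_power_resp : TFPower
        Response(error)-aligned FC-theta band power of detected errors.
    cpp_resp, cpp_report : EpochSet
        Response- and report-aligned CPP epochs of detected errors
        (already low-pass filtered for single-trial analysis).

    Returns one row per detected error with amplitude, build-up rate,
    latency (and latency windows) for both signals plus the
    report-aligned CPP slope used by the mediation analysis.
    """
    W = dict(WINDOWS)
    if windows:
        W.update(windows)
    idx = cpp_resp.trial_index
    sub = trials.loc[idx]
    rt_d = sub["rt_d"].to_numpy()

    theta = theta_power_resp.power
    t_tp = theta_power_resp.times
    fc_amp = window_mean(theta, t_tp, W["fctheta_amp"])
    fc_build = window_slope(theta, t_tp, W["fctheta_buildup"])
    fc_lat, fc_ws = single_trial_latency(theta, t_tp,
                                         W["fctheta_latency_start"], rt_d,
                                         W["latency_end_pad"])

    cpp_r = cpp_resp.channel("CPP")
    cpp_build = window_slope(cpp_r, cpp_resp.times, W["cpp_buildup"])
    cpp_lat, cpp_ws = single_trial_latency(cpp_r, cpp_resp.times,
                                           W["cpp_latency_start"], rt_d,
                                           W["latency_end_pad"])

    # report-aligned measures; row order may differ, so align by index
    rep_pos = {label: i for i, label in enumerate(cpp_report.trial_index)}
    order = np.array([rep_pos[label] for label in idx])
    cpp_rep = cpp_report.channel("CPP")[order]
    cpp_amp = window_mean(cpp_rep, cpp_report.times, W["cpp_amp"])
    cpp_build_med = window_slope(cpp_rep, cpp_report.times,
                                 W["cpp_buildup_mediation"])

    return pd.DataFrame({
        "trial_label": idx,
        "subject": sub["subject"].to_numpy(),
        "rt_d": rt_d,
        "fctheta_amp": fc_amp,
        "cpp_amp": cpp_amp,
        "fctheta_buildup": fc_build,
        "cpp_buildup": cpp_build,
        "cpp_buildup_mediation": cpp_build_med,
        "fctheta_latency": fc_lat,
        "cpp_latency": cpp_lat,
        "fctheta_lat_win_start": fc_ws,
        "cpp_lat_win_start": cpp_ws,
        "lat_win_end": rt_d + W["latency_end_pad"],
    })
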