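"""Synthetic Go/No-Go cohort generator.

Emulates the behavioral and electrophysiological structure that the
downstream analyses assume: blocked Go/No-Go trial streams with a minimum
spacing between No-Go stimuli, commission errors whose detection and
detection RT are produced by the one-choice diffusion model under a
per-subject deadline, a centro-parietal (CPP) ramp-to-threshold signal
whose build-up rate reflects the trial's post-decision drift, and a
fronto-central theta burst whose single-trial power modulates that drift
(theta -> CPP slope -> RT_d, the mediation structure).

Primary RTs follow per-condition log-normal laws tied together by a
latent "salience" variable: salient No-Go lapses are caught quickly
(fast primary RT) *and* generate strong error evidence (high drift), so
detected errors come out faster than correct Go responses while
undetected errors come out slower, without inducing an appreciable
correlation between primary RT and RT_d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm import SubjectParams, first_passage_times

logger = logging.getLogger(__name__)

__all__ = ["CohortConfig", "EpochSet", "generate_behavior", "render_epochs",
           "draw_subject_params", "nogo_positions", "pink_noise"]

CHANNELS = ("CPP", "FCtheta")
ALIGNMENTS = ("stimulus", "response", "report")

#: motor allotment before the report; the CPP reaches the bound at
#: rt_d - 0.09 s and then decays linearly over 0.3 s
MOTOR_TIME = 0.090
DECAY_TIME = 0.300


@dataclass
class CohortConfig:
    """Generative settings for a synthetic cohort.

    Behavioral defaults follow the study conditions the analyses target:
    224-trial blocks containing 200 Go and 24 No-Go stimuli with at least
    three Go trials between No-Go stimuli, a withhold rate of 56.6%, and
    detection behavior generated by the one-choice diffusion model at the
    group-mean fitted parameters (a=0.21, t_nd=0.20, v=0.45, eta=0.45,
    deadline 1.17 s) with their between-subject spreads.
    """

    n_subjects: int = 28
    n_blocks: int = 10
    trials_per_block: int = 224
    n_go_per_block: int = 200
    min_go_gap: int = 3
    p_withhold: float = 0.566
    p_withhold_sd: float = 0.13

    # primary-RT model (log-normal; spreads are log-scale s.d.)
    go_rt_median: float = 0.511
    go_rt_spread: float = 0.18
    error_rt_shift: float = 0.025        # Go median minus error base median (s)
    error_rt_spread: float = 0.15
    salience_rt_coupling: float = 0.16   # log-RT decrease per salience unit
    drift_salience_corr: float = 0.6

    # diffusion-model population (group mean, between-subject s.d.)
    ddm_mean: tuple[float, float, float, float] = (0.21, 0.20, 0.45, 0.45)  # a, t_nd, v, eta
    ddm_sd: tuple[float, float, float, float] = (0.12, 0.08, 0.30, 0.30)
    deadline_mean: float = 1.17
    deadline_sd: float = 0.19
    deadline_range: tuple[float, float] = (0.81, 1.47)
    dt: float = 1e-3

    # signal model
    sampling_rate: float = 256.0
    epoch_pre: float = 0.8
    epoch_post: float = 1.6
    theta_freq: float = 5.5
    theta_coupling: float = 0.3          # gamma: drift units per unit theta power
    theta_log_sd: float = 0.4
    theta_amp: float = 1.0
    theta_burst_center: float = 0.15     # s after the response
    theta_burst_width: float = 0.12      # Gaussian envelope s.d. (s)
    go_theta_atten: float = 0.5
    noise_sd: float = 0.05
    first_order_onset: float = 0.11      # CPP onset after stimulus on Go trials (s)

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_withhold <= 1.0:
            raise ValueError("p_withhold must lie in [0, 1]")
        for name in ("n_subjects", "n_blocks", "trials_per_block", "n_go_per_block"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.n_go_per_block >= self.trials_per_block:
            raise ValueError("n_go_per_block must be smaller than trials_per_block")
        n_nogo = self.trials_per_block - self.n_go_per_block
        needed = n_nogo + (n_nogo - 1) * self.min_go_gap
        if needed > self.trials_per_block:
            raise ValueError(
                f"block composition infeasible: {n_nogo} No-Go trials with "
                f">= {self.min_go_gap} Go trials between them need {needed} "
                f"slots but the block has {self.trials_per_block}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_nogo_per_block(self) -> int:
        return self.trials_per_block - self.n_go_per_block


@dataclass
class EpochSet:
    """Per-trial virtual-channel time series with a common alignment.

    ``data`` has shape (n_trials, n_channels, n_times); ``trial_index``
    maps rows one-to-one onto index labels of the originating trial
    table.
    """

    data: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    alignment: str
    sampling_rate: float
    trial_index: np.ndarray

    def __post_init__(self) -> None:
        dt = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(dt, 1.0 / self.sampling_rate):
            raise ValueError("times must be uniformly spaced at 1/sampling_rate")
        if len(self.trial_index) != self.data.shape[0]:
            raise ValueError("trial_index length must match the trial axis")
        if len(set(self.trial_index.tolist())) != len(self.trial_index):
            raise ValueError("trial_index must map trials one-to-one")

    def channel(self, name: str) -> np.ndarray:
        """(n_trials, n_times) view of one virtual channel."""
        return self.data[:, self.channels.index(name), :]

    def __len__(self) -> int:
        return self.data.shape[0]


def nogo_positions(rng: np.random.Generator, n_trials: int, n_nogo: int,
                   min_gap: int = 3) -> np.ndarray:
    """Random No-Go positions with >= min_gap Go trials between them."""
    needed = n_nogo + (n_nogo - 1) * min_gap
    if needed > n_trials:
        raise ValueError("spacing rule unsatisfiable for this composition")
    free = n_trials - needed
    extra = rng.multinomial(free, np.full(n_nogo + 1, 1.0 / (n_nogo + 1)))
    pos = np.empty(n_nogo, dtype=int)
    cursor = extra[0]
    for i in range(n_nogo):
        pos[i] = cursor
        cursor += 1 + min_gap + extra[i + 1]
    return pos


def draw_subject_params(config: CohortConfig, rng: np.random.Generator
                        ) -> SubjectParams:
    """Draw one subject's diffusion parameters from the population."""
    (ma, mt, mv, me) = config.ddm_mean
    (sa, st, sv, se) = config.ddm_sd
    a = float(np.clip(rng.normal(ma, sa), 0.05, 1.0))
    t_nd = float(np.clip(rng.normal(mt, st), 0.10, 0.40))
    v = float(np.clip(rng.normal(mv, sv), -0.5, 1.5))
    eta = float(np.clip(rng.normal(me, se), 0.05, 1.0))
    deadline = float(np.clip(rng.normal(config.deadline_mean, config.deadline_sd),
                             *config.deadline_range))
    return SubjectParams(a=a, v=v, eta=eta, t_nd=t_nd, deadline=deadline)


def _subject_rng(config: CohortConfig, subject: int, stream: int = 0
                 ) -> np.random.Generator:
    # per-subject substream derived deterministically from the global seed
    return np.random.default_rng([config.seed, subject, stream])


def generate_behavior(config: CohortConfig) -> pd.DataFrame:
    """Generate the per-trial behavioral table for a synthetic cohort.

    Columns: subject, block, trial (position within block), trial_type
    ('go'/'nogo'), primary_rt (NaN on correct withholds), is_error,
    detected, rt_d (NaN unless detected), theta_scale, drift_u (NaN on
    non-error trials), plus the subject-level generative parameters
    (subj_a, subj_v, subj_eta, subj_tnd, subj_deadline, subj_p_withhold).
    """
    rows: list[dict] = []
    rho = config.drift_salience_corr
    err_median = config.go_rt_median - config.error_rt_shift
    for subj in range(config.n_subjects):
        rng = _subject_rng(config, subj)
        params = draw_subject_params(config, rng)
        p_wh = float(np.clip(rng.normal(config.p_withhold, config.p_withhold_sd),
                             0.05, 0.95))
        subj_cols = dict(
            subject=subj, subj_a=params.a, subj_v=params.v, subj_eta=params.eta,
            subj_tnd=params.t_nd, subj_deadline=params.deadline,
            subj_p_withhold=p_wh,
        )
        error_rows: list[dict] = []
        error_u: list[float] = []
        for block in range(config.n_blocks):
            nogo = set(nogo_positions(rng, config.trials_per_block,
                                      config.n_nogo_per_block, config.min_go_gap))
            for trial in range(config.trials_per_block):
                row = dict(subj_cols, block=block, trial=trial)
                theta = float(np.exp(rng.normal(0.0, config.theta_log_sd)
                                     - config.theta_log_sd ** 2 / 2))
                if trial not in nogo:
                    rt = float(np.exp(np.log(config.go_rt_median)
                                      + config.go_rt_spread * rng.standard_normal()))
                    row.update(trial_type="go", primary_rt=rt, is_error=False,
                               detected=False, rt_d=np.nan,
                               theta_scale=theta * config.go_theta_atten,
                               drift_u=np.nan)
                    rows.append(row)
                    continue
                if rng.random() < p_wh:
                    row.update(trial_type="nogo", primary_rt=np.nan,
                               is_error=False, detected=False, rt_d=np.nan,
                               theta_scale=np.nan, drift_u=np.nan)
                    rows.append(row)
                    continue
                # commission error: latent salience couples primary RT and drift
                z_s = rng.standard_normal()
                z_o = rng.standard_normal()
                u = (params.v
                     + params.eta * (rho * z_s + np.sqrt(1 - rho ** 2) * z_o)
                     + config.theta_coupling * (theta - 1.0))
                rt = float(np.exp(np.log(err_median)
                                  - config.salience_rt_coupling * z_s
                                  + config.error_rt_spread * rng.standard_normal()))
                row.update(trial_type="nogo", primary_rt=rt, is_error=True,
                           theta_scale=theta, drift_u=float(u))
                error_rows.append(row)
                error_u.append(u)
        if error_rows:
            horizon = params.deadline - params.t_nd
            T = first_passage_times(np.asarray(error_u), params.a, params.s,
                                    config.dt, horizon, rng)
            rt_d = T + params.t_nd
            det = np.isfinite(T) & (rt_d <= params.deadline)
            for row, d, r in zip(error_rows, det, rt_d):
                row.update(detected=bool(d), rt_d=float(r) if d else np.nan)
        rows.extend(error_rows)
    df = pd.DataFrame(rows)
    col_order = ["subject", "block", "trial", "trial_type", "primary_rt",
                 "is_error", "detected", "rt_d", "theta_scale", "drift_u",
                 "subj_a", "subj_v", "subj_eta", "subj_tnd", "subj_deadline",
                 "subj_p_withhold"]
    df = df[col_order].sort_values(["subject", "block", "trial"], kind="stable")
    return df.reset_index(drop=True)


def pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    spec *= scale
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _second_order_cpp(t_err: np.ndarray, row, cap: float = 0.95) -> np.ndarray:
    """Clean second-order CPP as a function of time relative to the error."""
    a, t_nd = row.subj_a, row.subj_tnd
    onset = max(t_nd - MOTOR_TIME, 0.0)
    x = np.zeros_like(t_err)
    if row.detected:
        t_cross = row.rt_d - MOTOR_TIME
        slope = a / max(t_cross - onset, 1e-6)
        ramp = (t_err >= onset) & (t_err < t_cross)
        x[ramp] = slope * (t_err[ramp] - onset)
        decay = (t_err >= t_cross) & (t_err < t_cross + DECAY_TIME)
        x[decay] = a * (1.0 - (t_err[decay] - t_cross) / DECAY_TIME)
    else:
        # accumulation at the trial's drift until the deadline, capped below
        # the bound (the trial did not cross), then held
        stop = row.subj_deadline - MOTOR_TIME
        u = row.drift_u
        grow = (t_err >= onset) & (t_err < stop)
        x[grow] = u * (t_err[grow] - onset)
        x[t_err >= stop] = u * (stop - onset)
        np.clip(x, -a, cap * a, out=x)
    return x


def _first_order_cpp(t_stim: np.ndarray, row, onset: float = 0.11) -> np.ndarray:
    """Clean first-order CPP for a Go trial, time relative to stimulus."""
    a = row.subj_a
    t_cross = row.primary_rt - MOTOR_TIME
    x = np.zeros_like(t_stim)
    slope = a / max(t_cross - onset, 1e-2)
    ramp = (t_stim >= onset) & (t_stim < t_cross)
    x[ramp] = slope * (t_stim[ramp] - onset)
    decay = (t_stim >= t_cross) & (t_stim < t_cross + DECAY_TIME)
    x[decay] = a * (1.0 - (t_stim[decay] - t_cross) / DECAY_TIME)
    return x


def _theta_burst(t_resp: np.ndarray, row, config: CohortConfig) -> np.ndarray:
    env = np.exp(-((t_resp - config.theta_burst_center) ** 2)
                 / (2 * config.theta_burst_width ** 2))
    carrier = np.sin(2 * np.pi * config.theta_freq * t_resp)
    return config.theta_amp * np.sqrt(row.theta_scale) * env * carrier


def render_epochs(trials: pd.DataFrame, config: CohortConfig,
                  alignment: str = "response") -> EpochSet:
    """Render single-trial CPP and FC-theta epochs for one alignment.

    Trials lacking the alignment event (e.g. the report on an undetected
    error, or any response on a correct withhold) are excluded and
    logged.  With ``noise_sd = 0`` the traces are the clean generative
    signals, so construction guarantees such as the CPP reaching the
    bound exactly 90 ms before the report hold sample-for-sample.
    """
    if alignment not in ALIGNMENTS:
        raise ValueError(f"alignment must be one of {ALIGNMENTS}")
    fs = config.sampling_rate
    n_pre = int(round(config.epoch_pre * fs))
    n_post = int(round(config.epoch_post * fs))
    times = (np.arange(n_pre + n_post + 1) - n_pre) / fs

    if alignment == "stimulus":
        ok = pd.Series(True, index=trials.index)
    elif alignment == "response":
        ok = trials["primary_rt"].notna()
    else:
        ok = trials["detected"].astype(bool) & trials["rt_d"].notna()
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("render_epochs(%s): excluded %d trials without the "
                    "alignment event", alignment, n_excluded)
    kept = trials.loc[ok]

    data = np.zeros((len(kept), len(CHANNELS), times.size))
    align_code = ALIGNMENTS.index(alignment)
    for k, (idx, row) in enumerate(kept.iterrows()):
        if alignment == "stimulus":
            t_stim = times
        elif alignment == "response":
            t_stim = times + row.primary_rt
        else:
            t_stim = times + row.primary_rt + row.rt_d
        t_resp = t_stim - row.primary_rt if np.isfinite(row.primary_rt) else None

        if row.is_error:
            cpp = _second_order_cpp(t_resp, row)
        elif row.trial_type == "go":
            cpp = _first_order_cpp(t_stim, row, config.first_order_onset)
        else:
            cpp = np.zeros_like(times)
        if t_resp is not None and np.isfinite(row.theta_scale):
            theta = _theta_burst(t_resp, row, config)
        else:
            theta = np.zeros_like(times)

        if config.noise_sd > 0:
            rng = np.random.default_rng(
                [config.seed, 7, int(row.subject), int(idx), align_code])
            cpp = cpp + config.noise_sd * pink_noise(rng, times.size)
            theta = theta + config.noise_sd * pink_noise(rng, times.size)
        data[k, 0] = cpp
        data[k, 1] = theta

    return EpochSet(data=data, times=times, channels=CHANNELS,
                    alignment=alignment, sampling_rate=fs,
                    trial_index=np.asarray(kept.index))


def behavioral_summary(trials: pd.DataFrame) -> dict:
    """Cohort-level behavioral summaries used as generator calibration checks."""
    nogo = trials[trials.trial_type == "nogo"]
    errors = trials[trials.is_error]
    detected = errors[errors.detected]
    undetected = errors[~errors.detected.astype(bool)]
    go = trials[trials.trial_type == "go"]
    out = {
        "withhold_rate": float(1.0 - nogo.is_error.mean()) if len(nogo) else np.nan,
        "detection_rate": float(errors.detected.mean()) if len(errors) else np.nan,
        "median_go_rt": float(go.primary_rt.median()),
        "median_detected_rt": float(detected.primary_rt.median()) if len(detected) else np.nan,
        "median_undetected_rt": float(undetected.primary_rt.median()) if len(undetected) else np.nan,
        "median_rt_d": float(detected.rt_d.median()) if len(detected) else np.nan,
        "n_errors": int(len(errors)),
        "n_detected": int(len(detected)),
    }
    return out
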