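"""Within-subject robust regressions of detection RT on signal metrics.

Each subject's detected-error trials are fit with a two-predictor robust
regression (bisquare M-estimation via iteratively reweighted least
squares), e.g. ``log(RT_d) = b0 + b1*FCtheta_amp + b2*CPP_amp``; the two
coefficients are estimated simultaneously in one joint fit.  Per-subject
effect sizes ``t = beta / s.e.`` feed group-level one-sample and paired
t tests.  RT_d is log-transformed; peak latencies are square-root
transformed after shifting by the measurement-window start so the
argument stays nonnegative.  The dynamic latency window (bounded by each
trial's RT_d) builds in a spurious positive latency-RT coupling, so
latency effects are tested against a permutation null in which each
trial's latency is replaced by a uniform draw from its own window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["robust_fit", "vif", "within_subject_model", "group_level_tests",
           "latency_permutation_test", "MODEL_PREDICTORS"]

MODEL_PREDICTORS = {
    "amplitude": ("fctheta_amp", "cpp_amp"),
    "buildup": ("fctheta_buildup", "cpp_buildup"),
    "latency": ("fctheta_latency", "cpp_latency"),
}

#: shift added before the square-root transform of latencies, by
#: predictor, equal to minus the measurement-window start
LATENCY_SHIFT = {"fctheta_latency": 0.1, "cpp_latency": 0.0}


def robust_fit(X: np.ndarray, y: np.ndarray, add_intercept: bool = True,
               maxiter: int = 200) -> tuple[np.ndarray, np.ndarray, bool]:
    """Bisquare M-estimation (tuning 4.685) by IRLS.

    Returns (betas, standard errors, converged).  The intercept, when
    added, is the first coefficient.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 5:
        raise ValueError(f"too few observations ({n}) for {p} predictors")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant predictor column")
    design = sm.add_constant(X) if add_intercept else X
    model = sm.RLM(y, design, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = model.fit(maxiter=maxiter)
    converged = len(res.fit_history.get("deviance", [])) < maxiter
    return res.params, res.bse, converged


def vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor 1/(1 - R^2_j) per predictor column."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1 or X.shape[1] == 1:
        return np.array([1.0])
    p = X.shape[1]
    out = np.empty(p)
    for j in range(p):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _transform(metrics: pd.DataFrame, model: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    preds = MODEL_PREDICTORS[model]
    y = np.log(metrics["rt_d"].to_numpy())
    cols = []
    labels = []
    for p in preds:
        x = metrics[p].to_numpy(dtype=float)
        if model == "latency":
            x = np.sqrt(np.maximum(x + LATENCY_SHIFT[p], 0.0))
            labels.append(f"sqrt_{p}")
        else:
            labels.append(p)
        cols.append(x)
    return np.column_stack(cols), y, labels


def within_subject_model(metrics: pd.DataFrame, model: str,
                         min_trials: int = 20) -> pd.DataFrame:
    """Per-subject robust fit of log(RT_d) on a pair of signal metrics.

    ``model`` selects the predictor pair: 'amplitude', 'buildup' or
    'latency'.  Subjects with fewer than ``min_trials`` usable trials
    are excluded.  Returns the effect table (one row per subject and
    predictor) with betas, standard errors, effect sizes and the VIF of
    each predictor.
    """
    if model not in MODEL_PREDICTORS:
        raise ValueError(f"unknown model {model!r}")
    rows = []
    for subj, grp in metrics.groupby("subject"):
        grp = grp.dropna(subset=["rt_d", *MODEL_PREDICTORS[model]])
        if len(grp) < min_trials:
            continue
        X, y, labels = _transform(grp, model)
        betas, ses, converged = robust_fit(X, y)
        vifs = vif(X)
        for j, lab in enumerate(labels):
            rows.append(dict(subject=subj, model=model, predictor=lab,
                             beta=float(betas[j + 1]), se=float(ses[j + 1]),
                             effect_size=float(betas[j + 1] / ses[j + 1]),
                             vif=float(vifs[j]), n_trials=len(grp),
                             converged=converged))
    if not rows:
        raise ValueError("no subject met the minimum trial count")
    return pd.DataFrame(rows)


def group_level_tests(effects: pd.DataFrame) -> dict:
    """One-sample t per predictor and a paired t between the two predictors.

    Operates on the per-subject effect sizes (beta/se).  Degenerate
    inputs (zero variance across subjects) are flagged rather than
    returning a spurious p value.
    """
    out: dict = {"one_sample": {}, "paired": None}
    preds = list(effects["predictor"].unique())
    wide = effects.pivot(index="subject", columns="predictor",
                         values="effect_size")
    if len(wide) < 3:
        raise ValueError("need >= 3 subjects for group-level tests")
    for p in preds:
        x = wide[p].dropna().to_numpy()
        if np.allclose(x.std(ddof=1), 0.0):
            out["one_sample"][p] = dict(mean=float(x.mean()), t=np.nan,
                                        p=np.nan, degenerate=True)
            continue
        t, pv = stats.ttest_1samp(x, 0.0)
        out["one_sample"][p] = dict(mean=float(x.mean()), t=float(t),
                                    p=float(pv), degenerate=False)
    if len(preds) == 2:
        pair = wide[preds].dropna()
        d = pair[preds[0]] - pair[preds[1]]
        if np.allclose(d.std(ddof=1), 0.0):
            out["paired"] = dict(t=np.nan, p=np.nan, degenerate=True)
        else:
            t, pv = stats.ttest_rel(pair[preds[0]], pair[preds[1]])
            out["paired"] = dict(t=float(t), p=float(pv), degenerate=False)
    return out


def latency_permutation_test(metrics: pd.DataFrame, n: int = 1000,
                             seed: int = 0, min_trials: int = 20) -> dict:
    """Permutation test of the latency regression against window artifacts.

    For each iteration, every trial's FC-theta and CPP peak latencies are
    replaced by uniform draws from that trial's own measurement window
    and the full within-subject regression (sqrt transform, robust fit,
    effect sizes, group mean) is recomputed.  The observed group-mean
    effect size per predictor is compared against this null.

    Returns observed effects, the null distributions of the group means
    and two-sided percentile p values.
    """
    observed = within_subject_model(metrics, "latency", min_trials)
    obs_mean = observed.groupby("predictor")["effect_size"].mean()

    rng = np.random.default_rng(seed)
    work = metrics.copy()
    keep = work["lat_win_end"] > np.maximum(work["fctheta_lat_win_start"],
                                            work["cpp_lat_win_start"])
    work = work[keep]
    null = {p: np.empty(n) for p in obs_mean.index}
    for it in range(n):
        for col, start_col in (("fctheta_latency", "fctheta_lat_win_start"),
                               ("cpp_latency", "cpp_lat_win_start")):
            lo = work[start_col].to_numpy()
            hi = work["lat_win_end"].to_numpy()
            work[col] = lo + (hi - lo) * rng.random(len(work))
        eff = within_subject_model(work, "latency", min_trials)
        m = eff.groupby("predictor")["effect_size"].mean()
        for p in null:
            null[p][it] = m.get(p, np.nan)
    result = {"observed": obs_mean.to_dict(), "null": null, "p": {}}
    for p, dist in null.items():
        d = dist[np.isfinite(dist)]
        lo_p = (1 + np.sum(d <= obs_mean[p])) / (1 + d.size)
        hi_p = (1 + np.sum(d >= obs_mean[p])) / (1 + d.size)
        result["p"][p] = float(min(1.0, 2 * min(lo_p, hi_p)))
    return result
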