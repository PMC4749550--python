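"""Three-variable mediation: theta power -> CPP build-up rate -> RT_d.

Single-trial values are z-scored within subject, pooled across subjects,
sorted by the outcome (RT_d) and averaged in consecutive bins of 12
trials to suppress single-trial measurement noise before ordinary
least-squares path fitting:

* path a : M ~ X           (mediator on predictor)
* path b, c' : Y ~ X + M   (outcome on both; c' is the direct effect)
* path c : Y ~ X           (total effect)
* mediation effect ab = a * b, with c = c' + ab holding exactly.

Inference uses a bias-corrected (BC, no acceleration) bootstrap over
bins: the percentile interval is shifted by the normal quantile of the
fraction of bootstrap replicates below the point estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["MediationResult", "prepare_bins", "fit_paths",
           "bootstrap_mediation", "mediation_analysis"]


@dataclass
class MediationResult:
    path_a: float
    path_b: float
    path_c: float
    path_c_prime: float
    ab: float
    ci: dict = field(default_factory=dict)        # name -> (lo, hi)
    p_values: dict = field(default_factory=dict)  # name -> p
    bin_size: int = 0
    n_bins: int = 0
    n_boot: int = 0
    n_redrawn: int = 0

    def to_dict(self) -> dict:
        return dict(path_a=self.path_a, path_b=self.path_b, path_c=self.path_c,
                    path_c_prime=self.path_c_prime, ab=self.ab,
                    ci={k: list(v) for k, v in self.ci.items()},
                    p_values=self.p_values, bin_size=self.bin_size,
                    n_bins=self.n_bins, n_boot=self.n_boot,
                    n_redrawn=self.n_redrawn)


def _zscore_within(values: np.ndarray, subjects: np.ndarray) -> np.ndarray:
    out = np.empty_like(values, dtype=float)
    for s in np.unique(subjects):
        sel = subjects == s
        x = values[sel]
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        out[sel] = (x - x.mean()) / sd if sd > 0 else 0.0
    return out


def prepare_bins(X: np.ndarray, M: np.ndarray, Y: np.ndarray,
                 subjects: np.ndarray, bin_size: int = 12
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Within-subject z-scoring, pooling, RT-sorted binning.

    Trials are sorted by increasing Y (RT_d) and averaged in consecutive
    bins of ``bin_size``; a trailing remainder smaller than the bin size
    is dropped.  ``bin_size=1`` reduces to the identity (after sorting).
    """
    X, M, Y = (np.asarray(v, dtype=float) for v in (X, M, Y))
    subjects = np.asarray(subjects)
    n = Y.size
    if n < 2 * bin_size:
        raise ValueError("need at least two full bins of trials")
    if len(np.unique(subjects)) == 1:
        logger.warning("prepare_bins: all trials come from a single subject; "
                       "pooling is degenerate")
    Xz = _zscore_within(X, subjects)
    Mz = _zscore_within(M, subjects)
    Yz = _zscore_within(Y, subjects)
    order = np.argsort(Yz, kind="stable")
    n_bins = n // bin_size
    keep = order[: n_bins * bin_size]
    shape = (n_bins, bin_size)
    return (Xz[keep].reshape(shape).mean(axis=1),
            Mz[keep].reshape(shape).mean(axis=1),
            Yz[keep].reshape(shape).mean(axis=1))


def _ols(y: np.ndarray, *cols: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones_like(y), *cols])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise ValueError("rank-deficient path regression")
    return coef


def fit_paths(X: np.ndarray, M: np.ndarray, Y: np.ndarray,
              bin_size: int = 0) -> MediationResult:
    """OLS path coefficients on binned triples (point estimates only)."""
    X, M, Y = (np.asarray(v, dtype=float) for v in (X, M, Y))
    if X.size < 10:
        raise ValueError("need >= 10 bins to fit the path model")
    a = _ols(M, X)[1]
    cb = _ols(Y, X, M)
    c_prime, b = cb[1], cb[2]
    c = _ols(Y, X)[1]
    return MediationResult(path_a=float(a), path_b=float(b), path_c=float(c),
                           path_c_prime=float(c_prime), ab=float(a * b),
                           bin_size=bin_size, n_bins=int(X.size))


def _bc_interval(boot: np.ndarray, point: float, alpha: float = 0.05
                 ) -> tuple[float, float, float]:
    """Bias-corrected bootstrap CI and two-sided p value."""
    boot = boot[np.isfinite(boot)]
    nb = boot.size
    frac = np.clip(np.mean(boot < point), 1.0 / (nb + 1), nb / (nb + 1.0))
    z0 = stats.norm.ppf(frac)
    zc = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    qs = stats.norm.cdf(2 * z0 + zc)
    lo, hi = np.quantile(boot, qs)
    # p: the level at which the BC bound touches zero
    q_at_zero = np.clip(np.mean(boot < 0.0), 1.0 / (nb + 1), nb / (nb + 1.0))
    z = stats.norm.ppf(q_at_zero) - 2 * z0
    p = float(2 * stats.norm.sf(abs(z)))
    return float(lo), float(hi), p


def bootstrap_mediation(X: np.ndarray, M: np.ndarray, Y: np.ndarray,
                        n: int = 10_000, seed: int = 0,
                        bin_size: int = 0, alpha: float = 0.05
                        ) -> MediationResult:
    """BC-bootstrap inference for the path model over binned triples.

    Bins are resampled with replacement; resamples in which X or M is
    constant (rank-deficient) are redrawn and counted.
    """
    point = fit_paths(X, M, Y, bin_size=bin_size)
    rng = np.random.default_rng(seed)
    nb = X.size
    names = ("path_a", "path_b", "path_c", "path_c_prime", "ab")
    boot = {k: np.empty(n) for k in names}
    n_redrawn = 0
    for it in range(n):
        for _attempt in range(100):
            idx = rng.integers(0, nb, nb)
            if X[idx].std() > 0 and M[idx].std() > 0:
                break
            n_redrawn += 1
        else:
            raise ValueError("could not draw a non-degenerate resample")
        r = fit_paths(X[idx], M[idx], Y[idx], bin_size=bin_size)
        for k in names:
            boot[k][it] = getattr(r, k)
    if n_redrawn:
        logger.info("bootstrap_mediation: redrew %d degenerate resamples",
                    n_redrawn)
    for k in names:
        lo, hi, p = _bc_interval(boot[k], getattr(point, k), alpha)
        point.ci[k] = (lo, hi)
        point.p_values[k] = p
    point.n_boot = n
    point.n_redrawn = n_redrawn
    return point


def mediation_analysis(X, M, Y, subjects, bin_size: int = 12,
                       n_boot: int = 10_000, seed: int = 0) -> MediationResult:
    """Full pipeline: z-score, bin by RT_d, fit paths, BC bootstrap."""
    Xb, Mb, Yb = prepare_bins(X, M, Y, subjects, bin_size)
    return bootstrap_mediation(Xb, Mb, Yb, n=n_boot, seed=seed,
                               bin_size=bin_size)
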