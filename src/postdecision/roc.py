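"""Sliding-window ROC classification of detected vs undetected errors.

Single-trial signal means in consecutive 20 ms windows spanning -0.4 to
+0.6 s around the erroneous action are pooled across subjects and scored
with the rank-based area under the ROC curve (probability that a
detected-trial value exceeds an undetected-trial value; ties count 1/2).
Chance and its spread come from a permutation scheme that reshuffles
labels *within* subject, conserving each subject's detected/undetected
proportions; the significance band is the permutation mean +/- 1.96
permutation s.d. per window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = ["AUCSeries", "auc", "window_means", "sliding_window_auc",
           "permutation_null"]


@dataclass
class AUCSeries:
    window_centers: np.ndarray
    auc: np.ndarray
    perm_mean: np.ndarray | None = None
    perm_sd: np.ndarray | None = None
    threshold_lo: np.ndarray | None = None
    threshold_hi: np.ndarray | None = None
    n_permutations: int = 0

    def to_frame(self) -> pd.DataFrame:
        d = {"center": self.window_centers, "auc": self.auc}
        if self.perm_mean is not None:
            d.update(perm_mean=self.perm_mean, perm_sd=self.perm_sd,
                     threshold_lo=self.threshold_lo,
                     threshold_hi=self.threshold_hi)
        return pd.DataFrame(d)


def auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(value | label=1 > value | label=0), ties = 1/2."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(values)
    return float((r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def window_means(data: np.ndarray, times: np.ndarray,
                 width: float = 0.020, step: float = 0.020,
                 span: tuple[float, float] = (-0.4, 0.6)
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial mean signal in consecutive windows across ``span``.

    Windows that fall outside the epoch are omitted (logged).  Returns
    (window_centers, means) with means of shape (n_trials, n_windows).
    """
    centers, cols = [], []
    start = span[0]
    n_skipped = 0
    while start + width <= span[1] + 1e-9:
        lo, hi = start, start + width
        mask = (times >= lo - 1e-9) & (times < hi - 1e-9)
        if mask.any() and lo >= times[0] - 1e-9 and hi <= times[-1] + 1e-9:
            centers.append(lo + width / 2)
            cols.append(data[:, mask].mean(axis=1))
        else:
            n_skipped += 1
        start += step
    if n_skipped:
        logger.info("window_means: omitted %d windows outside the epoch",
                    n_skipped)
    if not centers:
        raise ValueError("no analysis window lies inside the epoch")
    return np.asarray(centers), np.column_stack(cols)


def _auc_from_ranks(ranks: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """AUC per column given precomputed midranks (n_trials, n_windows)."""
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return (labels.astype(float) @ ranks - n1 * (n1 + 1) / 2) / (n1 * n0)


def sliding_window_auc(data: np.ndarray, times: np.ndarray,
                       labels: np.ndarray,
                       width: float = 0.020, step: float = 0.020,
                       span: tuple[float, float] = (-0.4, 0.6)) -> AUCSeries:
    """Observed AUC time course on pooled trials (no null)."""
    centers, means = window_means(data, times, width, step, span)
    ranks = np.apply_along_axis(rankdata, 0, means)
    return AUCSeries(window_centers=centers,
                     auc=_auc_from_ranks(ranks, np.asarray(labels, bool)))


def permutation_null(data: np.ndarray, times: np.ndarray,
                     labels: np.ndarray, subjects: np.ndarray,
                     n: int = 1000, seed: int = 0,
                     width: float = 0.020, step: float = 0.020,
                     span: tuple[float, float] = (-0.4, 0.6)) -> AUCSeries:
    """Observed AUC series plus a within-subject permutation null.

    Labels are reshuffled independently within each subject, conserving
    that subject's detected/undetected counts; the AUC series is
    recomputed for each of ``n`` permutations.  The returned thresholds
    are ``perm_mean +/- 1.96 * perm_sd`` per window (a two-sided band;
    exceedances can be counted per tail).
    """
    if n < 100:
        warnings.warn("fewer than 100 permutations gives an unstable s.d.")
    labels = np.asarray(labels, dtype=bool)
    subjects = np.asarray(subjects)
    centers, means = window_means(data, times, width, step, span)
    ranks = np.apply_along_axis(rankdata, 0, means)
    observed = _auc_from_ranks(ranks, labels)

    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(subjects == s) for s in np.unique(subjects)]
    null = np.empty((n, centers.size))
    perm = labels.copy()
    for it in range(n):
        for idx in groups:
            perm[idx] = labels[idx][rng.permutation(idx.size)]
        null[it] = _auc_from_ranks(ranks, perm)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    return AUCSeries(window_centers=centers, auc=observed,
                     perm_mean=mean, perm_sd=sd,
                     threshold_lo=mean - 1.96 * sd,
                     threshold_hi=mean + 1.96 * sd,
                     n_permutations=n)
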