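"""One-way random-effects ANOVA estimator of the intracluster correlation.

The ICC (rho) is the proportion of total outcome variance attributable to
differences between clusters.  The method-of-moments estimator from one-way
ANOVA mean squares handles unbalanced cluster sizes and requires no strict
distributional assumption, so the same formula is applied to continuous
outcomes and to 0/1-coded binary outcomes::

    MSB = sum_i n_i (ybar_i - ybar)^2 / (k - 1)
    MSW = sum_i sum_j (y_ij - ybar_i)^2 / (N - k)
    m0  = (N - sum_i n_i^2 / N) / (k - 1)      # ANOVA-weighted cluster size
    rho_hat = (MSB - MSW) / (MSB + (m0 - 1) MSW)

Negative intracluster correlation being considered implausible, the point
estimate is censored at zero; the pre-censoring value and a censoring flag
are kept so true zeros remain distinguishable from censored negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_data import ClusteredDataset

__all__ = [
    "ICCEstimate",
    "anova_mean_squares",
    "anova_icc",
    "cluster_sufficient_stats",
    "icc_from_sums",
]


@dataclass(frozen=True)
class ICCEstimate:
    """ANOVA ICC point estimate with its mean-square ingredients."""

    icc: float
    raw_icc: float
    ms_between: float
    ms_within: float
    m0: float
    k: int
    n: int
    censored: bool


def cluster_sufficient_stats(
    values: np.ndarray, labels: pd.Series | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cluster (size, sum, sum of squares) in sorted-label order.

    These three vectors are sufficient for the ANOVA ICC of any reweighting
    or resampling of whole clusters, which is what makes the cluster
    bootstrap cheap.
    """
    codes, _ = pd.factorize(np.asarray(labels), sort=True)
    values = np.asarray(values, dtype=float)
    k = codes.max() + 1
    n_i = np.bincount(codes, minlength=k).astype(float)
    s_i = np.bincount(codes, weights=values, minlength=k)
    ss_i = np.bincount(codes, weights=values * values, minlength=k)
    return n_i, s_i, ss_i


def icc_from_sums(
    n_i: np.ndarray, s_i: np.ndarray, ss_i: np.ndarray, axis: int = -1
) -> np.ndarray | float:
    """Raw (uncensored) ANOVA ICC from per-cluster sufficient statistics.

    Works on stacked arrays (clusters along ``axis``), so a whole bootstrap
    replicate matrix is evaluated in one call.  Returns NaN where the ICC is
    undefined (all clusters singletons, i.e. N == k) and 0 where the data are
    totally degenerate (MSB = MSW = 0).
    """
    n_i = np.asarray(n_i, dtype=float)
    s_i = np.asarray(s_i, dtype=float)
    ss_i = np.asarray(ss_i, dtype=float)
    k = n_i.shape[axis]
    n = n_i.sum(axis=axis)
    total = s_i.sum(axis=axis)
    between = (s_i**2 / n_i).sum(axis=axis)
    ssb = between - total**2 / n
    ssw = ss_i.sum(axis=axis) - between
    with np.errstate(divide="ignore", invalid="ignore"):
        msb = ssb / (k - 1)
        msw = ssw / (n - k)  # NaN/inf where N == k
        m0 = (n - (n_i**2).sum(axis=axis) / n) / (k - 1)
        denom = msb + (m0 - 1.0) * msw
        raw = (msb - msw) / denom
    raw = np.where(denom == 0.0, 0.0, raw)  # MSB = MSW = 0: no variation at all
    raw = np.where(n == k, np.nan, raw)
    if np.ndim(raw) == 0:
        return float(raw)
    return raw


def anova_mean_squares(dataset: ClusteredDataset) -> tuple[float, float, float]:
    """One-way ANOVA decomposition ``(ms_between, ms_within, m0)``.

    ``m0`` is the ANOVA-weighted mean cluster size; it equals the common
    cluster size for balanced data and is slightly below the arithmetic mean
    under imbalance.
    """
    n_i, s_i, ss_i = cluster_sufficient_stats(dataset.values, dataset.cluster_labels)
    k = len(n_i)
    n = int(n_i.sum())
    if n <= k:
        raise ValueError(
            "within-cluster variance undefined: every cluster is a singleton"
        )
    total = s_i.sum()
    between = float((s_i**2 / n_i).sum())
    ssb = between - total**2 / n
    ssw = float(ss_i.sum() - between)
    msb = float(max(ssb, 0.0)) / (k - 1)
    msw = float(max(ssw, 0.0)) / (n - k)
    m0 = (n - float((n_i**2).sum()) / n) / (k - 1)
    return msb, msw, m0


def anova_icc(dataset: ClusteredDataset) -> ICCEstimate:
    """ANOVA ICC of a dataset at its analysed cluster level, censored at zero."""
    msb, msw, m0 = anova_mean_squares(dataset)
    denom = msb + (m0 - 1.0) * msw
    raw = 0.0 if denom == 0.0 else (msb - msw) / denom
    censored = bool(raw < 0.0)
    return ICCEstimate(
        icc=max(raw, 0.0),
        raw_icc=raw,
        ms_between=msb,
        ms_within=msw,
        m0=m0,
        k=dataset.k,
        n=dataset.n,
        censored=censored,
    )
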