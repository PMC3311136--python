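"""Cluster-resampling bootstrap confidence intervals for the ICC.

Whole clusters at the analysed level are drawn with replacement (k draws from
the k observed clusters), which preserves the within-cluster correlation in
every replicate.  Intervals: percentile, bias-corrected (BC) and
bias-corrected-and-accelerated (BCa), with the acceleration constant obtained
from a delete-one-cluster jackknife.  When a BC/BCa interval is not
calculable — the bias correction z0 is infinite because no (or every)
replicate falls below the point estimate, or the jackknife has zero
dispersion — the percentile interval is used instead and the substitution is
recorded.

Bootstrap replicates are censored at zero like the point estimate, and the
reported bounds are clipped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .icc_anova import anova_icc, cluster_sufficient_stats, icc_from_sums
from .trial_data import ClusteredDataset

__all__ = [
    "BootstrapCI",
    "NotCalculable",
    "cluster_resample",
    "percentile_interval",
    "bc_interval",
    "bca_interval",
    "jackknife_icc",
    "bootstrap_icc_ci",
]

logger = logging.getLogger(__name__)

#: sentinel for a BC/BCa interval that cannot be formed (infinite z0 or
#: degenerate jackknife); callers fall back to the percentile interval.
NotCalculable = None


@dataclass(frozen=True)
class BootstrapCI:
    """A bootstrap confidence interval for an ICC."""

    lower: float
    upper: float
    level: float
    n_replicates: int
    method_requested: str
    method_used: str
    seed: int | None
    replicates_summary: tuple[float, float]  # (mean, sd) of bootstrap ICCs
    n_skipped: int = 0


def _sorted_cluster_order(dataset: ClusteredDataset) -> pd.Index:
    return pd.Index(sorted(dataset.cluster_labels.unique()))


def cluster_resample(
    dataset: ClusteredDataset, rng: np.random.Generator
) -> ClusteredDataset:
    """One cluster-bootstrap resample of a dataset.

    Draws k clusters with replacement at the analysed level; every
    observation of a drawn cluster is copied, and each draw receives a
    distinct synthetic label (applied to both centre and surgeon ids so the
    nesting invariant survives duplication) so the resample again has exactly
    k clusters.
    """
    order = _sorted_cluster_order(dataset)
    k = len(order)
    draws = rng.integers(0, k, size=k)
    groups = {lab: df for lab, df in dataset.data.groupby(dataset.level, sort=False)}
    parts = []
    for j, idx in enumerate(draws):
        part = groups[order[idx]].copy()
        part["centre"] = part["centre"].astype(str) + f"#{j}"
        part["surgeon"] = part["surgeon"].map(
            lambda s, j=j: s if pd.isna(s) else f"{s}#{j}"
        )
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    return dc_replace(dataset, data=out, validate_on_init=False)


def percentile_interval(
    replicates: Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """Empirical alpha/2 and 1-alpha/2 quantiles of the replicates."""
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    alpha = 1.0 - level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _z0(theta_hat: float, reps: np.ndarray) -> float | None:
    """Bias-correction z0 = Phi^-1(share of replicates below the estimate)."""
    p = float(np.mean(reps < theta_hat))
    if p <= 0.0 or p >= 1.0:
        return NotCalculable
    return float(ndtri(p))


def bc_interval(
    theta_hat: float, replicates: Sequence[float], level: float = 0.95
) -> tuple[float, float] | None:
    """Bias-corrected bootstrap interval, or ``NotCalculable``."""
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    z0 = _z0(theta_hat, reps)
    if z0 is NotCalculable:
        return NotCalculable
    alpha = 1.0 - level
    z = ndtri(1.0 - alpha / 2.0)
    a1 = float(ndtr(2.0 * z0 - z))
    a2 = float(ndtr(2.0 * z0 + z))
    lo, hi = np.quantile(reps, [a1, a2])
    return float(lo), float(hi)


def bca_interval(
    theta_hat: float,
    replicates: Sequence[float],
    jackknife_estimates: Sequence[float],
    level: float = 0.95,
) -> tuple[float, float] | None:
    """Bias-corrected-and-accelerated interval, or ``NotCalculable``.

    ``jackknife_estimates`` must hold one delete-one-cluster estimate per
    cluster; the acceleration constant is
    ``a = sum d^3 / (6 (sum d^2)^{3/2})`` with ``d_i = mean(jack) - jack_i``.
    """
    reps = np.asarray(replicates, dtype=float)
    jack = np.asarray(jackknife_estimates, dtype=float)
    if reps.size < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    z0 = _z0(theta_hat, reps)
    if z0 is NotCalculable:
        return NotCalculable
    d = jack.mean() - jack
    ss2 = float((d**2).sum())
    if ss2 <= 0.0:
        return NotCalculable
    a = float((d**3).sum()) / (6.0 * ss2**1.5)
    alpha = 1.0 - level
    z = ndtri(1.0 - alpha / 2.0)
    bounds = []
    for zq in (-z, z):
        denom = 1.0 - a * (z0 + zq)
        if denom <= 0.0:
            return NotCalculable
        bounds.append(float(ndtr(z0 + (z0 + zq) / denom)))
    lo, hi = np.quantile(reps, bounds)
    return float(lo), float(hi)


def jackknife_icc(dataset: ClusteredDataset) -> np.ndarray:
    """Delete-one-cluster ICC estimates (censored), in sorted-label order."""
    n_i, s_i, ss_i = cluster_sufficient_stats(dataset.values, dataset.cluster_labels)
    k = len(n_i)
    keep = ~np.eye(k, dtype=bool)
    idx = np.tile(np.arange(k), (k, 1))[keep].reshape(k, k - 1)
    raw = icc_from_sums(n_i[idx], s_i[idx], ss_i[idx], axis=1)
    return np.maximum(np.asarray(raw, dtype=float), 0.0)


def bootstrap_icc_ci(
    dataset: ClusteredDataset,
    estimator: Callable[[ClusteredDataset], float] | None = None,
    n_replicates: int = 1000,
    level: float = 0.95,
    method: str = "bca",
    seed: int | np.random.SeedSequence | None = None,
) -> BootstrapCI:
    """Cluster-bootstrap confidence interval for the ICC of a dataset.

    With the default estimator (zero-censored ANOVA ICC) the replicate
    statistics are computed from per-cluster sufficient statistics, which is
    algebraically identical to estimating each materialised resample but far
    cheaper.  Passing a custom ``estimator`` switches to materialised
    resamples.  Replicates on which the estimator is undefined (e.g. an
    all-singleton resample) are skipped and counted; more than 10% skipped
    logs a warning.
    """
    if method not in ("percentile", "bc", "bca"):
        raise ValueError(f"unknown interval method {method!r}")
    rng = np.random.default_rng(seed)
    k = dataset.k

    if estimator is None:
        theta_hat = anova_icc(dataset).icc
        n_i, s_i, ss_i = cluster_sufficient_stats(
            dataset.values, dataset.cluster_labels
        )
        draws = rng.integers(0, k, size=(n_replicates, k))
        raw = np.asarray(
            icc_from_sums(n_i[draws], s_i[draws], ss_i[draws], axis=1), dtype=float
        )
        reps = np.maximum(raw[~np.isnan(raw)], 0.0)
        jack = jackknife_icc(dataset) if k >= 3 else None
    else:
        theta_hat = float(estimator(dataset))
        vals = []
        for _ in range(n_replicates):
            resample = cluster_resample(dataset, rng)
            try:
                vals.append(float(estimator(resample)))
            except Exception:
                continue
        reps = np.asarray(vals, dtype=float)
        jack = _jackknife_generic(dataset, estimator)

    n_skipped = n_replicates - reps.size
    if n_skipped > 0.1 * n_replicates:
        logger.warning(
            "%d of %d bootstrap replicates skipped", n_skipped, n_replicates
        )
    if reps.size < 2:
        raise ValueError("too few usable bootstrap replicates")

    bounds = NotCalculable
    method_used = method
    if method == "bca" and jack is not None:
        bounds = bca_interval(theta_hat, reps, jack, level)
    elif method == "bc":
        bounds = bc_interval(theta_hat, reps, level)
    if bounds is NotCalculable and method != "percentile":
        bounds = percentile_interval(reps, level)
        method_used = "percentile"
    elif method == "percentile":
        bounds = percentile_interval(reps, level)

    lo = float(np.clip(bounds[0], 0.0, 1.0))
    hi = float(np.clip(bounds[1], 0.0, 1.0))
    seed_out = seed if isinstance(seed, (int, np.integer)) or seed is None else None
    return BootstrapCI(
        lower=min(lo, hi),
        upper=max(lo, hi),
        level=level,
        n_replicates=n_replicates,
        method_requested=method,
        method_used=method_used,
        seed=seed_out,
        replicates_summary=(float(reps.mean()), float(reps.std(ddof=1))),
        n_skipped=int(n_skipped),
    )


def _jackknife_generic(
    dataset: ClusteredDataset, estimator: Callable[[ClusteredDataset], float]
) -> np.ndarray | None:
    order = _sorted_cluster_order(dataset)
    if len(order) < 3:
        return None
    out = []
    for lab in order:
        sub = dataset.data[dataset.cluster_labels != lab]
        try:
            out.append(
                float(
                    estimator(
                        dc_replace(dataset, data=sub, validate_on_init=False)
                    )
                )
            )
        except Exception:
            return None
    return np.asarray(out, dtype=float)
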