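"""Three-level variance decomposition: patient within surgeon within centre.

Fits the random-intercept model

    y_ijk = mu + u_k + v_jk + e_ijk,
    u_k ~ N(0, var_centre),  v_jk ~ N(0, var_surgeon),  e_ijk ~ N(0, var_residual)

by REML (through :class:`statsmodels` ``MixedLM`` with a variance component
for surgeon nested in the centre grouping) and derives the three ICCs as
variance ratios:

* level-3 (centre) ICC          = var_centre / total
* level-2 (surgeon) ICC         = var_surgeon / total
* levels-2-and-3 combined ICC   = (var_centre + var_surgeon) / total

The combined ICC is the correlation between two patients of the same surgeon;
the centre ICC is that between two patients of the same centre under
different surgeons.  Uncertainty comes from a cluster bootstrap that
resamples centres (the top-level units) with replacement, with BCa intervals
from a delete-one-centre jackknife and a percentile fallback.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .cluster_bootstrap import (
    BootstrapCI,
    NotCalculable,
    bca_interval,
    bc_interval,
    percentile_interval,
)
from .icc_anova import anova_icc
from .trial_data import ClusteredDataset

__all__ = [
    "VarianceComponents3L",
    "ThreeLevelICCs",
    "fit_three_level",
    "three_level_iccs",
    "bootstrap_three_level",
]

logger = logging.getLogger(__name__)

_DEFINITION_NOTE = (
    "level-2 ICC = var_surgeon/total, level-3 ICC = var_centre/total, "
    "levels-2&3 ICC = (var_centre+var_surgeon)/total"
)


@dataclass(frozen=True)
class VarianceComponents3L:
    var_centre: float
    var_surgeon: float
    var_residual: float
    converged: bool
    loglik: float
    note: str = ""


@dataclass(frozen=True)
class ThreeLevelICCs:
    icc_level3_centre: float
    icc_level2_surgeon: float
    icc_levels23_combined: float
    definition_note: str = _DEFINITION_NOTE


def fit_three_level(dataset: ClusteredDataset) -> VarianceComponents3L:
    """REML fit of the three-level random-intercept model.

    Requires a continuous outcome, >= 2 centres and surgeon labels for every
    participant.  When no centre holds more than one surgeon the centre and
    surgeon components are confounded (only their sum is identified); the fit
    proceeds and the confounding is recorded in ``note`` rather than raised.
    Variance components are constrained non-negative by the optimiser;
    non-convergence is flagged, not silenced.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    if dataset.outcome_kind != "continuous":
        raise ValueError("three-level decomposition requires a continuous outcome")
    df = dataset.data
    if df["surgeon"].isna().any():
        raise ValueError("three-level model requires surgeon labels for all rows")
    if df["centre"].nunique() < 2:
        raise ValueError("need at least 2 centres")

    note = ""
    surgeons_per_centre = df.groupby("centre")["surgeon"].nunique()
    if (surgeons_per_centre <= 1).all():
        note = (
            "every centre has a single surgeon: centre and surgeon variance are "
            "confounded; only their sum is identified"
        )

    model = MixedLM.from_formula(
        "value ~ 1",
        groups="centre",
        re_formula="1",
        vc_formula={"surgeon": "0 + C(surgeon)"},
        data=df,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method="lbfgs")
    var_centre = max(float(result.cov_re.iloc[0, 0]), 0.0)
    var_surgeon = max(float(result.vcomp[0]), 0.0)
    var_residual = float(result.scale)
    converged = bool(getattr(result, "converged", True))
    if not converged and not note:
        # with confounded components a flat likelihood direction is expected
        logger.warning("three-level REML fit did not converge")
    return VarianceComponents3L(
        var_centre=var_centre,
        var_surgeon=var_surgeon,
        var_residual=var_residual,
        converged=converged,
        loglik=float(result.llf),
        note=note,
    )


def three_level_iccs(vc: VarianceComponents3L) -> ThreeLevelICCs:
    """Variance-ratio ICCs of a fitted three-level decomposition."""
    total = vc.var_centre + vc.var_surgeon + vc.var_residual
    if total <= 0.0:
        raise ValueError("total variance must be positive")
    return ThreeLevelICCs(
        icc_level3_centre=vc.var_centre / total,
        icc_level2_surgeon=vc.var_surgeon / total,
        icc_levels23_combined=(vc.var_centre + vc.var_surgeon) / total,
    )


def _resample_centres(
    dataset: ClusteredDataset, rng: np.random.Generator
) -> ClusteredDataset:
    """Draw centres with replacement, relabelling duplicates distinctly."""
    centres = sorted(dataset.data["centre"].unique())
    draws = rng.integers(0, len(centres), size=len(centres))
    groups = {lab: df for lab, df in dataset.data.groupby("centre", sort=False)}
    parts = []
    for j, idx in enumerate(draws):
        part = groups[centres[idx]].copy()
        part["centre"] = part["centre"].astype(str) + f"#{j}"
        part["surgeon"] = part["surgeon"].astype(str) + f"#{j}"
        parts.append(part)
    return dc_replace(
        dataset, data=pd.concat(parts, ignore_index=True), validate_on_init=False
    )


_ICC_KEYS = ("icc_level3_centre", "icc_level2_surgeon", "icc_levels23_combined")


def _fit_iccs(dataset: ClusteredDataset) -> dict[str, float]:
    iccs = three_level_iccs(fit_three_level(dataset))
    return {key: np.clip(getattr(iccs, key), 0.0, 1.0) for key in _ICC_KEYS}


def bootstrap_three_level(
    dataset: ClusteredDataset,
    n_replicates: int = 1000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
    method: str = "bca",
) -> dict[str, BootstrapCI]:
    """Centre-resampling bootstrap intervals for the three derived ICCs.

    Returns one :class:`BootstrapCI` per ICC, keyed ``icc_level3_centre``,
    ``icc_level2_surgeon`` and ``icc_levels23_combined``.  Replicates on
    which the REML fit fails are skipped and counted.
    """
    rng = np.random.default_rng(seed)
    point = _fit_iccs(dataset)

    reps: dict[str, list[float]] = {key: [] for key in _ICC_KEYS}
    n_failed = 0
    for _ in range(n_replicates):
        resample = _resample_centres(dataset, rng)
        try:
            est = _fit_iccs(resample)
        except Exception:
            n_failed += 1
            continue
        for key in _ICC_KEYS:
            reps[key].append(est[key])
    if n_failed > 0.1 * n_replicates:
        logger.warning("%d of %d bootstrap fits failed", n_failed, n_replicates)

    # delete-one-centre jackknife for the acceleration constants
    centres = sorted(dataset.data["centre"].unique())
    jack: dict[str, list[float]] | None = {key: [] for key in _ICC_KEYS}
    if len(centres) >= 3:
        for lab in centres:
            sub = dataset.data[dataset.data["centre"] != lab]
            try:
                est = _fit_iccs(
                    dc_replace(dataset, data=sub, validate_on_init=False)
                )
            except Exception:
                jack = None
                break
            for key in _ICC_KEYS:
                jack[key].append(est[key])  # type: ignore[union-attr]
    else:
        jack = None

    out: dict[str, BootstrapCI] = {}
    for key in _ICC_KEYS:
        r = np.asarray(reps[key], dtype=float)
        if r.size < 2:
            raise ValueError("too few usable bootstrap replicates")
        bounds = NotCalculable
        method_used = method
        if method == "bca" and jack is not None:
            bounds = bca_interval(point[key], r, jack[key], level)
        elif method == "bc":
            bounds = bc_interval(point[key], r, level)
        if bounds is NotCalculable and method != "percentile":
            bounds = percentile_interval(r, level)
            method_used = "percentile"
        elif method == "percentile":
            bounds = percentile_interval(r, level)
        lo = float(np.clip(bounds[0], 0.0, 1.0))
        hi = float(np.clip(bounds[1], 0.0, 1.0))
        out[key] = BootstrapCI(
            lower=min(lo, hi),
            upper=max(lo, hi),
            level=level,
            n_replicates=n_replicates,
            method_requested=method,
            method_used=method_used,
            seed=seed if isinstance(seed, (int, np.integer)) else None,
            replicates_summary=(float(r.mean()), float(r.std(ddof=1))),
            n_skipped=n_failed,
        )
    return out
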