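"""Design-effect and sample-size arithmetic for surgical trial designs.

The design effect (variance inflation factor) is the multiplier applied to a
standard, independence-assuming sample size to account for clustering by
surgeon (or centre).  For a continuous outcome:

* expertise-based design — each surgeon delivers only one of the compared
  interventions, so treatment contrasts are between clusters and the sample
  size inflates by ``1 + (m - 1) * rho`` for average cluster size ``m``;
* stratified (or minimised) within-surgeon design — each surgeon delivers
  both interventions, and clustering *reduces* the required size by the
  factor ``1 - rho``.

Unequal cluster sizes are absorbed through the adjusted cluster size
``sum(n_i^2) / sum(n_i)``, which exceeds the arithmetic mean whenever sizes
vary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignEffectResult",
    "stratified_design_effect",
    "expertise_design_effect",
    "adjusted_cluster_size",
    "inflated_sample_size",
    "design_effect_table",
    "round_half_away",
]

DESIGNS = ("expertise_based", "stratified_within_surgeon")


@dataclass(frozen=True)
class DesignEffectResult:
    design: str
    icc: float
    cluster_size_used: float
    design_effect: float
    base_n: int | None = None
    adjusted_n: int | None = None


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with halves away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_icc(icc: float) -> None:
    if not (0.0 <= icc < 1.0):
        raise ValueError(f"icc must lie in [0, 1), got {icc}")


def stratified_design_effect(icc: float) -> float:
    """Design effect ``1 - rho`` of a stratified within-surgeon design."""
    _check_icc(icc)
    return 1.0 - icc


def expertise_design_effect(icc: float, avg_cluster_size: float) -> float:
    """Design effect ``1 + (m - 1) * rho`` of an expertise-based design."""
    _check_icc(icc)
    if avg_cluster_size < 1.0:
        raise ValueError(f"average cluster size must be >= 1, got {avg_cluster_size}")
    return 1.0 + (avg_cluster_size - 1.0) * icc


def adjusted_cluster_size(sizes: Sequence[int] | np.ndarray) -> float:
    """Adjusted cluster size ``sum(n_i^2) / sum(n_i)``.

    An effective cluster size that allows for variation in cluster size; by
    Cauchy-Schwarz it is at least the arithmetic mean, with equality only for
    equal sizes.
    """
    arr = np.asarray(sizes, dtype=float)
    if arr.size == 0:
        raise ValueError("sizes must be non-empty")
    if (arr < 1).any():
        raise ValueError("all cluster sizes must be >= 1")
    return float((arr**2).sum() / arr.sum())


def inflated_sample_size(base_n: int, design_effect: float) -> int:
    """Clustering-adjusted total sample size ``ceil(base_n * design_effect)``."""
    if base_n < 1:
        raise ValueError("base_n must be >= 1")
    if design_effect <= 0:
        raise ValueError("design_effect must be > 0")
    return math.ceil(base_n * design_effect)


def design_effect_table(
    icc_values: Sequence[float],
    size_summaries: Sequence[tuple[str, float]] | Iterable[tuple[str, float]],
    base_n: int | None = None,
    ndigits: int = 2,
) -> pd.DataFrame:
    """Grid of design effects over ICCs x labelled cluster sizes.

    One row per (icc, size) pair with the expertise-based multiplier and the
    (size-independent) stratified within-surgeon multiplier, both rendered
    half-away-from-zero to ``ndigits``; when ``base_n`` is given the inflated
    sample sizes are appended.
    """
    rows = []
    for icc in icc_values:
        for label, size in size_summaries:
            de_exp = expertise_design_effect(icc, size)
            de_strat = stratified_design_effect(icc)
            row = {
                "icc": icc,
                "cluster_size_label": label,
                "cluster_size": size,
                "expertise_design_effect": round_half_away(de_exp, ndigits),
                "stratified_design_effect": round_half_away(de_strat, ndigits),
            }
            if base_n is not None:
                row["expertise_n"] = inflated_sample_size(base_n, de_exp)
                row["stratified_n"] = inflated_sample_size(base_n, de_strat)
            rows.append(row)
    return pd.DataFrame(rows)
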