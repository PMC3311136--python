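"""Generators of clustered trial datasets with known ICC structure.

Real multicentre surgical trial data are confidential, so every stage of the
pipeline is exercised on simulated trials whose clustering is known by
construction:

* continuous outcomes — random-intercept normal model
  ``y = mu + b_cluster + e`` with ``b ~ N(0, rho * sigma^2)`` and
  ``e ~ N(0, (1 - rho) * sigma^2)``, so the population ICC is exactly rho;
* binary outcomes — beta-binomial model: each cluster draws an event
  probability ``p_i ~ Beta(alpha, beta)`` with mean equal to the prevalence
  and ``ICC = 1 / (alpha + beta + 1)``, members are Bernoulli(p_i);
* three-level outcomes — independent centre and surgeon-within-centre normal
  intercepts with specified variances.

:func:`simulate_trial_suite` emulates the shapes of a published database of
10 multicentre surgical trials (138-1370 participants, 8-27 centres, 16-191
surgeons, one trial without surgeon identifiers) over a configurable palette
of ICC values spanning the 0-0.47 range observed there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trial_data import ClusteredDataset

__all__ = [
    "SimulationSpec",
    "beta_parameters",
    "simulate_continuous",
    "simulate_binary",
    "simulate_three_level",
    "simulate_trial_suite",
    "TRIAL_SHAPES",
    "DEFAULT_ICC_PALETTE",
]

#: (name, participants, centres, surgeons-or-None) of the 10 emulated trials
TRIAL_SHAPES: tuple[tuple[str, int, int, int | None], ...] = (
    ("CLIVIT", 491, 13, 125),
    ("DISPACT", 352, 21, 126),
    ("FILMS", 138, 9, None),
    ("HERNIA", 928, 24, 31),
    ("INSECT", 625, 24, 191),
    ("KATMETAL", 409, 8, 16),
    ("KATMOBILE", 539, 13, 24),
    ("KATPATELLA", 1370, 27, 99),
    ("REFLUX", 178, 19, 31),
    ("STARS", 298, 11, 49),
)

#: centre-level ICCs assigned to the emulated trials, spanning the observed range
DEFAULT_ICC_PALETTE: tuple[float, ...] = (
    0.0, 0.01, 0.05, 0.1, 0.15, 0.2, 0.27, 0.33, 0.4, 0.47,
)

# size distribution: int (all equal), sequence of ints (explicit), or
# ("nbinom", mean) — 1 + NegativeBinomial with the dispersion below, a
# zero-truncated shape whose mean is exactly `mean`
SizeDist = int | Sequence[int] | tuple[str, float]

_NBINOM_DISPERSION = 2.0


@dataclass
class SimulationSpec:
    """Parameters of one simulated clustered trial.

    ``level`` names the level carrying the cluster effect in the two-level
    generators (and the level the resulting dataset is analysed at).  For
    two-level simulation give ``icc``; for three-level simulation give
    ``variances = (var_centre, var_surgeon, var_residual)``.  ``total_var``
    is the total outcome variance of the continuous model (default 1).
    """

    n_centres: int
    surgeons_per_centre: SizeDist = 1
    patients_per_surgeon: SizeDist = 30
    outcome_kind: str = "continuous"
    icc: float | None = None
    variances: tuple[float, float, float] | None = None
    mu: float = 0.0
    prevalence: float | None = None
    total_var: float = 1.0
    level: str = "centre"
    outcome_name: str = "simulated outcome"
    timepoint: str = ""
    trial: str = "SIM"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.icc is not None and not (0.0 <= self.icc < 1.0):
            raise ValueError(f"two-level icc must lie in [0, 1), got {self.icc}")
        if self.variances is not None:
            if len(self.variances) != 3 or any(v < 0 for v in self.variances):
                raise ValueError("variances must be three non-negative numbers")
        if self.prevalence is not None and not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_centres < 1:
            raise ValueError("need at least one centre")


def _draw_sizes(dist: SizeDist, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(dist, (int, np.integer)):
        return np.full(n, int(dist), dtype=int)
    if isinstance(dist, tuple) and len(dist) == 2 and dist[0] == "nbinom":
        mean = float(dist[1])
        if mean < 1.0:
            raise ValueError("nbinom size distribution needs mean >= 1")
        r = _NBINOM_DISPERSION
        p = r / (r + mean - 1.0) if mean > 1.0 else 1.0
        return 1 + rng.negative_binomial(r, p, size=n)
    sizes = np.asarray(dist, dtype=int)
    if len(sizes) != n:
        raise ValueError(f"expected {n} sizes, got {len(sizes)}")
    return sizes


def _hierarchy(
    spec: SimulationSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Participant frame with centre/surgeon labels per the spec's shape."""
    n_surg = _draw_sizes(spec.surgeons_per_centre, spec.n_centres, rng)
    pat_sizes = _draw_sizes(spec.patients_per_surgeon, int(n_surg.sum()), rng)
    centres, surgeons = [], []
    pos = 0
    for c, ns in enumerate(n_surg):
        c_lab = f"C{c:03d}"
        for s in range(int(ns)):
            npat = int(pat_sizes[pos])
            pos += 1
            centres.extend([c_lab] * npat)
            surgeons.extend([f"{c_lab}.S{s:03d}"] * npat)
    df = pd.DataFrame({"centre": centres, "surgeon": surgeons})
    df["participant_id"] = [f"p{i:05d}" for i in range(len(df))]
    df["arm"] = "surgery"
    return df


def _dataset(spec: SimulationSpec, df: pd.DataFrame, kind: str) -> ClusteredDataset:
    return ClusteredDataset(
        outcome_name=spec.outcome_name,
        timepoint=spec.timepoint,
        outcome_kind=kind,
        data=df,
        level=spec.level,
        trial=spec.trial,
    )


def simulate_continuous(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> ClusteredDataset:
    """Two-level normal outcome with population ICC exactly ``spec.icc``."""
    if spec.icc is None:
        raise ValueError("simulate_continuous needs spec.icc")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    df = _hierarchy(spec, rng)
    labels, codes = np.unique(df[spec.level].to_numpy(), return_inverse=True)
    b = rng.normal(0.0, np.sqrt(spec.icc * spec.total_var), size=len(labels))
    e = rng.normal(0.0, np.sqrt((1.0 - spec.icc) * spec.total_var), size=len(df))
    df["value"] = spec.mu + b[codes] + e
    return _dataset(spec, df, "continuous")


def beta_parameters(icc: float, prevalence: float) -> tuple[float, float]:
    """(alpha, beta) of the cluster-probability Beta with the given ICC.

    Solves ``mean = alpha/(alpha+beta) = prevalence`` and
    ``ICC = 1/(alpha+beta+1)``.
    """
    if not (0.0 < icc < 1.0):
        raise ValueError("beta parameters require 0 < icc < 1")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    total = 1.0 / icc - 1.0
    return prevalence * total, (1.0 - prevalence) * total


def simulate_binary(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> ClusteredDataset:
    """Beta-binomial binary outcome; ``icc = 0`` degenerates to a common p."""
    if spec.icc is None or spec.prevalence is None:
        raise ValueError("simulate_binary needs spec.icc and spec.prevalence")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    df = _hierarchy(spec, rng)
    labels, codes = np.unique(df[spec.level].to_numpy(), return_inverse=True)
    if spec.icc == 0.0:
        p = np.full(len(labels), spec.prevalence)
    else:
        alpha, beta = beta_parameters(spec.icc, spec.prevalence)
        p = rng.beta(alpha, beta, size=len(labels))
    df["value"] = (rng.random(len(df)) < p[codes]).astype(float)
    return _dataset(spec, df, "binary")


def simulate_three_level(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> ClusteredDataset:
    """Patient-within-surgeon-within-centre normal outcome."""
    if spec.variances is None:
        raise ValueError("simulate_three_level needs spec.variances")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    var_c, var_s, var_e = spec.variances
    df = _hierarchy(spec, rng)
    c_labels, c_codes = np.unique(df["centre"].to_numpy(), return_inverse=True)
    s_labels, s_codes = np.unique(df["surgeon"].to_numpy(), return_inverse=True)
    u = rng.normal(0.0, np.sqrt(var_c), size=len(c_labels))
    v = rng.normal(0.0, np.sqrt(var_s), size=len(s_labels))
    e = rng.normal(0.0, np.sqrt(var_e), size=len(df))
    df["value"] = spec.mu + u[c_codes] + v[s_codes] + e
    return _dataset(spec, df, "continuous")


def _allocate(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Split `total` units over `parts` groups, each >= 1, unbalanced."""
    weights = rng.dirichlet(np.ones(parts))
    extra = rng.multinomial(total - parts, weights)
    return 1 + extra


def simulate_trial_suite(
    seed: int | None = None,
    icc_palette: Sequence[float] = DEFAULT_ICC_PALETTE,
) -> list[ClusteredDataset]:
    """Ten synthetic trials with the shapes of the emulated trial database.

    Each dataset reproduces one trial's participant count, centre count and
    surgeon count (surgeons allocated to centres and participants to surgeons
    with unbalanced Dirichlet-multinomial splits, every cluster non-empty) and
    carries a continuous outcome with the centre-level ICC taken from
    ``icc_palette`` in order.  One global seed drives a split per-trial
    stream, so individual datasets are reproducible item-wise.
    """
    if len(icc_palette) != len(TRIAL_SHAPES):
        raise ValueError(
            f"icc_palette must provide {len(TRIAL_SHAPES)} values"
        )
    streams = np.random.SeedSequence(seed).spawn(len(TRIAL_SHAPES))
    suite = []
    for (name, n, n_centres, n_surgeons), icc, ss in zip(
        TRIAL_SHAPES, icc_palette, streams
    ):
        rng = np.random.default_rng(ss)
        if n_surgeons is None:
            pat_per_centre = _allocate(n, n_centres, rng)
            spec = SimulationSpec(
                n_centres=n_centres,
                surgeons_per_centre=1,
                patients_per_surgeon=list(pat_per_centre),
                icc=icc,
                level="centre",
                outcome_name="simulated outcome",
                trial=name,
            )
            ds = simulate_continuous(spec, rng)
            ds.data["surgeon"] = pd.NA  # this trial recorded no surgeon ids
        else:
            surg_per_centre = _allocate(n_surgeons, n_centres, rng)
            pat_per_surgeon = _allocate(n, n_surgeons, rng)
            spec = SimulationSpec(
                n_centres=n_centres,
                surgeons_per_centre=list(surg_per_centre),
                patients_per_surgeon=list(pat_per_surgeon),
                icc=icc,
                level="centre",
                outcome_name="simulated outcome",
                trial=name,
            )
            ds = simulate_continuous(spec, rng)
        ds.outcome_name = f"simulated outcome ({name})"
        suite.append(ds)
    return suite
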