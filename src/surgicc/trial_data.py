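"""Data model and I/O for clustered patient-level surgical trial data.

A :class:`ClusteredDataset` holds the participant-level values of one outcome
at one time point, together with the nested cluster labels (operating surgeon
within centre) and the trial arm of each participant.  Clustering can be
analysed at either the centre or the surgeon level; the operating surgeon
defines the surgeon-level cluster whether or not surgeons featured in the
randomisation algorithm.

The canonical on-disk format is a UTF-8 CSV with header columns
``participant_id, outcome, value, centre, surgeon, arm, timepoint``; a column
map allows other headers to be used.  Rows with a missing outcome value or a
missing cluster label at the analysed level are dropped at load time
(complete-case within outcome) and the dropped count is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClusteredDataset",
    "ClusterSummary",
    "DataValidationError",
    "NestingError",
    "TooFewClustersError",
    "load_trial_table",
    "write_trial_table",
    "select_surgical_arms",
    "summarize_clusters",
    "CANONICAL_COLUMNS",
]

logger = logging.getLogger(__name__)

LEVELS = ("centre", "surgeon")
OUTCOME_KINDS = ("continuous", "binary")

#: canonical CSV header, in order
CANONICAL_COLUMNS = (
    "participant_id",
    "outcome",
    "value",
    "centre",
    "surgeon",
    "arm",
    "timepoint",
)


class DataValidationError(ValueError):
    """Participant table violates a structural requirement."""


class NestingError(DataValidationError):
    """A surgeon appears under more than one centre."""


class TooFewClustersError(DataValidationError):
    """Fewer than two clusters at the analysed level."""


@dataclass
class ClusteredDataset:
    """Participant-level values of one outcome with nested cluster labels.

    Parameters
    ----------
    outcome_name, timepoint
        Identify which outcome / time point the values belong to.
    outcome_kind
        ``"continuous"`` or ``"binary"`` (values coded 0/1).
    data
        One row per participant with columns ``participant_id``, ``value``,
        ``centre``, ``surgeon``, ``arm``.  ``surgeon`` may be entirely missing
        for trials that did not record the operating surgeon.
    level
        Cluster level selected for analysis, ``"centre"`` or ``"surgeon"``.
    n_dropped
        Number of rows removed while loading (missing value or label).
    """

    outcome_name: str
    timepoint: str
    outcome_kind: str
    data: pd.DataFrame
    level: str = "centre"
    n_dropped: int = 0
    trial: str = ""
    validate_on_init: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("participant_id", "value", "centre", "surgeon", "arm"):
            if col not in df.columns:
                if col == "surgeon":
                    df[col] = pd.NA
                elif col == "arm":
                    df[col] = ""
                elif col == "participant_id":
                    df[col] = [f"p{i}" for i in range(len(df))]
                else:
                    raise DataValidationError(f"required column {col!r} missing")
        df["value"] = pd.to_numeric(df["value"], errors="raise").astype(float)
        self.data = df.reset_index(drop=True)
        if self.validate_on_init:
            self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        if self.outcome_kind not in OUTCOME_KINDS:
            raise DataValidationError(f"unknown outcome kind {self.outcome_kind!r}")
        if self.level not in LEVELS:
            raise DataValidationError(f"unknown cluster level {self.level!r}")
        df = self.data
        if df["value"].isna().any():
            raise DataValidationError("missing outcome values inside observations")
        if df["centre"].isna().any():
            raise DataValidationError("missing centre labels inside observations")
        if self.level == "surgeon" and df["surgeon"].isna().any():
            raise DataValidationError(
                "surgeon-level analysis requested but surgeon labels are missing"
            )
        if self.outcome_kind == "binary":
            bad = set(df["value"].unique()) - {0.0, 1.0}
            if bad:
                raise DataValidationError(
                    f"binary outcome contains values outside {{0,1}}: {sorted(bad)}"
                )
        # nesting: each surgeon under exactly one centre
        with_surgeon = df[df["surgeon"].notna()]
        if len(with_surgeon):
            per_surgeon = with_surgeon.groupby("surgeon", sort=False)["centre"].nunique()
            offenders = per_surgeon[per_surgeon > 1]
            if len(offenders):
                raise NestingError(
                    "surgeon(s) appear under more than one centre: "
                    + ", ".join(map(str, offenders.index[:5]))
                )
        k, n = self.k, self.n
        if k < 2:
            raise TooFewClustersError(
                f"need at least 2 clusters at {self.level} level, found {k}"
            )
        if n <= k:
            raise DataValidationError(
                f"need N > k for within-cluster degrees of freedom (N={n}, k={k})"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def cluster_labels(self) -> pd.Series:
        """Cluster label of each participant at the analysed level."""
        return self.data[self.level]

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def k(self) -> int:
        return int(self.cluster_labels.nunique())

    def cluster_sizes(self) -> np.ndarray:
        """Cluster sizes in sorted-label order."""
        return (
            self.cluster_labels.value_counts().sort_index().to_numpy(dtype=int)
        )

    @property
    def has_surgeon(self) -> bool:
        return bool(self.data["surgeon"].notna().all()) and len(self.data) > 0

    def with_level(self, level: str) -> "ClusteredDataset":
        """Same data analysed at a different cluster level."""
        return replace(self, level=level, validate_on_init=True)

    def label(self) -> str:
        """Outcome label combining name and time point (e.g. ``EQ-5D 3 m``)."""
        return f"{self.outcome_name} {self.timepoint}".strip()


@dataclass(frozen=True)
class ClusterSummary:
    """Cluster-size distribution and outcome level for one dataset."""

    level: str
    k: int
    n: int
    sizes: tuple[int, ...]
    mean_size: float
    adjusted_size: float
    min_size: int
    max_size: int
    outcome_mean_or_prevalence: float


def load_trial_table(
    path: str | Path,
    outcome_kind: str,
    column_map: Mapping[str, str] | None = None,
    level: str = "centre",
    outcome: str | None = None,
    timepoint: str | None = None,
) -> ClusteredDataset:
    """Read a participant-level CSV into a :class:`ClusteredDataset`.

    ``column_map`` maps canonical column names to the file's headers, e.g.
    ``{"value": "eq5d_score"}``.  Rows with a missing outcome value or a
    missing cluster label at the analysed level are dropped and counted in
    ``n_dropped``.  ``outcome``/``timepoint`` select one outcome when the file
    holds several.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    rename = {}
    for canonical, actual in (column_map or {}).items():
        if canonical not in CANONICAL_COLUMNS:
            raise DataValidationError(f"unknown canonical column {canonical!r}")
        if actual not in df.columns:
            raise DataValidationError(f"mapped column {actual!r} not in {path.name}")
        rename[actual] = canonical
    df = df.rename(columns=rename)
    for required in ("value", "centre"):
        if required not in df.columns:
            raise DataValidationError(f"column {required!r} missing from {path.name}")

    if "outcome" in df.columns and outcome is not None:
        df = df[df["outcome"] == outcome]
    if "timepoint" in df.columns and timepoint is not None:
        df = df[df["timepoint"] == timepoint]

    outcome_names = df["outcome"].dropna().unique() if "outcome" in df.columns else []
    if len(outcome_names) > 1:
        raise DataValidationError(
            f"file holds several outcomes {list(outcome_names)}; pass outcome="
        )
    name = outcome if outcome is not None else (
        outcome_names[0] if len(outcome_names) else path.stem
    )
    timepoints = (
        df["timepoint"].dropna().unique() if "timepoint" in df.columns else []
    )
    tp = timepoint if timepoint is not None else (
        str(timepoints[0]) if len(timepoints) == 1 else ""
    )

    n_before = len(df)
    value_num = pd.to_numeric(df["value"], errors="coerce")
    keep = value_num.notna() & df["centre"].notna()
    if level == "surgeon":
        if "surgeon" not in df.columns:
            raise DataValidationError(
                "surgeon-level analysis requested but file has no surgeon column"
            )
        keep &= df["surgeon"].notna()
    df = df.loc[keep].copy()
    df["value"] = value_num.loc[keep]
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("%s: dropped %d row(s) with missing data", path.name, n_dropped)

    return ClusteredDataset(
        outcome_name=str(name),
        timepoint=tp,
        outcome_kind=outcome_kind,
        data=df,
        level=level,
        n_dropped=n_dropped,
    )


def write_trial_table(dataset: ClusteredDataset, path: str | Path) -> None:
    """Write a dataset back to the canonical CSV format."""
    df = dataset.data.copy()
    df["outcome"] = dataset.outcome_name
    df["timepoint"] = dataset.timepoint
    df[list(CANONICAL_COLUMNS)].to_csv(path, index=False)


def select_surgical_arms(
    dataset: ClusteredDataset, surgical_arms: Iterable[str]
) -> ClusteredDataset:
    """Keep only participants in the listed surgical arms.

    Post-intervention values from the surgical arms are pooled with no
    adjustment for treatment (a common ICC across the interventions is
    assumed).  The result is re-validated; filtering that leaves fewer than
    two clusters raises :class:`TooFewClustersError`.
    """
    arms = set(surgical_arms)
    if not arms:
        raise ValueError("surgical_arms must be non-empty")
    df = dataset.data[dataset.data["arm"].isin(arms)]
    if df[dataset.level].nunique() < 2:
        raise TooFewClustersError(
            f"fewer than 2 {dataset.level} clusters remain after selecting arms {sorted(arms)}"
        )
    return replace(dataset, data=df.reset_index(drop=True), validate_on_init=True)


def summarize_clusters(dataset: ClusteredDataset) -> ClusterSummary:
    """Cluster-size distribution and outcome mean (or prevalence)."""
    from .design_effects import adjusted_cluster_size

    sizes = dataset.cluster_sizes()
    return ClusterSummary(
        level=dataset.level,
        k=dataset.k,
        n=dataset.n,
        sizes=tuple(int(s) for s in sizes),
        mean_size=float(np.mean(sizes)),
        adjusted_size=float(adjusted_cluster_size(sizes)),
        min_size=int(sizes.min()),
        max_size=int(sizes.max()),
        outcome_mean_or_prevalence=float(np.mean(dataset.values)),
    )
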