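"""The publishable ICC database: records, pipeline runner and summaries.

An :class:`ICCRecord` is one row of the database — one outcome at one time
point of one trial, analysed at one cluster level, with its ANOVA ICC and a
cluster-bootstrap 95% CI.  :func:`run_full_analysis` turns a collection of
clustered datasets into such records (two per outcome where surgeon
identifiers exist, one otherwise), and :func:`summarize_by_outcome` condenses
records into per-outcome-group medians and ranges.

A copy of the point estimates of a published database of 10 multicentre
surgical trials (48 outcomes at centre and surgeon level) ships with the
package for use as summary-stage input and reference data; see
:func:`load_published_estimates`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster_bootstrap import bootstrap_icc_ci
from .design_effects import round_half_away
from .icc_anova import anova_icc
from .trial_data import ClusteredDataset, select_surgical_arms, summarize_clusters

__all__ = [
    "ICCRecord",
    "OutcomeSummary",
    "DEFAULT_OUTCOME_GROUPS",
    "run_full_analysis",
    "summarize_by_outcome",
    "write_database",
    "read_database",
    "load_published_estimates",
]

logger = logging.getLogger(__name__)

#: outcome-label -> summary group; labels not listed summarise under their own
#: name.  Groups follow the published database: EQ-5D and the Oxford knee
#: score by time point (with the 4-month EQ-5D pooled into the 3-month group),
#: operating time including one trial's wound-closure time, and the
#: complication-type outcomes pooled as surgical complications.
DEFAULT_OUTCOME_GROUPS: dict[str, str] = {
    "EQ-5D 4 m": "EQ-5D 3 m",
    "Operating time (min)": "Operating time",
    "Closure time (min)": "Operating time",
    "Length of stay (days)": "Length of stay",
    "Fistula": "Surgical complications",
    "Complication 6 m": "Surgical complications",
    "Complication 1 wk": "Surgical complications",
    "Wound infection": "Surgical complications",
}

_DB_COLUMNS = (
    "trial",
    "outcome",
    "timepoint",
    "level",
    "n",
    "mean_or_prop",
    "icc",
    "ci_lower",
    "ci_upper",
    "ci_method_used",
    "n_clusters",
    "avg_cluster_size",
    # full-precision shadows of the 3-dp display columns
    "icc_full",
    "ci_lower_full",
    "ci_upper_full",
    "mean_or_prop_full",
    "avg_cluster_size_full",
)


@dataclass(frozen=True)
class ICCRecord:
    """One row of the publishable ICC database."""

    trial: str
    outcome: str
    timepoint: str
    level: str
    n: int
    mean_or_prop: float
    icc: float
    ci_lower: float
    ci_upper: float
    ci_method_used: str
    n_clusters: int
    avg_cluster_size: float

    @property
    def outcome_label(self) -> str:
        return f"{self.outcome} {self.timepoint}".strip()


@dataclass(frozen=True)
class OutcomeSummary:
    """Median and range of ICC point estimates in one outcome group."""

    outcome_group: str
    level: str
    n_trials: int
    median_icc: float
    min_icc: float
    max_icc: float


def run_full_analysis(
    datasets: Iterable[ClusteredDataset],
    surgical_arms: Sequence[str] | None = None,
    n_replicates: int = 1000,
    ci_level: float = 0.95,
    method: str = "bca",
    seed: int | None = None,
    trial_names: Sequence[str] | None = None,
    levels: Sequence[str] = ("centre", "surgeon"),
) -> list[ICCRecord]:
    """Run the whole ICC pipeline over a collection of datasets.

    For each dataset: optional pooling of the listed surgical arms, then at
    each cluster level an ANOVA ICC and a cluster-bootstrap CI.  The surgeon
    level is skipped where the data carry no surgeon identifiers.  Failures
    on a single dataset are logged and skipped so the run continues.  A
    single ``seed`` drives split per-analysis streams, so the full run is
    reproducible.
    """
    datasets = list(datasets)
    names = list(trial_names) if trial_names is not None else [
        getattr(ds, "trial", None) or f"trial-{i + 1}" for i, ds in enumerate(datasets)
    ]
    root = np.random.SeedSequence(seed)
    records: list[ICCRecord] = []
    for ds, name, stream in zip(datasets, names, root.spawn(len(datasets))):
        substreams = iter(stream.spawn(len(levels)))
        for level in levels:
            sub = next(substreams)
            if level == "surgeon" and not ds.has_surgeon:
                logger.info("%s %s: no surgeon identifiers, level skipped",
                            name, ds.label())
                continue
            try:
                d = ds.with_level(level)
                if surgical_arms is not None:
                    d = select_surgical_arms(d, surgical_arms)
                est = anova_icc(d)
                ci = bootstrap_icc_ci(
                    d,
                    n_replicates=n_replicates,
                    level=ci_level,
                    method=method,
                    seed=sub,
                )
                summary = summarize_clusters(d)
            except Exception as exc:  # keep going; record the failure
                logger.warning("%s %s @ %s failed: %s", name, ds.label(), level, exc)
                continue
            records.append(
                ICCRecord(
                    trial=name,
                    outcome=d.outcome_name,
                    timepoint=d.timepoint,
                    level=level,
                    n=d.n,
                    mean_or_prop=summary.outcome_mean_or_prevalence,
                    icc=est.icc,
                    ci_lower=ci.lower,
                    ci_upper=ci.upper,
                    ci_method_used=ci.method_used,
                    n_clusters=d.k,
                    avg_cluster_size=summary.mean_size,
                )
            )
            logger.info("%s %s @ %s: ICC %.3f (%.3f, %.3f) [%s]",
                        name, ds.label(), level, est.icc, ci.lower, ci.upper,
                        ci.method_used)
    return records


def summarize_by_outcome(
    records: Sequence[ICCRecord],
    grouping: Mapping[str, str] | None = None,
) -> list[OutcomeSummary]:
    """Per outcome-group x level: count, median, min and max of the ICCs.

    ``grouping`` maps outcome labels to group names (default
    :data:`DEFAULT_OUTCOME_GROUPS`); labels without an entry summarise under
    their own name.  The median of an even count is the midpoint of the two
    central values.
    """
    if not records:
        raise ValueError("no records to summarise")
    grouping = DEFAULT_OUTCOME_GROUPS if grouping is None else dict(grouping)
    buckets: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        group = grouping.get(rec.outcome_label, rec.outcome_label)
        key = (group, rec.level)
        if key not in buckets:
            buckets[key] = []
            order.append(key)
        buckets[key].append(rec.icc)
    out = []
    for group, level in order:
        vals = np.asarray(buckets[(group, level)], dtype=float)
        out.append(
            OutcomeSummary(
                outcome_group=group,
                level=level,
                n_trials=len(vals),
                median_icc=float(np.median(vals)),
                min_icc=float(vals.min()),
                max_icc=float(vals.max()),
            )
        )
    return out


def write_database(records: Sequence[ICCRecord], path: str | Path) -> None:
    """Write records as CSV: 3-dp display columns plus full-precision shadows."""
    rows = []
    for rec in records:
        d = asdict(rec)
        d["icc_full"] = f"{rec.icc:.17g}"
        d["ci_lower_full"] = f"{rec.ci_lower:.17g}"
        d["ci_upper_full"] = f"{rec.ci_upper:.17g}"
        d["mean_or_prop_full"] = f"{rec.mean_or_prop:.17g}"
        d["avg_cluster_size_full"] = f"{rec.avg_cluster_size:.17g}"
        for col in ("icc", "ci_lower", "ci_upper"):
            d[col] = f"{round_half_away(d[col], 3):.3f}"
        d["mean_or_prop"] = f"{round_half_away(d['mean_or_prop'], 2):.2f}"
        d["avg_cluster_size"] = f"{round_half_away(d['avg_cluster_size'], 1):.1f}"
        rows.append(d)
    pd.DataFrame(rows, columns=_DB_COLUMNS).to_csv(path, index=False)


def read_database(path: str | Path) -> list[ICCRecord]:
    """Read a database CSV back into records (full-precision values)."""
    df = pd.read_csv(
        path,
        dtype={"timepoint": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = set(_DB_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ICCRecord(
                    trial=str(row["trial"]),
                    outcome=str(row["outcome"]),
                    timepoint=str(row["timepoint"]),
                    level=str(row["level"]),
                    n=int(row["n"]),
                    mean_or_prop=float(row["mean_or_prop_full"]),
                    icc=float(row["icc_full"]),
                    ci_lower=float(row["ci_lower_full"]),
                    ci_upper=float(row["ci_upper_full"]),
                    ci_method_used=str(row["ci_method_used"]),
                    n_clusters=int(row["n_clusters"]),
                    avg_cluster_size=float(row["avg_cluster_size_full"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i + 2}: {exc}") from exc
    return records


def load_published_estimates() -> list[ICCRecord]:
    """Point estimates of the published surgical-trial ICC database.

    48 outcomes from 10 multicentre trials at centre and (where surgeon
    identifiers existed) surgeon level.  Only the published point estimates,
    Ns and outcome means are carried; CI fields are set to NaN and the CI
    method is marked ``published``.
    """
    with resources.files("surgicc.data").joinpath(
        "published_icc_database.csv"
    ).open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(
            ICCRecord(
                trial=str(row["trial"]),
                outcome=str(row["outcome"]),
                timepoint=str(row["timepoint"]),
                level=str(row["level"]),
                n=int(row["n"]),
                mean_or_prop=float(row["mean_or_prop"]),
                icc=float(row["icc"]),
                ci_lower=float("nan"),
                ci_upper=float("nan"),
                ci_method_used="published",
                n_clusters=0,
                avg_cluster_size=float("nan"),
            )
        )
    return records
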