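"""Count-table normalization and time-course statistics.

The three per-category count tables (human-specific, mouse-specific,
conserved) are analyzed separately. Within each table the pipeline fixes a
strict order: the erythrocyte hemolysis marker miR-451 is removed from the
counts first, then counts are scaled to counts per million (CPM) against
the within-table column totals — so the exclusion changes the CPM of every
remaining miRNA, as intended for a red-blood-cell contaminant.

Replicates of each (compartment, timepoint) condition are averaged on the
CPM scale. Accumulation of tumor-derived signal over time is tested with an
unpaired one-tailed two-sample t-test of each timepoint against the
tumor-free controls; the tested statistic is, by default, the per-sample
number of detected (CPM > 0) human-specific miRNAs, with the per-sample
total CPM available as an alternative. Conserved miRNAs, which pre-exist in
the host, pass a growth-trend filter instead: kept only when mean
expression at the late timepoint strictly exceeds the control mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXCLUDED_PATTERNS = ("miR-451",)


class Compartment(str, Enum):
    TOTAL_PLASMA = "total_plasma"
    SEV = "sev"


TIMEPOINTS = ("control", "day7", "day14", "day23")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    compartment: str
    timepoint: str
    replicate: int

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.compartment not in (c.value for c in Compartment):
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass
class CountMatrix:
    """miRNA x sample integer counts for one origin category."""

    category: str
    values: pd.DataFrame  # rows miRNA, columns sample_id
    meta: dict[str, SampleMeta] = field(default_factory=dict)
    exclusions_applied: bool = False

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.values.columns) - set(self.meta)
        if self.meta and missing:
            raise ValueError(f"columns without metadata: {sorted(missing)}")


@dataclass
class ExpressionMatrix:
    """CPM (or externally normalized) values, same layout as CountMatrix."""

    category: str
    values: pd.DataFrame
    meta: dict[str, SampleMeta] = field(default_factory=dict)


def remove_excluded_mirnas(
    m: CountMatrix, patterns: tuple[str, ...] = EXCLUDED_PATTERNS
) -> CountMatrix:
    """Drop rows whose name contains any pattern (case-insensitive).

    Defaults to miR-451, expressed exclusively by red blood cells and hence
    a hemolysis artifact in plasma counts. Removal is logged by row name.
    """
    if not patterns:
        return replace(m, exclusions_applied=True)
    lowered = [p.lower() for p in patterns]
    drop = [n for n in m.values.index if any(p in n.lower() for p in lowered)]
    if drop:
        logger.info("excluding %d miRNAs: %s", len(drop), ", ".join(sorted(drop)))
    return CountMatrix(
        category=m.category,
        values=m.values.drop(index=drop),
        meta=m.meta,
        exclusions_applied=True,
    )


def cpm_normalize(m: CountMatrix) -> ExpressionMatrix:
    """Counts per million against within-category column totals.

    Requires :func:`remove_excluded_mirnas` to have run first (the
    exclusion must change the library size). A zero-library column becomes
    all zeros with a warning.
    """
    if not m.exclusions_applied:
        raise ValueError(
            "cpm_normalize requires remove_excluded_mirnas first: "
            "excluded miRNAs must not contribute to library sizes"
        )
    libsize = m.values.sum(axis=0)
    zero_cols = libsize[libsize == 0].index
    if len(zero_cols):
        logger.warning("zero library size in columns: %s", list(zero_cols))
    safe = libsize.replace(0, np.nan)
    cpm = m.values.div(safe, axis=1) * 1e6
    cpm[zero_cols] = 0.0
    return ExpressionMatrix(category=m.category, values=cpm, meta=m.meta)


def average_replicates(e: ExpressionMatrix) -> ExpressionMatrix:
    """Mean CPM across replicates per (compartment, timepoint) condition."""
    groups: dict[tuple[str, str], list[str]] = {}
    for sid, sm in e.meta.items():
        if sid in e.values.columns:
            groups.setdefault((sm.compartment, sm.timepoint), []).append(sid)
    cols = {}
    meta = {}
    for (comp, tp), sids in sorted(groups.items()):
        cid = f"{comp}_{tp}"
        cols[cid] = e.values[sids].mean(axis=1)
        meta[cid] = SampleMeta(cid, comp, tp, replicate=0)
    return ExpressionMatrix(category=e.category, values=pd.DataFrame(cols), meta=meta)


def columns_for(e: ExpressionMatrix, compartment: str, timepoint: str) -> list[str]:
    return sorted(
        sid
        for sid, sm in e.meta.items()
        if sm.compartment == compartment
        and sm.timepoint == timepoint
        and sid in e.values.columns
    )


def accumulation_test(
    e: ExpressionMatrix,
    timepoint_cols: list[str],
    control_cols: list[str],
    statistic: str = "n_detected",
) -> float:
    """One-tailed (greater) unpaired t-test of a timepoint vs control.

    ``statistic`` selects the per-sample summary: ``n_detected`` (number of
    miRNAs with CPM > 0, the default) or ``total`` (summed CPM). Returns the
    one-sided p-value; degenerate variance with equal means gives 0.5 by
    the t = 0 convention.
    """
    if len(timepoint_cols) < 2 or len(control_cols) < 2:
        raise ValueError("need >=2 samples per group")

    def summarize(cols: list[str]) -> np.ndarray:
        sub = e.values[cols]
        if statistic == "n_detected":
            return (sub > 0).sum(axis=0).to_numpy(dtype=float)
        if statistic == "total":
            return sub.sum(axis=0).to_numpy(dtype=float)
        raise ValueError(f"unknown statistic {statistic!r}")

    a, b = summarize(timepoint_cols), summarize(control_cols)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.5 if a.mean() == b.mean() else (0.0 if a.mean() > b.mean() else 1.0)
    res = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
    return float(res.pvalue)


def growth_trend_filter(
    e: ExpressionMatrix,
    control_cols: list[str],
    late_cols: list[str],
    min_fold: float = 1.0,
) -> set[str]:
    """Conserved miRNAs upregulated during tumor growth.

    Keeps miRNA i iff mean CPM over ``late_cols`` (day 23 by default usage)
    strictly exceeds ``min_fold`` times the control mean. ``min_fold`` = 1
    is the plain strict increase over control; no multiplicity correction.
    """
    control = e.values[control_cols].mean(axis=1)
    late = e.values[late_cols].mean(axis=1)
    kept = late > control * min_fold
    return set(e.values.index[kept])


def write_matrix_tsv(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index_label="mirna")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_meta_tsv(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "compartment", "timepoint", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = {}
    for _, row in df.iterrows():
        sm = SampleMeta(
            str(row.sample_id), row.compartment, row.timepoint, int(row.replicate)
        )
        if sm.sample_id in meta:
            raise ValueError(f"duplicate sample_id {sm.sample_id}")
        meta[sm.sample_id] = sm
    keys = [(m.compartment, m.timepoint, m.replicate) for m in meta.values()]
    if len(keys) != len(set(keys)):
        raise ValueError("(compartment, timepoint, replicate) not unique")
    return meta


def write_meta_tsv(meta: dict[str, SampleMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcompartment\ttimepoint\treplicate\n")
        for sm in meta.values():
            fh.write(f"{sm.sample_id}\t{sm.compartment}\t{sm.timepoint}\t{sm.replicate}\n")
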