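"""Validation of abundant sEV miRNAs against an external EV microarray set.

The external evidence is a matrix of log2 quantile-normalized probe
intensities for EV miRNAs from melanoma patients and healthy controls
(healthy / primary / metastatic groups). A miRNA counts as "expressed" in a
group when its intensity is strictly above a cutoff (default 5) in at least
half of that group's samples. The abundant xenograft sEV miRNAs are
intersected with the expressed set after canonicalizing names across the
sequencing and array naming schemes. Group differences use a per-miRNA
Welch t-test on the log2 intensities with Benjamini-Hochberg adjustment,
and a progression screen keeps miRNAs whose group medians increase strictly
from healthy to primary to metastatic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUPS = ("healthy", "primary", "metastatic")
_SPECIES_PREFIX = re.compile(r"^(hsa|mmu|rno|ptr|mml)-", re.IGNORECASE)


@dataclass
class ValidationConfig:
    intensity_cutoff: float = 5.0
    sample_fraction: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")


@dataclass
class ExternalProfileSet:
    """Probe-intensity matrix with per-sample clinical group labels."""

    intensities: pd.DataFrame  # rows miRNA, columns sample
    groups: dict[str, str] = field(default_factory=dict)
    platform_note: str = ""

    def __post_init__(self) -> None:
        missing = set(self.intensities.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        if not np.isfinite(self.intensities.to_numpy(dtype=float)).all():
            raise ValueError("non-finite intensities")
        if self.intensities.index.duplicated().any():
            dup = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicated row ids: {sorted(set(dup))}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.intensities.columns if self.groups[s] == group]


def load_profiles(path: str | Path, groups_path: str | Path) -> ExternalProfileSet:
    """Load a series-matrix-style TSV and its sample-group sidecar."""
    intensities = pd.read_csv(path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t")
    if not {"sample_id", "group"} <= set(gdf.columns):
        raise ValueError("groups file needs columns sample_id, group")
    groups = dict(zip(gdf.sample_id.astype(str), gdf.group))
    bad = set(groups.values()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return ExternalProfileSet(intensities=intensities, groups=groups)


def expressed_filter(
    p: ExternalProfileSet, group: str, cfg: ValidationConfig | None = None
) -> set[str]:
    """miRNAs with intensity strictly > cutoff in >= ceil(fraction * n) samples."""
    cfg = cfg or ValidationConfig()
    samples = p.samples_in(group)
    if not samples:
        raise ValueError(f"group {group!r} has no samples")
    need = math.ceil(cfg.sample_fraction * len(samples))
    hits = (p.intensities[samples] > cfg.intensity_cutoff).sum(axis=1)
    return set(p.intensities.index[hits >= need])


def canonical_name(name: str) -> str:
    """Strip species prefix and case-fold; the arm suffix is kept.

    Maps e.g. ``hsa-miR-21-5p`` and the array probe label ``miR-21-5p``
    to the same key.
    """
    return _SPECIES_PREFIX.sub("", name.strip()).lower()


def overlap_validation(
    query: list[str], expressed: set[str]
) -> tuple[int, float, pd.DataFrame]:
    """Overlap of an ordered query list with the expressed set.

    Returns (count, fraction of query, per-name hit table). Canonical-name
    collisions within the query are counted once per query name.
    """
    canon_expressed = {canonical_name(n) for n in expressed}
    rows = [
        {"query": q, "canonical": canonical_name(q), "expressed": canonical_name(q) in canon_expressed}
        for q in query
    ]
    table = pd.DataFrame(rows, columns=["query", "canonical", "expressed"])
    count = int(table.expressed.sum())
    fraction = count / len(query) if query else 0.0
    return count, fraction, table


def differential_expression(
    p: ExternalProfileSet, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-miRNA Welch t on log2 intensities, BH-adjusted over all rows.

    Rows with zero variance in both groups and equal means get p = 1.
    Returns a table (mirna, log2_fold_difference, p, p_adj) sorted by p.
    """
    a_cols, b_cols = p.samples_in(group_a), p.samples_in(group_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >=2 samples per group")
    A = p.intensities[a_cols].to_numpy(dtype=float)
    B = p.intensities[b_cols].to_numpy(dtype=float)
    diff = A.mean(axis=1) - B.mean(axis=1)
    pvals = np.ones(len(diff))
    degenerate = (A.std(axis=1) == 0) & (B.std(axis=1) == 0)
    nontrivial = ~(degenerate & (diff == 0))
    if nontrivial.any():
        res = stats.ttest_ind(
            A[nontrivial], B[nontrivial], axis=1, equal_var=False
        )
        pvals[nontrivial] = np.nan_to_num(res.pvalue, nan=1.0)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "mirna": p.intensities.index,
            "log2_fold_difference": diff,
            "p": pvals,
            "p_adj": p_adj,
        }
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def progression_trend(
    p: ExternalProfileSet, ordered_groups: tuple[str, ...] = GROUPS
) -> set[str]:
    """miRNAs whose group medians increase strictly along ordered_groups.

    No significance requirement: with two primary-stage samples a real
    trend cannot reach significance, so the screen is purely ordinal.
    """
    medians = []
    for g in ordered_groups:
        samples = p.samples_in(g)
        if not samples:
            raise ValueError(f"group {g!r} has no samples")
        medians.append(p.intensities[samples].median(axis=1))
    kept = pd.Series(True, index=p.intensities.index)
    for lo, hi in zip(medians, medians[1:]):
        kept &= hi > lo
    return set(p.intensities.index[kept])
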