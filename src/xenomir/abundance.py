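"""Percentage-abundance profiles, the 2% selection, clustering, correlation.

The abundance of each miRNA within one compartment/category is expressed as
the percentage of the summed expression of that profile; miRNAs above a 2%
threshold are called "abundant" (expression below 2% is taken as not
functionally relevant for a circulating miRNA). Rank-abundance curves are
the sorted percentages; sample structure is explored by hierarchical
clustering on 1 - Pearson correlation of log2(CPM+1) columns with average
linkage, and compartments are compared by Pearson correlation over the
union of their miRNA names (absent = 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 2.0


@dataclass
class AbundanceProfile:
    """Per-miRNA percentage of total expression with 1-based ranks."""

    percent: pd.Series  # name -> percent of summed expression (0..100)
    rank: pd.Series  # name -> 1-based rank by descending percent
    threshold: float = DEFAULT_THRESHOLD
    compartment: str | None = None
    category: str | None = None

    @property
    def above_threshold(self) -> pd.Series:
        return self.percent > self.threshold


def percent_abundance(
    values: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
    compartment: str | None = None,
    category: str | None = None,
) -> AbundanceProfile:
    """Percentage profile of one expression vector (e.g. replicate-mean CPM).

    Ties in rank are broken by miRNA name (lexicographic). All-zero input
    is a hard error — a profile of an unexpressed compartment is undefined.
    """
    total = float(values.sum())
    if total <= 0:
        raise ValueError("all-zero expression vector: percentage profile undefined")
    percent = 100.0 * values / total
    order = percent.to_frame("p").assign(name=percent.index)
    order = order.sort_values(["p", "name"], ascending=[False, True])
    rank = pd.Series(np.arange(1, len(order) + 1), index=order.index, name="rank")
    return AbundanceProfile(
        percent=percent,
        rank=rank.reindex(percent.index),
        threshold=threshold,
        compartment=compartment,
        category=category,
    )


def select_abundant(
    p: AbundanceProfile, threshold: float | None = None
) -> list[str]:
    """Names with percent strictly above the threshold, in rank order."""
    thr = p.threshold if threshold is None else threshold
    kept = p.percent[p.percent > thr]
    return list(kept.index[np.argsort(p.rank.loc[kept.index].to_numpy())])


def rank_abundance_curve(p: AbundanceProfile) -> pd.DataFrame:
    """Plot-ready (rank, percent, name) table, percent non-increasing."""
    df = pd.DataFrame(
        {"rank": p.rank, "percent": p.percent, "name": p.percent.index}
    ).sort_values("rank")
    return df.reset_index(drop=True)


def _correlation_distance(log_values: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson distance between sample columns.

    Constant (zero-variance) columns get correlation 0 with everything,
    with a warning, rather than NaN.
    """
    X = log_values.to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant expression column(s) {list(log_values.columns[constant])}; "
            "their correlations are defined as 0"
        )
    n = X.shape[1]
    corr = np.zeros((n, n))
    ok = ~constant
    if ok.sum() >= 2:
        sub = np.corrcoef(X[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = sub
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0, None)
    return squareform(dist, checks=False)


def hierarchical_cluster(
    values: pd.DataFrame, k: int = 2, log_transform: bool = True
) -> tuple[np.ndarray, pd.Series]:
    """Average-linkage clustering of sample columns.

    Distance is 1 - Pearson correlation on log2(CPM+1). Columns are sorted
    by sample id before linkage so tie handling is deterministic. Returns
    the scipy linkage matrix and flat cluster labels at ``k``.
    """
    if values.shape[1] < 2:
        raise ValueError("need >=2 samples to cluster")
    values = values[sorted(values.columns)]
    logv = np.log2(values + 1) if log_transform else values
    condensed = _correlation_distance(logv)
    Z = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Z, pd.Series(labels, index=values.columns, name="cluster")


def compartment_correlation(a: pd.Series, b: pd.Series) -> float:
    """Pearson r between two expression vectors on log2(CPM+1).

    Vectors are aligned on the union of miRNA names; a miRNA absent from
    one compartment contributes 0 there. Zero variance on either side gives
    NaN with a warning.
    """
    names = sorted(set(a.index) | set(b.index))
    av = np.log2(a.reindex(names).fillna(0).to_numpy(dtype=float) + 1)
    bv = np.log2(b.reindex(names).fillna(0).to_numpy(dtype=float) + 1)
    if av.std() == 0 or bv.std() == 0:
        warnings.warn("zero variance in a compartment vector; correlation undefined")
        return float("nan")
    return float(np.corrcoef(av, bv)[0, 1])


def write_profile_tsv(p: AbundanceProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "percent": p.percent,
            "rank": p.rank,
            "above_threshold": p.above_threshold,
        }
    ).sort_values("rank")
    df.to_csv(path, sep="\t", index_label="name")


def dendrogram_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a newick string with heights."""
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = max(node.dist - node.left.dist, 0.0)
        dr = max(node.dist - node.right.dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"
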