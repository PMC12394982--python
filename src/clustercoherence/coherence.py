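"""Transcriptional coherence of gene sets across stress time-courses.

Coherence of a gene set is the mean pairwise Pearson correlation (PCC) of
its members' expression profiles over the timepoints of one stress
response.  Comparing the coherence of a family's clustered subset with its
singleton subset, stressor by stressor, yields the deviation matrix
(clustered PCC minus singleton PCC) whose sign says whether clustering is
associated with tighter co-expression under that stimulus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import ClusterPartition

logger = logging.getLogger(__name__)

__all__ = [
    "TimeCourse",
    "CoherenceResult",
    "load_timecourse",
    "mean_pairwise_pcc",
    "subset_coherence",
    "coherence_panel",
    "deviation_matrix",
    "unsigned_deviation",
]


@dataclass
class TimeCourse:
    """One stressor's gene x timepoint matrix of log2 relative expression."""

    stressor: str
    values: pd.DataFrame  # genes (rows) x ordered timepoints (columns)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError(f"{self.stressor}: duplicate gene ids")
        if self.values.shape[1] < 3:
            raise ValueError(
                f"{self.stressor}: need >= 3 timepoints for correlation, "
                f"got {self.values.shape[1]}"
            )


def load_timecourse(path: str | Path, stressor: str, provenance: str = "") -> TimeCourse:
    """Read one stressor's TSV: first column gene id, then timepoint columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TimeCourse(stressor=stressor, values=df.astype(float), provenance=provenance)


def mean_pairwise_pcc(
    values: pd.DataFrame, aggregate: str = "mean"
) -> tuple[float, int]:
    """Aggregate pairwise Pearson r over all unordered gene pairs.

    Genes with any missing timepoint (listwise exclusion) or zero variance
    (Pearson undefined) are dropped before correlating; the second return
    value is the number of genes actually used.  With fewer than two usable
    genes the result is NaN — not-applicable, deliberately distinct from a
    coherence of 0.

    ``aggregate`` is ``"mean"`` (default) or ``"median"``.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    complete = values.dropna(axis=0)
    usable = complete[complete.std(axis=1, ddof=0) > 0]
    n_dropped = len(values) - len(usable)
    if n_dropped:
        logger.debug("excluded %d incomplete/flat gene profiles", n_dropped)
    n_used = len(usable)
    if n_used < 2:
        return float("nan"), n_used
    r = np.corrcoef(usable.to_numpy())
    pairs = r[np.triu_indices(n_used, k=1)]
    agg = np.mean if aggregate == "mean" else np.median
    return float(agg(pairs)), n_used


@dataclass
class CoherenceResult:
    """Coherence of one family under one stressor, whole and by subset.

    PCC fields are NaN (not-applicable) when fewer than two usable genes
    remain in the corresponding subset.
    """

    stressor: str
    family: str
    pcc_family: float
    pcc_clustered: float
    pcc_singleton: float
    n_family: int
    n_clustered: int
    n_singleton: int


def subset_coherence(
    tc: TimeCourse, partition: ClusterPartition, aggregate: str = "mean"
) -> CoherenceResult:
    """Coherence of the whole family and its clustered/singleton subsets.

    The clustered subset pools the genes of all of the family's runs.  All
    three PCCs are computed on (subsets of) the same stressor matrix, after
    intersecting partition gene ids with the measured genes.
    """
    genes = set(tc.values.index)
    clustered = sorted(partition.clustered_genes & genes)
    singles = sorted(partition.singletons & genes)
    fam = sorted((partition.clustered_genes | partition.singletons) & genes)
    if not fam:
        logger.warning(
            "family %s: no genes measured under %s",
            partition.family.name,
            tc.stressor,
        )
    pcc_f, n_f = mean_pairwise_pcc(tc.values.loc[fam], aggregate)
    pcc_c, n_c = mean_pairwise_pcc(tc.values.loc[clustered], aggregate)
    pcc_s, n_s = mean_pairwise_pcc(tc.values.loc[singles], aggregate)
    return CoherenceResult(
        stressor=tc.stressor,
        family=partition.family.name,
        pcc_family=pcc_f,
        pcc_clustered=pcc_c,
        pcc_singleton=pcc_s,
        n_family=n_f,
        n_clustered=n_c,
        n_singleton=n_s,
    )


def coherence_panel(
    timecourses: Sequence[TimeCourse],
    partitions: Sequence[ClusterPartition],
    aggregate: str = "mean",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stressor x family matrices of clustered, singleton and family PCCs.

    Rows follow the input stressor order, columns the input family order.
    """
    stressors = [tc.stressor for tc in timecourses]
    families = [p.family.name for p in partitions]
    mats = {
        key: pd.DataFrame(index=stressors, columns=families, dtype=float)
        for key in ("clustered", "singleton", "family")
    }
    for tc in timecourses:
        for part in partitions:
            res = subset_coherence(tc, part, aggregate)
            mats["clustered"].loc[tc.stressor, res.family] = res.pcc_clustered
            mats["singleton"].loc[tc.stressor, res.family] = res.pcc_singleton
            mats["family"].loc[tc.stressor, res.family] = res.pcc_family
    return mats["clustered"], mats["singleton"], mats["family"]


def kmeans_order(matrix: pd.DataFrame, k: int, seed: int = 0, axis: int = 0) -> list:
    """Label order for heatmap display: k-means groups rows (or columns).

    NaN cells are imputed with the matrix mean for grouping only.  Returns
    the row (axis=0) or column (axis=1) labels sorted by cluster label,
    preserving input order within a cluster.
    """
    from sklearn.cluster import KMeans

    X = matrix if axis == 0 else matrix.T
    k = min(k, len(X))
    filled = X.astype(float).fillna(np.nanmean(X.to_numpy(dtype=float)))
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(
        filled.to_numpy()
    )
    order = sorted(range(len(X)), key=lambda i: (labels[i], i))
    return [X.index[i] for i in order]


def deviation_matrix(clustered: pd.DataFrame, singleton: pd.DataFrame) -> pd.DataFrame:
    """Signed deviation: clustered PCC minus singleton PCC, element-wise.

    Positive cells mean the clustered subset is more coherent under that
    stressor.  Not-applicable (NaN) propagates; mismatched labels raise.
    """
    if not clustered.index.equals(singleton.index) or not clustered.columns.equals(
        singleton.columns
    ):
        raise ValueError("clustered and singleton matrices have mismatched labels")
    return clustered - singleton


def unsigned_deviation(clustered: pd.DataFrame, singleton: pd.DataFrame) -> pd.DataFrame:
    """Unsigned distance |clustered - singleton|, as a companion matrix."""
    return deviation_matrix(clustered, singleton).abs()
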