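"""Hypergeometric disruption screen over a deletion-mutant compendium.

Each deletion mutant's expression profile (log2 ratio vs wild type) is
thresholded into a set of *disrupted* genes.  For every (mutant, family)
pair the screen asks whether disruption concentrates in the family's
clustered subset: with N measured genes of which K are disrupted, and a
clustered subset of m measured genes containing x disrupted ones, the tail
probability is

    P = P(X >= x),   X ~ Hypergeometric(N, K, m)

i.e. the chance of seeing at least x disrupted genes in the clustered
subset if the K disruptions were placed at random among the N measured
genes.  For display the p-value is transformed to the deviation score
1 - P (its Euclidean distance from 1.0): scores near 1 flag mutants whose
disruption specifically targets the clustered genes.  The mutant x family
score matrix is grouped by k-means to separate global disruptors,
family-specific disruptors, and mutants with negligible effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from sklearn.cluster import KMeans

from .genome import ClusterPartition

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionCompendium",
    "DisruptionCalls",
    "ScreenCell",
    "ScreenMatrix",
    "load_compendium",
    "call_disrupted",
    "hypergeom_tail",
    "transform_deviation",
    "screen",
    "group_mutants",
]


class ExpressionCompendium:
    """Mutant x gene matrix of log2 expression ratios vs wild type.

    Rows are mutants, columns genes.  Missing measurements are NaN and are
    excluded per-mutant from every downstream count.
    """

    def __init__(self, values: pd.DataFrame) -> None:
        if values.index.duplicated().any():
            raise ValueError("duplicate mutant ids")
        if values.columns.duplicated().any():
            raise ValueError("duplicate gene ids")
        vals = values.astype(float)
        if np.isinf(vals.to_numpy()).any():
            raise ValueError("compendium contains non-finite (inf) values")
        self.values = vals

    @property
    def mutants(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


def load_compendium(path: str | Path) -> ExpressionCompendium:
    """Read a compendium TSV: first column gene id, remaining columns mutants.

    Empty cells are missing.  The GCT dialect (``#1.2`` header, dimensions
    line, Name/Description columns) is accepted too.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        df = df.drop(columns=[c for c in ("Description",) if c in df.columns])
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionCompendium(df.T)


@dataclass
class DisruptionCalls:
    """Disrupted-gene set for one mutant at a |log2 ratio| threshold."""

    mutant: str
    disrupted: frozenset[str]
    threshold: float
    n_measured: int  # N: genes with a non-missing value for this mutant

    @property
    def K(self) -> int:
        return len(self.disrupted)


def call_disrupted(
    compendium: ExpressionCompendium,
    mutant: str,
    threshold: float = 1.0,
    top_fraction: float | None = None,
) -> DisruptionCalls:
    """Call disrupted genes for one mutant.

    Default rule: |log2 ratio| >= ``threshold`` (2-fold at the default 1.0).
    If ``top_fraction`` is given, the top that fraction of measured genes by
    |ratio| is called instead — useful when the compendium's scale is
    uncertain.  Missing values are excluded from both N and the calls.
    """
    if mutant not in compendium.values.index:
        raise KeyError(f"unknown mutant: {mutant!r}")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    row = compendium.values.loc[mutant]
    measured = row.dropna()
    if len(measured) == 0:
        logger.warning("mutant %s: no measured genes", mutant)
        return DisruptionCalls(mutant, frozenset(), threshold, 0)
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        k = int(round(top_fraction * len(measured)))
        hit = measured.abs().nlargest(k).index
    else:
        hit = measured.index[measured.abs() >= threshold]
    return DisruptionCalls(mutant, frozenset(hit), threshold, len(measured))


# ---------------------------------------------------------------------------
# Hypergeometric tail
# ---------------------------------------------------------------------------

def _log_comb(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(N: int, K: int, m: int, x: int, tail: str = "upper") -> float:
    """Tail probability of the hypergeometric count in the clustered subset.

    Upper tail (default): ``P(X >= x)`` with ``X ~ Hypergeometric(population
    N, successes K, draws m)``; lower tail: ``P(X <= x)``.  Computed by
    summing probability terms in log space (stable for N up to ~1e5);
    exactly 1.0 for x = 0 on the upper tail.  Invalid argument order raises
    — arguments are never silently clamped.
    """
    for name, v in (("N", N), ("K", K), ("m", m), ("x", x)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if not (x <= m <= N):
        raise ValueError(f"need 0 <= x <= m <= N, got x={x}, m={m}, N={N}")
    if K > N:
        raise ValueError(f"need K <= N, got K={K}, N={N}")
    if tail not in ("upper", "lower"):
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")

    lo = max(0, m - (N - K))  # smallest achievable x
    hi = min(K, m)            # largest achievable x
    if tail == "upper":
        if x <= lo:
            return 1.0
        if x > hi:
            return 0.0
        j = np.arange(x, hi + 1)
    else:
        if x >= hi:
            return 1.0
        if x < lo:
            return 0.0
        j = np.arange(lo, x + 1)
    log_terms = _log_comb(K, j) + _log_comb(N - K, m - j) - _log_comb(N, m)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def transform_deviation(P: float | np.ndarray) -> float | np.ndarray:
    """Deviation score: the (scalar Euclidean) distance of P from 1.0.

    ``score = 1 - P``; monotone decreasing in P, so significant cells map
    near 1 for heatmap display.
    """
    arr = np.asarray(P, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("P must lie in [0, 1]")
    out = 1.0 - arr
    return float(out) if np.isscalar(P) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenCell:
    """One (mutant, family) cell of the screen with its counts and p-value.

    N: measured genes for the mutant; K: disrupted among them; n: family
    members measured; m: clustered-subset members measured; x: disrupted
    genes inside the clustered subset; P: hypergeometric tail; score: 1 - P.
    """

    mutant: str
    family: str
    N: int
    K: int
    n: int
    m: int
    x: int
    P: float
    score: float
    applicable: bool = True


class ScreenMatrix:
    """Mutant x family grid of screen cells plus optional k-means groups."""

    def __init__(self, cells: list[ScreenCell]) -> None:
        self.cells = cells
        long = pd.DataFrame([vars(c) for c in cells])
        self.table = long
        piv = long.pivot(index="mutant", columns="family")
        self.pvalues = piv["P"].where(piv["applicable"])
        self.scores = piv["score"].where(piv["applicable"])
        self.mutant_groups: pd.Series | None = None
        self.k_groups: int | None = None
        self.inertia: float | None = None

    def cell_table(self) -> pd.DataFrame:
        """Long-format table with a Benjamini-Hochberg column (extension)."""
        df = self.table.copy()
        mask = df["applicable"].to_numpy()
        q = np.full(len(df), np.nan)
        q[mask] = _benjamini_hochberg(df.loc[mask, "P"].to_numpy())
        df["q_bh"] = q
        return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def screen(
    compendium: ExpressionCompendium,
    partitions: Sequence[ClusterPartition],
    threshold: float = 1.0,
    tail: str = "upper",
    top_fraction: float | None = None,
) -> ScreenMatrix:
    """Score every (mutant, family) pair for cluster-specific disruption.

    All counts (N, K, n, m, x) are recomputed per mutant on the measured-gene
    intersection, so missing values never leak between cells.  Families whose
    clustered subset has no measured gene for a mutant yield a not-applicable
    cell, excluded from grouping.
    """
    gene_set = set(compendium.genes)
    for part in partitions:
        missing = (part.clustered_genes | part.singletons) - gene_set
        if missing:
            logger.info(
                "family %s: %d gene(s) absent from compendium",
                part.family.name,
                len(missing),
            )
    cells: list[ScreenCell] = []
    for mutant in compendium.mutants:
        calls = call_disrupted(compendium, mutant, threshold, top_fraction)
        row = compendium.values.loc[mutant]
        measured = set(row.dropna().index)
        N, K = calls.n_measured, calls.K
        for part in partitions:
            fam_measured = (part.clustered_genes | part.singletons) & measured
            clust_measured = part.clustered_genes & measured
            n, m = len(fam_measured), len(clust_measured)
            x = len(clust_measured & calls.disrupted)
            if m == 0 or N == 0:
                cells.append(
                    ScreenCell(
                        mutant, part.family.name, N, K, n, m, x,
                        P=np.nan, score=np.nan, applicable=False,
                    )
                )
                continue
            P = hypergeom_tail(N, K, m, x, tail=tail)
            cells.append(
                ScreenCell(
                    mutant, part.family.name, N, K, n, m, x,
                    P=P, score=transform_deviation(P),
                )
            )
    return ScreenMatrix(cells)


def group_mutants(matrix: ScreenMatrix, k: int = 3, seed: int = 0) -> ScreenMatrix:
    """k-means on the score rows; labels stored on the matrix in place.

    Not-applicable cells are imputed as score 0 (no evidence of disruption).
    Rows are not re-scaled: scores already lie in [0, 1].  Ten restarts with
    a fixed seed make the labels reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = matrix.scores.fillna(0.0)
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} mutants available")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X.to_numpy())
    matrix.mutant_groups = pd.Series(labels, index=X.index, name="group")
    matrix.k_groups = k
    matrix.inertia = float(km.inertia_)
    return matrix
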