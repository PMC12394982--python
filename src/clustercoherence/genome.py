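"""Gene coordinates, family membership, and functional-cluster detection.

A *functional gene cluster* is a run of two or more members of the same gene
family lying adjacent (or near-adjacent) along a chromosome.  Adjacency is
measured by chromosome rank — the per-chromosome ordering of genes by start
coordinate — so the cluster definition is insensitive to intergenic distance
unless an explicit base-pair gap limit is requested.  Family members that do
not fall in any run are *singletons*.  Whether a family clusters more than
chance expects is assessed by a relabelling permutation test that keeps the
gene map fixed and redraws the family membership uniformly at random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationError",
    "ParseError",
    "GenomeAnnotation",
    "GeneFamily",
    "ClusterPartition",
    "ClusterSignificance",
    "load_annotation",
    "load_gmt",
    "detect_clusters",
    "clustering_significance",
    "select_clustered_families",
]


class AnnotationError(ValueError):
    """Invalid gene annotation (duplicate ids, bad coordinates, ...)."""


class ParseError(AnnotationError):
    """A malformed line in an input file; message names the line number."""


class GenomeAnnotation:
    """Ordered gene coordinates: the frame on which clusters are detected.

    Parameters
    ----------
    genes
        Iterable of ``(gene_id, chromosome, start, end, strand)`` tuples.
        Coordinates follow the BED convention (0-based, half-open).

    Genes are sorted per chromosome by start coordinate and assigned a rank
    index; ranks on each chromosome are a bijection onto ``0..n_chrom-1``.
    """

    def __init__(self, genes: Iterable[tuple]) -> None:
        rows = list(genes)
        df = pd.DataFrame(
            rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
        )
        if len(df) == 0:
            logger.warning("empty annotation")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise AnnotationError(f"duplicate gene_id: {dup!r}")
        bad = df[df["start"] >= df["end"]] if len(df) else df
        if len(bad):
            g = bad.iloc[0]
            raise AnnotationError(
                f"gene {g.gene_id!r}: start {g.start} >= end {g.end}"
            )
        df = df.sort_values(
            ["chromosome", "start", "end", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        df["rank"] = df.groupby("chromosome").cumcount()
        self._df = df.set_index("gene_id", drop=False)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._df.index

    @property
    def gene_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self._df["chromosome"]))

    @property
    def frame(self) -> pd.DataFrame:
        """Annotation as a DataFrame (gene_id, chromosome, start, end, strand, rank)."""
        return self._df.copy()

    def rank_of(self, gene_id: str) -> tuple[str, int]:
        """Return ``(chromosome, rank)`` for a gene."""
        row = self._df.loc[gene_id]
        return row["chromosome"], int(row["rank"])

    def genes_on(self, chromosome: str) -> list[str]:
        """Gene ids on one chromosome, in rank order."""
        sub = self._df[self._df["chromosome"] == chromosome]
        return list(sub.sort_values("rank")["gene_id"])


@dataclass(frozen=True)
class GeneFamily:
    """A named functional gene family (e.g. a GO Slim descriptor)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class ClusterPartition:
    """A family split into clustered runs, singletons, and unplaced ids.

    ``clusters`` holds gene-id runs in chromosomal order, each of length >= 2;
    ``singletons`` are annotated members in no run; ``unplaced`` are members
    absent from the annotation (reported, never silently dropped).
    """

    family: GeneFamily
    clusters: list[list[str]]
    singletons: set[str]
    unplaced: set[str]
    max_intervening: int = 0
    max_gap_bp: int | None = None

    @property
    def clustered_genes(self) -> set[str]:
        """Union of all runs: the family's clustered subset."""
        return {g for run in self.clusters for g in run}

    @property
    def n_clustered(self) -> int:
        return sum(len(run) for run in self.clusters)

    def to_frame(self, annotation: GenomeAnnotation | None = None) -> pd.DataFrame:
        """Long-format table: family, gene, chromosome, subset, cluster_index."""
        rows = []
        for i, run in enumerate(self.clusters):
            for g in run:
                rows.append((self.family.name, g, "cluster", i))
        for g in sorted(self.singletons):
            rows.append((self.family.name, g, "singleton", -1))
        for g in sorted(self.unplaced):
            rows.append((self.family.name, g, "unplaced", -1))
        df = pd.DataFrame(rows, columns=["family", "gene", "subset", "cluster_index"])
        if annotation is not None:
            chrom = [
                annotation.rank_of(g)[0] if g in annotation else ""
                for g in df["gene"]
            ]
            df.insert(2, "chromosome", chrom)
        return df


@dataclass
class ClusterSignificance:
    """Permutation-test result for one family's genomic clustering.

    ``p_value`` uses the pseudo-count estimator
    ``(1 + #{null >= observed}) / (1 + n_permutations)`` and therefore lies
    in (0, 1].
    """

    family_name: str
    observed_clustered_count: int
    null_counts: np.ndarray
    n_permutations: int
    seed: int

    @property
    def p_value(self) -> float:
        ge = int(np.sum(self.null_counts >= self.observed_clustered_count))
        return (1 + ge) / (1 + self.n_permutations)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def load_annotation(path: str | Path) -> GenomeAnnotation:
    """Read a BED-like file (>= 4 tab-separated columns) into an annotation.

    Columns: chrom, start, end, name, [score], [strand].  Lines beginning
    with ``#``, ``track`` or ``browser`` and blank lines are skipped.
    Coordinates are 0-based half-open; start must be < end.  Duplicate gene
    ids raise :class:`AnnotationError`; malformed lines raise
    :class:`ParseError` naming the line number.
    """
    path = Path(path)
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path.name}:{lineno}: expected >= 4 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer coordinate"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            genes.append((name, chrom, start, end, strand))
    return GenomeAnnotation(genes)


def load_gmt(path: str | Path) -> list[GeneFamily]:
    """Read gene families from a GMT file (name, description, members...)."""
    families = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{Path(path).name}:{lineno}: GMT line needs name, "
                    "description and >= 1 member"
                )
            families.append(
                GeneFamily(
                    name=fields[0],
                    members=frozenset(f for f in fields[2:] if f),
                    description=fields[1],
                )
            )
    return families


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------

def detect_clusters(
    annotation: GenomeAnnotation,
    family: GeneFamily,
    max_intervening: int = 0,
    max_gap_bp: int | None = None,
) -> ClusterPartition:
    """Partition a family into maximal clustered runs and singletons.

    Consecutive family members on one chromosome join the same run when they
    are separated by at most ``max_intervening`` non-family genes (by rank)
    and, if ``max_gap_bp`` is given, by at most that many base pairs between
    the end of one gene and the start of the next.  Runs of length >= 2 are
    clusters; remaining annotated members are singletons.  Members absent
    from the annotation are reported as unplaced.

    The chain condition is pairwise, so a single left-to-right sweep yields
    the maximal runs; the result is deterministic and independent of input
    file ordering.
    """
    if len(annotation) == 0:
        raise AnnotationError("annotation is empty")
    placed = [g for g in family.members if g in annotation]
    unplaced = set(family.members) - set(placed)
    if unplaced:
        logger.warning(
            "family %s: %d member(s) not in annotation", family.name, len(unplaced)
        )

    df = annotation.frame
    sub = df.loc[placed].sort_values(["chromosome", "rank"])
    clusters: list[list[str]] = []
    singletons: set[str] = set()
    for _, grp in sub.groupby("chromosome", sort=True):
        run: list[pd.Series] = []
        for _, gene in grp.iterrows():
            if run:
                prev = run[-1]
                rank_gap = gene["rank"] - prev["rank"] - 1
                bp_gap = gene["start"] - prev["end"]
                joined = rank_gap <= max_intervening and (
                    max_gap_bp is None or bp_gap <= max_gap_bp
                )
            else:
                joined = False
            if joined:
                run.append(gene)
            else:
                _close_run(run, clusters, singletons)
                run = [gene]
        _close_run(run, clusters, singletons)

    return ClusterPartition(
        family=family,
        clusters=clusters,
        singletons=singletons,
        unplaced=unplaced,
        max_intervening=max_intervening,
        max_gap_bp=max_gap_bp,
    )


def _close_run(run, clusters, singletons) -> None:
    if len(run) >= 2:
        clusters.append([g["gene_id"] for g in run])
    elif len(run) == 1:
        singletons.add(run[0]["gene_id"])


def clustering_significance(
    annotation: GenomeAnnotation,
    family: GeneFamily,
    max_intervening: int = 0,
    max_gap_bp: int | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ClusterSignificance:
    """Permutation test: is the family's clustered gene count non-random?

    The null relabels genes — family membership is reassigned to a uniform
    random subset of annotated genes of the same size, keeping the gene map
    fixed — and clusters are re-detected per permutation.  The statistic is
    the number of family genes inside runs.  The p-value uses a pseudo-count
    so it is never exactly zero.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if len(family.members) > len(annotation):
        raise AnnotationError(
            f"family {family.name!r} larger than the annotated genome"
        )
    placed = [g for g in family.members if g in annotation]
    size = len(placed)
    observed = detect_clusters(
        annotation, family, max_intervening, max_gap_bp
    ).n_clustered

    # Work on rank/coordinate arrays: re-running the full detector per
    # permutation would redo the pandas bookkeeping thousands of times.
    df = annotation.frame.sort_values(["chromosome", "rank"])
    chrom_codes = pd.factorize(df["chromosome"])[0]
    ranks = df["rank"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    n = len(df)

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        null_counts[i] = _count_clustered(
            idx, chrom_codes, ranks, starts, ends, max_intervening, max_gap_bp
        )
    return ClusterSignificance(
        family_name=family.name,
        observed_clustered_count=observed,
        null_counts=null_counts,
        n_permutations=n_permutations,
        seed=seed,
    )


def _count_clustered(
    idx: np.ndarray,
    chrom_codes: np.ndarray,
    ranks: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    max_intervening: int,
    max_gap_bp: int | None,
) -> int:
    """Clustered-gene count for a membership given as sorted positional indices."""
    if len(idx) < 2:
        return 0
    same_chrom = chrom_codes[idx[1:]] == chrom_codes[idx[:-1]]
    rank_ok = (ranks[idx[1:]] - ranks[idx[:-1]] - 1) <= max_intervening
    joined = same_chrom & rank_ok
    if max_gap_bp is not None:
        joined &= (starts[idx[1:]] - ends[idx[:-1]]) <= max_gap_bp
    # Genes in runs of length >= 2: count members with a joined edge on
    # either side.
    in_run = np.zeros(len(idx), dtype=bool)
    in_run[1:] |= joined
    in_run[:-1] |= joined
    return int(in_run.sum())


def partitions_from_table(df: pd.DataFrame) -> list[ClusterPartition]:
    """Rebuild partitions from the long-format TSV written by ``to_frame``."""
    needed = {"family", "gene", "subset", "cluster_index"}
    if not needed <= set(df.columns):
        raise ParseError(
            f"partition table missing column(s): {', '.join(sorted(needed - set(df.columns)))}"
        )
    parts = []
    for name, grp in df.groupby("family", sort=False):
        clusters = [
            list(run["gene"])
            for _, run in grp[grp["subset"] == "cluster"].groupby("cluster_index")
        ]
        singletons = set(grp.loc[grp["subset"] == "singleton", "gene"])
        unplaced = set(grp.loc[grp["subset"] == "unplaced", "gene"])
        fam = GeneFamily(name=str(name), members=frozenset(grp["gene"]))
        parts.append(
            ClusterPartition(
                family=fam, clusters=clusters, singletons=singletons, unplaced=unplaced
            )
        )
    return parts


def select_clustered_families(
    results: Sequence[ClusterSignificance], alpha: float = 0.05
) -> list[str]:
    """Family names with permutation p-value <= alpha, in stable input order."""
    return [r.family_name for r in results if r.p_value <= alpha]
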