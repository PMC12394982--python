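"""Synthetic genomes, compendia, time-courses and Ct tables with planted truth.

The generator emulates the statistical structure the analysis assumes:

* a genome whose gene families are partly arranged in adjacent clusters and
  partly scattered as singletons (no accidental adjacency within a family);
* a deletion-mutant compendium of log2 ratios where selected mutants add a
  +/-effect shift to the clustered (or singleton) subset of selected
  families on top of Gaussian measurement noise;
* stress time-courses where the genes of one cluster share a latent
  response — gene profile = sqrt(rho)*latent + sqrt(1-rho)*noise — so the
  mean pairwise Pearson correlation within a cluster recovers rho;
* qPCR Ct tables consistent with given log2 fold changes.

Every artifact is byte-reproducible from (config, seed), and the realized
planted effects are serialized as a :class:`SyntheticTruth` sufficient to
recompute the expected screen and coherence outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coherence import TimeCourse
from .genome import ClusterPartition, GeneFamily, GenomeAnnotation
from .screen import ExpressionCompendium

__all__ = [
    "FamilySpec",
    "PlantedDisruption",
    "TimecourseConfig",
    "SimulationConfig",
    "SyntheticTruth",
    "default_config",
    "simulate_genome",
    "simulate_compendium",
    "simulate_timecourses",
    "simulate_ct_table",
    "write_bed",
    "write_gmt",
    "write_compendium",
    "write_timecourse",
]

# Fourteen stress and nutritional stimuli: nine osmotic/redox/heat shifts
# plus five environmental and nutritional responses, mirroring the standard
# yeast stress-response panels.
DEFAULT_STRESSORS = [
    "menadione_2.5mM",
    "menadione_1mM",
    "dtt_2.5mM",
    "hyperosmotic_1M_sorbitol",
    "hypoosmotic_from_1M_sorbitol",
    "diamide_1.5mM",
    "heat_29_to_33",
    "heat_30_to_37",
    "heat_25_to_37",
    "heat_37",
    "h2o2_0.3mM",
    "mms_0.02pct",
    "nitrogen_starvation",
    "glucose_to_glycerol",
]


@dataclass(frozen=True)
class FamilySpec:
    """Size and planted cluster layout of one synthetic gene family."""

    name: str
    size: int
    cluster_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if any(c < 2 for c in self.cluster_sizes):
            raise ValueError(f"{self.name}: cluster sizes must be >= 2")
        if sum(self.cluster_sizes) > self.size:
            raise ValueError(f"{self.name}: clusters exceed family size")


@dataclass(frozen=True)
class PlantedDisruption:
    """One mutant's planted effect on one family's target subset."""

    mutant: str
    family: str
    target: str = "clustered"  # clustered | singleton | both
    effect: float = 2.0  # |log2| magnitude added to target genes
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if self.target not in ("clustered", "singleton", "both"):
            raise ValueError(f"bad target {self.target!r}")
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must be in [0, 1]")


@dataclass(frozen=True)
class TimecourseConfig:
    """Latent-factor time-course parameters."""

    n_timepoints: int = 8
    rho_cluster: float = 0.7
    rho_singleton: float = 0.0
    stressors: tuple[str, ...] = tuple(DEFAULT_STRESSORS)

    def __post_init__(self) -> None:
        if self.n_timepoints < 3:
            raise ValueError("need >= 3 timepoints")
        for r in (self.rho_cluster, self.rho_singleton):
            if not -1 <= r <= 1:
                raise ValueError("rho values must lie in [-1, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic study.

    Defaults mirror the study scale — 165 mutants, 38 families, 14
    stressors on a ~6000-gene, 16-chromosome genome — and every field can
    be overridden for small, fast runs.
    """

    n_genes: int = 6000
    n_chromosomes: int = 16
    families: tuple[FamilySpec, ...] = ()
    n_mutants: int = 165
    planted_disruptions: tuple[PlantedDisruption, ...] = ()
    noise_sd: float = 0.25  # log2 units
    background_disruption_rate: float = 0.0
    background_effect: float = 2.0
    timecourse: TimecourseConfig = field(default_factory=TimecourseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_disruption_rate <= 1:
            raise ValueError("background_disruption_rate must be in [0, 1]")
        total_family = sum(f.size for f in self.families)
        if total_family > self.n_genes:
            raise ValueError("families exceed the genome size")


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-scale config: 38 families with planted clusters, 165 mutants."""
    sizes = [20, 30, 43, 50]
    layouts: list[tuple[int, ...]] = [(3,), (2, 2), (2,), (3, 2)]
    fams = tuple(
        FamilySpec(
            name=f"family{i:02d}",
            size=sizes[i % len(sizes)],
            cluster_sizes=layouts[i % len(layouts)],
        )
        for i in range(38)
    )
    planted = tuple(
        PlantedDisruption(mutant=f"mut{i:03d}", family=f"family{i % 38:02d}")
        for i in range(10)
    )
    return SimulationConfig(families=fams, planted_disruptions=planted, seed=seed)


@dataclass
class SyntheticTruth:
    """The planted effects and latent structure actually drawn."""

    seed: int
    placements: dict = field(default_factory=dict)
    # family -> {"clusters": [[gene ids]], "singletons": [gene ids]}
    disruptions: list = field(default_factory=list)
    # records {"mutant","family","gene","effect"} (signed)
    n_background: int = 0
    background_rate: float = 0.0
    rho_cluster: float | None = None
    rho_singleton: float | None = None
    stressors: list = field(default_factory=list)

    def clustered_genes(self, family: str) -> list[str]:
        return [g for run in self.placements[family]["clusters"] for g in run]

    def singleton_genes(self, family: str) -> list[str]:
        return list(self.placements[family]["singletons"])

    def planted_pairs(self) -> set[tuple[str, str]]:
        """(mutant, family) pairs carrying a planted disruption."""
        return {(d["mutant"], d["family"]) for d in self.disruptions}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

_GENE_LEN = 1500
_GENE_PITCH = 2000  # start-to-start spacing, leaves a 500 bp gap


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, list[GeneFamily], SyntheticTruth]:
    """Draw a genome with families partly arranged in planted clusters.

    Cluster runs occupy adjacent rank windows at uniform random
    non-overlapping positions; remaining members are singletons placed so
    that no two placements of the same family are rank-adjacent (planted
    singletons can never accidentally extend a cluster).  Raises if a
    placement cannot be found after bounded retries.
    """
    rng = np.random.default_rng([config.seed, 1])
    per_chrom = _split_evenly(config.n_genes, config.n_chromosomes)
    chrom_of: list[int] = []
    pos_of: list[int] = []
    for c, n in enumerate(per_chrom):
        chrom_of.extend([c] * n)
        pos_of.extend(range(n))
    genes = [
        (
            f"g{i:05d}",
            f"chr{chrom_of[i] + 1:02d}",
            pos_of[i] * _GENE_PITCH,
            pos_of[i] * _GENE_PITCH + _GENE_LEN,
            "+" if rng.random() < 0.5 else "-",
        )
        for i in range(config.n_genes)
    ]
    annotation = GenomeAnnotation(genes)
    gene_ids = [g[0] for g in genes]

    chrom_offsets = np.cumsum([0] + per_chrom[:-1])
    occupied: set[int] = set()  # global indices claimed by any family
    truth = SyntheticTruth(seed=config.seed)
    families: list[GeneFamily] = []
    for spec in config.families:
        blocked: set[int] = set()  # indices adjacent to this family's genes
        runs: list[list[str]] = []
        fam_ids: list[str] = []
        for csize in spec.cluster_sizes:
            window = _place_window(
                rng, per_chrom, chrom_offsets, csize, occupied, blocked
            )
            run = [gene_ids[i] for i in window]
            runs.append(run)
            fam_ids.extend(run)
            _claim(window, per_chrom, chrom_offsets, occupied, blocked)
        singles: list[str] = []
        for _ in range(spec.size - sum(spec.cluster_sizes)):
            window = _place_window(rng, per_chrom, chrom_offsets, 1, occupied, blocked)
            singles.append(gene_ids[window[0]])
            fam_ids.append(gene_ids[window[0]])
            _claim(window, per_chrom, chrom_offsets, occupied, blocked)
        families.append(GeneFamily(name=spec.name, members=frozenset(fam_ids)))
        truth.placements[spec.name] = {"clusters": runs, "singletons": singles}
    return annotation, families, truth


def _split_evenly(n: int, parts: int) -> list[int]:
    base, extra = divmod(n, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _place_window(
    rng: np.random.Generator,
    per_chrom: list[int],
    chrom_offsets: np.ndarray,
    width: int,
    occupied: set[int],
    blocked: set[int],
    max_tries: int = 2000,
) -> list[int]:
    weights = np.array(per_chrom, dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        c = int(rng.choice(len(per_chrom), p=weights))
        if per_chrom[c] < width:
            continue
        start = int(rng.integers(0, per_chrom[c] - width + 1))
        window = [int(chrom_offsets[c]) + start + j for j in range(width)]
        if any(i in occupied or i in blocked for i in window):
            continue
        return window
    raise RuntimeError(
        "could not place a family member after bounded retries; "
        "use a larger genome or fewer/smaller families"
    )


def _claim(
    window: list[int],
    per_chrom: list[int],
    chrom_offsets: np.ndarray,
    occupied: set[int],
    blocked: set[int],
) -> None:
    occupied.update(window)
    # Block the rank-neighbours on the same chromosome for this family.
    c = int(np.searchsorted(chrom_offsets, window[0], side="right") - 1)
    lo, hi = int(chrom_offsets[c]), int(chrom_offsets[c]) + per_chrom[c] - 1
    if window[0] - 1 >= lo:
        blocked.add(window[0] - 1)
    if window[-1] + 1 <= hi:
        blocked.add(window[-1] + 1)


# ---------------------------------------------------------------------------
# Compendium
# ---------------------------------------------------------------------------

def simulate_compendium(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> ExpressionCompendium:
    """Draw the mutant x gene log2-ratio matrix with planted disruptions.

    Baseline values are Normal(0, noise_sd).  Each planted (mutant, family)
    effect adds +/-effect to its target-subset genes with the configured
    penetrance (sign drawn per gene and recorded in the truth).  A uniform
    background disruption of the same form is applied at
    ``background_disruption_rate`` for realism; the truth keeps its count.
    """
    rng = np.random.default_rng([config.seed, 2])
    gene_ids = annotation.gene_ids
    mutants = [f"mut{i:03d}" for i in range(config.n_mutants)]
    values = rng.normal(0.0, config.noise_sd, size=(config.n_mutants, len(gene_ids)))
    col_of = {g: j for j, g in enumerate(gene_ids)}
    row_of = {m: i for i, m in enumerate(mutants)}

    for d in config.planted_disruptions:
        if d.mutant not in row_of:
            raise ValueError(f"planted mutant {d.mutant!r} outside n_mutants")
        if d.family not in truth.placements:
            raise ValueError(f"planted family {d.family!r} not in the genome truth")
        targets: list[str] = []
        if d.target in ("clustered", "both"):
            targets += truth.clustered_genes(d.family)
        if d.target in ("singleton", "both"):
            targets += truth.singleton_genes(d.family)
        for g in targets:
            if rng.random() >= d.penetrance:
                continue
            sign = 1.0 if rng.random() < 0.5 else -1.0
            values[row_of[d.mutant], col_of[g]] += sign * d.effect
            truth.disruptions.append(
                {"mutant": d.mutant, "family": d.family, "gene": g,
                 "effect": sign * d.effect}
            )
    if config.background_disruption_rate > 0:
        mask = rng.random(values.shape) < config.background_disruption_rate
        signs = np.where(rng.random(values.shape) < 0.5, 1.0, -1.0)
        values += mask * signs * config.background_effect
        truth.n_background = int(mask.sum())
    truth.background_rate = config.background_disruption_rate
    return ExpressionCompendium(
        pd.DataFrame(values, index=mutants, columns=gene_ids)
    )


# ---------------------------------------------------------------------------
# Time-courses
# ---------------------------------------------------------------------------

def simulate_timecourses(
    partitions: Sequence[ClusterPartition],
    truth: SyntheticTruth,
    config: SimulationConfig,
    gene_ids: Sequence[str] | None = None,
) -> list[TimeCourse]:
    """Draw per-stressor latent-factor time-courses.

    One latent factor is drawn per (stressor, cluster): each clustered gene
    is sqrt(rho_cluster)*latent + sqrt(1-rho_cluster)*noise.  A family's
    singletons analogously share a per-(stressor, family) latent at
    rho_singleton.  All other genes are iid standard normal per timepoint.
    ``gene_ids`` defaults to the union of partition genes.
    """
    tc_cfg = config.timecourse
    rng = np.random.default_rng([config.seed, 3])
    if gene_ids is None:
        ids: list[str] = []
        for p in partitions:
            ids.extend(sorted(p.clustered_genes | p.singletons))
        gene_ids = ids
    cols = [f"t{j}" for j in range(tc_cfg.n_timepoints)]
    rc, rs = tc_cfg.rho_cluster, tc_cfg.rho_singleton
    out: list[TimeCourse] = []
    for stressor in tc_cfg.stressors:
        mat = pd.DataFrame(
            rng.standard_normal((len(gene_ids), tc_cfg.n_timepoints)),
            index=list(gene_ids),
            columns=cols,
        )
        for part in partitions:
            for run in part.clusters:
                latent = rng.standard_normal(tc_cfg.n_timepoints)
                for g in run:
                    if g not in mat.index:
                        continue
                    noise = rng.standard_normal(tc_cfg.n_timepoints)
                    mat.loc[g] = np.sqrt(rc) * latent + np.sqrt(1 - rc) * noise
            latent_s = rng.standard_normal(tc_cfg.n_timepoints)
            for g in sorted(part.singletons):
                if g not in mat.index:
                    continue
                noise = rng.standard_normal(tc_cfg.n_timepoints)
                mat.loc[g] = np.sqrt(rs) * latent_s + np.sqrt(1 - rs) * noise
        out.append(TimeCourse(stressor=stressor, values=mat, provenance="synthetic"))
    truth.rho_cluster = rc
    truth.rho_singleton = rs
    truth.stressors = list(tc_cfg.stressors)
    return out


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(
    log2_folds: dict[str, float],
    reference_gene: str = "ACT1",
    test: str = "mutant",
    control: str = "WT",
    n_replicates: int = 3,
    base_ct: float = 20.0,
    ct_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a long-format Ct table consistent with given log2 fold changes.

    The target gene's test-condition Ct is shifted by -log2_fold relative to
    control (one extra doubling of template removes one cycle); the
    reference gene is constant across conditions.  Replicate noise is
    Normal(0, ct_sd).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, lf in list(log2_folds.items()) + [(reference_gene, 0.0)]:
        for sample, shift in ((control, 0.0), (test, -lf)):
            for rep in range(n_replicates):
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "replicate": rep,
                        "ct": base_ct + shift + rng.normal(0.0, ct_sd),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers (the exact formats the other modules read)
# ---------------------------------------------------------------------------

def write_bed(annotation: GenomeAnnotation, path: str | Path) -> None:
    df = annotation.frame.sort_values(["chromosome", "start"])
    with open(path, "w") as fh:
        for _, g in df.iterrows():
            fh.write(
                f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def write_gmt(families: Sequence[GeneFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fam in families:
            members = "\t".join(sorted(fam.members))
            fh.write(f"{fam.name}\t{fam.description or 'synthetic'}\t{members}\n")


def write_compendium(comp: ExpressionCompendium, path: str | Path) -> None:
    # Genes as rows, mutants as columns (the on-disk orientation).
    df = comp.values.T
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g", na_rep="")


def write_timecourse(tc: TimeCourse, path: str | Path) -> None:
    df = tc.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g", na_rep="")
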