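"""Calibration and recovery studies on synthetic data with planted truth.

These are the package's standing validation experiments: each function
simulates data under known conditions, runs the relevant pipeline stage,
and measures how well the planted structure is recovered.  They are used
by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .coherence import subset_coherence
from .genome import GeneFamily, GenomeAnnotation, detect_clusters
from .screen import screen
from .simulate import (
    FamilySpec,
    PlantedDisruption,
    SimulationConfig,
    TimecourseConfig,
    simulate_compendium,
    simulate_genome,
    simulate_timecourses,
)

__all__ = [
    "null_calibration_study",
    "planted_recovery_study",
    "coherence_recovery_study",
    "toy_cluster_layout",
]


def _null_config(seed: int) -> SimulationConfig:
    # 20 mutants x 10 families, nothing planted.  noise_sd = 0.8 makes the
    # |log2| >= 1 disruption call fire on ~21% of genes, so K > 0 and the
    # calibration exercises real hypergeometric tails rather than all-P=1
    # cells.
    return SimulationConfig(
        n_genes=300,
        n_chromosomes=4,
        families=tuple(FamilySpec(f"fam{i:02d}", 10, (3,)) for i in range(10)),
        n_mutants=20,
        planted_disruptions=(),
        noise_sd=0.8,
        seed=seed,
    )


def null_calibration_study(
    n_replicates: int = 200, seed: int = 0
) -> dict[str, object]:
    """Screen P-values under the no-effect null: are they super-uniform?

    Simulates ``n_replicates`` compendia (20 mutants x 10 families each)
    with no planted disruption, screens them, and pools the per-cell
    P-values.  Returns the pooled P-values, and for alpha in {0.01, 0.05,
    0.1} the excess of the empirical fraction P <= alpha over alpha together
    with the 3-standard-error Monte-Carlo bound.
    """
    pvals: list[float] = []
    for i in range(n_replicates):
        cfg = _null_config(seed=seed + i)
        ann, fams, truth = simulate_genome(cfg)
        comp = simulate_compendium(ann, truth, cfg)
        parts = [detect_clusters(ann, f) for f in fams]
        mat = screen(comp, parts)
        pvals.extend(mat.table.loc[mat.table["applicable"], "P"])
    p = np.asarray(pvals)
    alphas = (0.01, 0.05, 0.1)
    excess = {}
    bound = {}
    for a in alphas:
        excess[a] = float(np.mean(p <= a) - a)
        bound[a] = float(3 * np.sqrt(a * (1 - a) / len(p)))
    return {"pvalues": p, "excess": excess, "bound_3se": bound, "n_cells": len(p)}


def planted_recovery_study(
    n_replicates: int = 100,
    effect: float = 2.0,
    penetrance: float = 1.0,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> dict[str, object]:
    """AUC of the deviation score for planted clustered-target disruptions.

    Per replicate: 10 mutants x 6 families, three mutants each disrupting
    one family's clustered subset.  Cells are pooled across replicates and
    ranked by score against the planted (mutant, family) labels.
    """
    scores: list[float] = []
    labels: list[int] = []
    for i in range(n_replicates):
        cfg = SimulationConfig(
            n_genes=300,
            n_chromosomes=4,
            families=tuple(FamilySpec(f"fam{j}", 12, (3,)) for j in range(6)),
            n_mutants=10,
            planted_disruptions=tuple(
                PlantedDisruption(
                    f"mut{j:03d}", f"fam{j}", "clustered", effect, penetrance
                )
                for j in range(3)
            ),
            noise_sd=noise_sd,
            background_disruption_rate=0.02,
            seed=seed + i,
        )
        ann, fams, truth = simulate_genome(cfg)
        comp = simulate_compendium(ann, truth, cfg)
        parts = [detect_clusters(ann, f) for f in fams]
        table = screen(comp, parts).table
        planted = truth.planted_pairs()
        for row in table.itertuples():
            if not row.applicable:
                continue
            scores.append(row.score)
            labels.append(int((row.mutant, row.family) in planted))
    from sklearn.metrics import roc_auc_score

    return {
        "auc": float(roc_auc_score(labels, scores)),
        "n_cells": len(labels),
        "n_planted": int(sum(labels)),
    }


def coherence_recovery_study(
    n_replicates: int = 100,
    rho_cluster: float = 0.7,
    rho_singleton: float = 0.0,
    n_timepoints: int = 8,
    seed: int = 0,
) -> dict[str, object]:
    """Recovery of planted latent correlations from subset coherence.

    Per replicate: a 50-gene genome carrying two families, each with one
    6-gene cluster and 6 singletons (one latent per cluster, so the pooled
    clustered subset has a single correlation level to recover).  Returns
    the mean recovered clustered and singleton PCC and the fraction of
    family cells whose deviation sign matches the planted contrast.
    """
    rc_vals: list[float] = []
    rs_vals: list[float] = []
    sign_hits: list[bool] = []
    contrast = np.sign(rho_cluster - rho_singleton)
    for i in range(n_replicates):
        cfg = SimulationConfig(
            n_genes=50,
            n_chromosomes=2,
            families=(
                FamilySpec("famA", 12, (6,)),
                FamilySpec("famB", 12, (6,)),
            ),
            n_mutants=1,
            timecourse=TimecourseConfig(
                n_timepoints=n_timepoints,
                rho_cluster=rho_cluster,
                rho_singleton=rho_singleton,
                stressors=("stress",),
            ),
            seed=seed + i,
        )
        ann, fams, truth = simulate_genome(cfg)
        parts = [detect_clusters(ann, f) for f in fams]
        tcs = simulate_timecourses(parts, truth, cfg)
        for part in parts:
            res = subset_coherence(tcs[0], part)
            rc_vals.append(res.pcc_clustered)
            rs_vals.append(res.pcc_singleton)
            sign_hits.append(
                np.sign(res.pcc_clustered - res.pcc_singleton) == contrast
            )
    return {
        "rho_cluster_recovered": float(np.mean(rc_vals)),
        "rho_singleton_recovered": float(np.mean(rs_vals)),
        "sign_agreement": float(np.mean(sign_hits)),
        "n_cells": len(rc_vals),
    }


def toy_cluster_layout() -> tuple[GenomeAnnotation, list[GeneFamily], dict]:
    """A 200-gene, 3-chromosome genome with three validation-style families.

    Mirrors the canonical validation layout: a vitamin-pathway triplet plus
    a singleton control, and two ribosome-related adjacent pairs each with a
    singleton control.  Returns the annotation, the families, and the
    expected partition (clusters and singletons per family).
    """
    per_chrom = 200 // 3 + 1
    genes = []
    for i in range(200):
        c, pos = divmod(i, per_chrom)
        genes.append(
            (f"g{i:03d}", f"chr{c + 1}", pos * 2000, pos * 2000 + 1500, "+")
        )
    ann = GenomeAnnotation(genes)
    expected = {
        # BIO5-BIO4-BIO3-style triplet on one chromosome, singleton on another
        "vitamin": {
            "clusters": [["g010", "g011", "g012"]],
            "singletons": {"g150"},
        },
        # MPP10-MRX12-style convergent pair near a centromere-proximal region
        "ribi": {
            "clusters": [["g080", "g081"]],
            "singletons": {"g190"},
        },
        # RPS0A-RSM27-style tandem pair
        "rp": {
            "clusters": [["g110", "g111"]],
            "singletons": {"g030"},
        },
    }
    fams = [
        GeneFamily(
            name=name,
            members=frozenset(g for run in spec["clusters"] for g in run)
            | frozenset(spec["singletons"]),
        )
        for name, spec in expected.items()
    ]
    return ann, fams, expected
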