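# clustercoherence

Tools for asking whether *functional gene clusters* — runs of two or more
same-family genes lying adjacent on a chromosome — are transcriptionally
coordinated, in the style of analyses of the budding-yeast vitamin
metabolic process (VMP), ribosome biogenesis (RiBi) and ribosomal protein
(RP) families.  The package is aimed at computational biologists who have

1. gene coordinates (BED) and gene-family membership (GMT),
2. a deletion-mutant expression compendium (mutant × gene log2 ratios vs
   wild type, e.g. a chromatin-remodeler mutant panel), and
3. stress-response time-courses (gene × timepoint log2 matrices),

and want to know which mutants disrupt the clustered subset of a family
specifically, and whether clustered genes respond to stress more coherently
than their singleton relatives.

## The statistics

**Cluster detection.**  Genes are ranked along each chromosome by start
coordinate.  Family members separated by at most `max_intervening`
non-family genes (default 0, strict adjacency) and optionally at most
`max_gap_bp` base pairs form maximal runs; runs of length ≥ 2 are clusters,
the rest are singletons.  Whether a family clusters more than chance expects
is tested by permutation: membership is reassigned to uniform random gene
subsets of the same size and the clustered-gene count re-measured, with
p = (1 + #{null ≥ observed}) / (1 + N_perm).

**Disruption screen.**  For a mutant with N measured genes of which K are
disrupted (|log2 ratio| ≥ 1 by default), and a family whose clustered subset
has m measured genes of which x are disrupted, the cell statistic is the
hypergeometric upper tail

P = P(X ≥ x),  X ~ Hypergeom(N, K, m) = Σ_{j=x}^{min(K,m)} C(K,j) C(N−K, m−j) / C(N, m)

computed in log space.  For display it is transformed to the deviation
score 1 − P, and the mutant × family score matrix is grouped by k-means
(k = 3: global disruptors, family-specific disruptors, negligible effect).

**Coherence.**  The coherence of a gene set under one stressor is the mean
pairwise Pearson correlation (PCC) of its members' complete profiles.  The
deviation matrix is PCC_clustered − PCC_singleton per (stressor, family);
positive cells mean clustering goes with tighter co-expression.

**qPCR.**  Wet-lab-style validation data flow through the standard
2^(−ΔΔCt) quantification with delta-method SEM propagation.

A synthetic-data generator plants all of this structure (cluster layouts,
mutant disruptions with known targets, latent-factor correlations) and
serializes the ground truth, so every stage has a recovery-based test.

## Worked example

```python
from clustercoherence import *
from clustercoherence.simulate import (
    FamilySpec, PlantedDisruption, SimulationConfig, TimecourseConfig,
    simulate_genome, simulate_compendium, simulate_timecourses,
)

cfg = SimulationConfig(
    n_genes=300, n_chromosomes=3,
    families=(FamilySpec("vitamin", 10, (3,)), FamilySpec("ribi", 8, (2,))),
    n_mutants=6,
    planted_disruptions=(
        PlantedDisruption("mut000", "vitamin", "clustered", 2.0, 1.0),
    ),
    timecourse=TimecourseConfig(stressors=("dtt",), rho_cluster=0.7,
                                rho_singleton=0.0),
    seed=42,
)
ann, fams, truth = simulate_genome(cfg)
parts = [detect_clusters(ann, f) for f in fams]
sig = clustering_significance(ann, fams[0], n_permutations=1000, seed=42)
print("vitamin clustering p =", round(sig.p_value, 4))

comp = simulate_compendium(ann, truth, cfg)
print(screen(comp, parts).scores.round(3))

tcs = simulate_timecourses(parts, truth, cfg, gene_ids=ann.gene_ids)
res = subset_coherence(tcs[0], parts[0])
print(f"PCC clustered={res.pcc_clustered:.3f} singleton={res.pcc_singleton:.3f}")
```

prints

```
vitamin clustering p = 0.026
family  ribi  vitamin
mutant
mut000   0.0      1.0
mut001   0.0      0.0
...
PCC clustered=0.855 singleton=0.033
```

The planted triplet makes the vitamin family significantly clustered
(p = 0.026 against the permutation null); `mut000`, which carries a planted
2-log2 disruption of exactly that clustered triplet, is the only cell with
deviation score 1 − P ≈ 1; and under the DTT time-course the clustered
subset is far more coherent (PCC 0.855) than the singletons (0.033),
recovering the planted latent correlation of 0.7 up to sampling error.

The same stages run from the shell:

```sh
clustercoherence run --config run.yaml --out-dir results/
clustercoherence detect-clusters --bed genome.bed --gmt families.gmt --out parts/
clustercoherence screen --compendium compendium.tsv --partitions parts/partitions.tsv --out screen/
clustercoherence coherence --manifest stressors.yaml --partitions parts/partitions.tsv --out coh/
clustercoherence qpcr --ct-table ct.tsv --test snf2d --out qpcr.tsv
```

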