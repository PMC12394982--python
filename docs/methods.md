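# Methods

## Cluster model

A functional gene cluster is defined on chromosome *rank* (the ordering of
genes by start coordinate within a chromosome), not on base-pair distance:
two family members belong to the same run when at most `max_intervening`
non-family genes lie between them.  The default is `max_intervening = 0`
(strict adjacency), because the canonical validated examples — a
vitamin-pathway triplet, a convergent ribosome-biogenesis pair, a tandem
ribosomal-protein pair — are all immediately adjacent; both parameters are
exposed, and an optional `max_gap_bp` cap (BED convention, 0-based
half-open, gap measured end-to-start) restores physical-distance control
when wanted.  Strand is recorded but ignored: convergent and tandem pairs
both count as clusters.  Because the joining condition is pairwise, maximal
runs are unique and a single left-to-right sweep finds them; partitions are
invariant to input line order.

## Permutation null for clustering

The significance of a family's clustered-gene count is assessed by
relabelling: membership is reassigned to a uniform random subset of
annotated genes of the same size, keeping the gene map fixed, which
preserves the genome's architecture (chromosome sizes, gene density).  The
statistic is the number of family genes inside runs.  The p-value uses the
pseudo-count estimator (1 + #{null ≥ obs}) / (1 + N_perm), which is never
exactly zero and keeps the test valid; selection uses p ≤ α with α = 0.05
inclusive.  For a 3-gene family on a 30-gene chromosome the sampled p-value
is checked against exhaustive enumeration of all C(30,3) placements.

## Disruption screen

A gene is *disrupted* in a mutant when |log2 ratio| ≥ 1.0 (2-fold) by
default.  The original compendium's calling rule is not recoverable, so the
threshold is configurable and a quantile mode (top q% by |ratio|) is
provided for compendia with unknown scale.  The cell statistic is the upper
hypergeometric tail P(X ≥ x) of the disrupted count inside the clustered
subset: population = the mutant's N measured genes, successes = its K
disrupted genes, draws = the m measured clustered-subset genes.  The upper
tail is the reading consistent with asking whether disruption *concentrates*
in the clustered subset; the lower tail is available behind a flag.  The
tail is summed in log space (gammaln terms combined with logsumexp), which
keeps it stable to N ≈ 1e5 and agrees with exact-integer enumeration to
< 1e-12 for every valid argument triple with N ≤ 30.

Missing measurements are excluded per mutant from N, K, n, m and x — per-cell
recomputation, never global listwise deletion.  A cell whose clustered
subset has no measured gene is marked not-applicable and excluded from
grouping, distinct from a score of 0.  Raw p-values are reported; a
Benjamini–Hochberg column is emitted alongside as a clearly-labelled
extension, not used by any decision in the pipeline.  The score matrix
(1 − P per cell) is grouped by k-means with k = 3 (global / family-specific
/ negligible disruptors), 10 restarts, fixed seed; rows are not re-scaled
since scores already lie in [0, 1].

## Coherence

Coherence of a gene set is the mean Pearson correlation over all unordered
pairs of member profiles (median available by flag).  Genes with any
missing timepoint are excluded listwise per stressor, and zero-variance
profiles (Pearson undefined) are excluded and counted; a subset with fewer
than two usable genes yields not-applicable, never 0.  PCCs are computed
per stressor, not on a concatenation across stressors.  The deviation
matrix is the *signed* difference PCC_clustered − PCC_singleton, because
positive and negative deviations mean different biology; the unsigned
distance is emitted as a companion matrix.  Time-courses are used as
provided (log2 ratios); no detrending or reference-timepoint re-centering
is applied.  No significance test is attached to subset-PCC differences:
none is canonically defined for this contrast, and fabricating one would
overstate the evidence.

## 2^(−ΔΔCt)

Replicate Ct values are averaged per (sample, gene) before differencing
(standard Livak ordering): ΔCt = mean Ct(target) − mean Ct(reference) per
sample, ΔΔCt = ΔCt(test) − ΔCt(control), fold = 2^(−ΔΔCt).  The SEM of
ΔΔCt is the root of the summed squared standard errors of the four group
means — the delta method, exact on the log2 scale; the fold-scale SEM
(fold·ln2·SEM) is exposed separately.  Welch t-tests on per-replicate ΔCt
values are offered as report columns only.  When biological and technical
replicates are both present, technical replicates should be averaged within
biological replicate before loading (nested averaging).

## Synthetic data

The generator emulates the structure the analysis assumes, not a microarray
error model:

- **Genome**: evenly spaced genes (1.5 kb genes, 0.5 kb gaps) across
  chromosomes; family clusters placed as adjacent rank windows at uniform
  random non-overlapping positions; singletons placed so no two placements
  of the same family are rank-adjacent, so planted truth and detected
  partition coincide by construction.
- **Compendium**: baseline Normal(0, noise_sd) log2 ratios (default
  noise_sd = 0.25); planted effects add ±effect (default 2.0, sign drawn
  per gene and recorded) to the target subset with given penetrance; an
  optional uniform background disruption (rate configurable; magnitude
  `background_effect`, default 2.0, the same scale as planted effects)
  adds realism.  Gaussian noise suffices because the screen consumes only
  thresholded calls; heavy-tailed realism would not change any count.
- **Time-courses**: one standard-normal latent per (stressor, cluster);
  clustered gene = √ρc·latent + √(1−ρc)·noise, singletons analogously share
  a per-(stressor, family) latent at ρs.  This exchangeable one-factor
  structure is the simplest model with a planted correlation level; real
  stress responses have autocorrelated, non-exchangeable dynamics, so
  passing recovery tests shows the estimator is calibrated, not that real
  families behave this way.
- Default scale mirrors the study design: 165 mutants, 38 families, 14
  stressors, ~6000 genes — all overridable.

Everything is byte-reproducible from (config, seed); seeds for the genome,
compendium and time-course stages are derived from the config seed with
distinct stream keys.

## Validation experiment sizes

The standing experiments (tests and `scripts/acceptance.py`) use: the full
hypergeometric sweep over all N ≤ 30 (≈128k argument triples); null
calibration over 200 compendia of 20 mutants × 10 size-10 families on a
300-gene genome with noise_sd = 0.8 — chosen so the default threshold calls
≈21% of genes and the calibration exercises non-trivial tails rather than
all-P = 1 cells; planted-disruption recovery over 100 replicates (10
mutants × 6 families, effect 2.0, penetrance 1, noise 0.25, 2% background);
and coherence recovery over 100 replicates of a 50-gene genome with two
families of one 6-gene cluster + 6 singletons each at 8 timepoints.  The
coherence configuration uses one cluster per family deliberately: the
generator draws one latent per cluster, so pooling several clusters of one
family would mix independent latents and the pooled clustered PCC would sit
below ρc by design, confounding the calibration check.

## Numerical and degenerate-input choices

- Hypergeometric tails sum the shorter tail directly in log space instead
  of complementing a CDF, avoiding catastrophic cancellation near P = 1.
- P(X ≥ 0) is returned as exactly 1.0; argument-order violations raise,
  never clamp.
- Mean pairwise PCC at n = 2 genes is the single pair's r; expected
  recovered PCC at T timepoints is slightly below ρ (the usual downward
  bias of r at small T, ≈ ρ(1−ρ²)/(2(T−1))), well inside the ±0.1
  recovery band at T = 8.
- Empty annotation files load with a warning; an empty GMT entry raises.
- k-means ties (identical rows) are deterministic given the fixed seed and
  `n_init = 10`.

## Known limitations

- The permutation null relabels genes uniformly; it does not preserve GC,
  expression-level or telomere-distance structure of real family
  membership.
- The screen reports association between a mutant and cluster-specific
  disruption; direct versus indirect (epistatic) regulation cannot be
  distinguished from the compendium alone.
- Absolute reproduction of any published mutant × family p-value table
  requires the original disruption-calling threshold, which is not
  recoverable from a published compendium; the package therefore validates
  by calibration and planted-effect recovery instead.
- Amplification-efficiency correction and melt-curve QC are out of scope
  for the qPCR module; Ct tables are assumed pre-filtered.
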