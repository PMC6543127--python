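# Methods

This note records the statistical procedures gutflow implements, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Study design assumptions

All stages assume a two-group (case/control) cross-sectional design with
one sample per subject. Inputs are features-by-samples tables: gene read
depths (reads mapped per gene, normalised by gene length upstream), taxon
relative abundances per rank (columns sum to 1), and LC-MS peak areas per
compartment (serum, feces) and ionisation mode (ES+, ES−). No covariate
adjustment is performed anywhere — group comparisons are unadjusted rank
or t tests, which is the convention this pipeline reproduces; confounded
cohorts need matching upstream.

## Ecology

Shannon diversity is reported in **nats** (natural log); a `base` switch is
provided since conventions differ. Chao richness uses the bias-corrected
Chao1 estimator `S_obs + F1(F1-1)/(2(F2+1))`, which stays finite when no
doubletons are observed; it is defined on integer counts only, so the
pipeline's diversity report rounds gene depths to the nearest integer
pseudo-count when fed depth data (documented, visible in
`ecology.diversity_report`). Rarefaction draws m samples **with
replacement** (m = 1..N, default 100 iterations) and counts the union of
genes with positive depth; the curve is the iteration mean. A gene is
"identified" if its depth is positive in at least one drawn sample.

## Enterotyping

The sample-by-sample distance is the square root of the base-2
Jensen–Shannon divergence — a metric bounded by [0, 1], which makes the CH
decomposition below well defined. PAM is implemented as deterministic
BUILD (greedy cost-decreasing additions starting from the 1-medoid
minimiser) plus best-improvement SWAP; ties break toward the lowest sample
index, so results are reproducible without a seed (the seed argument is
kept for API symmetry). Cluster number is chosen on k = 2..10 by the
distance-based Calinski–Harabasz index

    CH(k) = [B/(k-1)] / [W/(n-k)],
    W = sum_c ( sum_{i<j in c} D_ij^2 ) / n_c,   B = T - W,

the standard sum-of-squared-distance generalisation used when no
coordinates exist. One behaviour worth knowing: on *one-dimensional*
Gaussian clusters this criterion can favour oversplitting, because the
best split of a 1-D Gaussian cuts its within-SS by ≈ 0.363 — nearly the
same factor as the (n−k)/(k−1) penalty. In two or more effective
dimensions a single split shrinks only one direction's variance, and the
criterion peaks at the true k; genus profiles are high-dimensional, so the
pipeline is unaffected, but toy fixtures must be multivariate.

Enterotype-by-group association uses the two-sided Fisher exact test with
the "sum of tables no more probable than the observed" rule (ties within
1e-12 relative tolerance); for more than two clusters a chi-square test on
the full contingency is reported instead. The dominant taxon of a cluster
is the genus with the highest mean relative abundance among its samples.

## Differential abundance

Features first pass the inclusion filter: mean relative abundance ≥ 1e-4
over the **pooled** cohort and strictly positive abundance in ≥ 6 samples
("present" means detected at all; depth 0 is undetected). The per-feature
test is the two-sided Wilcoxon rank-sum: for pooled n ≤ 20 the p-value is
computed by full enumeration of the label permutations of the rank sum,
which is exact with or without ties (this is why identical samples give
p = 1 exactly); larger samples use the normal approximation with tie and
continuity corrections. BH adjustment runs across the tested features
only; calls use q < 0.05 and direction is the larger group mean.

Clinical tables use the pooled-variance t-test (df = n1+n2−2) from summary
statistics — Welch available by flag — and the Pearson chi-square
**without** Yates correction; both choices reproduce the conventional
printed p-values for cohort tables of this design (the Yates-corrected χ²
would roughly double the sex-ratio p). Heatmap z-scores standardise each
feature row with the population SD (divide by n); constant rows map to 0.

## Co-abundance gene groups

Marker genes are the q < 0.05 genes from the Wilcoxon+BH screen on depths.
Clustering is a deterministic canopy procedure: seeds iterate over the
unclustered pool in descending mean-abundance order (gene id breaks ties,
making the partition invariant to input order); a canopy is every pool
gene with Pearson r ≥ 0.9 to the seed profile; the canopy profile is then
re-centred to the member-wise **median** profile and membership
re-evaluated to a fixed point (≤ 20 rounds); members leave the pool.
Clusters with more than 50 genes are CAGs; smaller clusters are reported
separately, never as CAGs. The 0.9 threshold is the canonical canopy
setting and is configurable.

CAG abundance is the gene-length-weighted mean depth. Taxonomy follows the
tracer-gene rules on an already-filtered hit table (e-value and ≥70 %
coverage filters are an upstream contract): species requires ≥90 % of
member genes hitting one genome at ≥95 % nucleotide identity and ≥70 %
query overlap; genus requires ≥80 % of genes at ≥85 % identity in *both*
DNA and protein. Candidates are ranked by (fraction of genes mapped, mean
nucleotide identity). The species rule reads "identity" as nucleotide
identity (BLASTN context); this is a documented interpretation.

Enrichment is a presence/absence odds ratio between groups with the
Haldane–Anscombe +0.5 correction when any cell is zero; case-enriched
above 2, case-depleted below 0.5. Because a CAG detected in every sample
has an undefined presence split at threshold 0, the pipeline default is a
cohort-**median** split of the CAG's abundance ("presence" = above the
cohort median), with a plain numeric threshold available.

## Discrimination

The cohort is split 80/20 stratified by group. Features are ranked **once
on the full training set** by permutation importance (mean decrease in
accuracy) of a 500-tree random forest — this reproduces the usual
"CV error versus number of features" chart design; per-fold re-ranking
(which avoids the known selection bias of the chart) is available via the
`importance` argument. For each candidate k the misclassification error is
averaged over 5 trials of stratified 10-fold CV; k with the lowest mean
error wins, ties toward the smallest k. AUC uses the rank (Mann–Whitney)
formulation; the 95 % CI is DeLong's analytic estimator (truncated to
[0, 1], flagged degenerate at zero variance, e.g. perfect separation).
The reported training AUC comes from the final forest's out-of-bag class
votes — an honest within-training estimate; resubstitution AUC would be
near 1 by construction.

## Metabolomics

Peak areas are normalised so every sample sums to 1,000,000. PLS-DA is
NIPALS PLS1 on column-autoscaled X (mean 0, unit variance — the common
chemometrics default; center-only is available) against the centred ±1
class code; with a single response each component weight has the closed
form w = X'y/‖X'y‖ and X is deflated by t p' per component. OPLS-DA is the
Trygg–Wold construction: the orthogonal weight is the part of the X
loading orthogonal to the predictive weight, giving orthogonal scores
exactly uncorrelated with the response; after stripping the requested
orthogonal components one predictive component is fitted. VIP is

    VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ),  SS_a = q_a^2 t_a' t_a,

so mean(VIP²) = 1 identically — asserted in tests at machine precision.
Differential metabolites require VIP > 1 (default: 2-component PLS-DA,
matching 2-D score plots) **and** Welch-t p < 0.05 on normalised areas;
fold change is the ratio of group means. Compounds named in both
ionisation modes keep the lower-p mode. Serum/feces concordance compares
the sign of log2 fold change of compounds selected in both compartments;
the exported heat matrix standardises each compartment's log2FC across the
shared compounds (mean 0, SD 1).

## Integration

Spearman correlations between selected genera and selected (serum)
metabolites are computed on the intersection of the two assays' samples,
with average ranks for ties; p-values are exact (full permutation
enumeration) for n ≤ 9 and t-approximate otherwise. Stars follow the
figure convention — raw p < 0.05 (*) and p < 0.01 (**) — and a BH-adjusted
matrix is emitted alongside for honest reuse.

## Synthetic-data generator

The generator emulates a 50 + 50 cohort:

* **Gene layer** — each planted co-abundant block shares a lognormal(1, 1)
  per-sample latent factor; each member gene is `gain * (factor + noise)`
  with the noise variance set to `var(factor)*(1-r)/r`, so the expected
  pairwise Pearson correlation equals the configured r (default 0.95;
  r = 1 gives exact scalar multiples). Three 60-gene blocks plus one
  40-gene block are planted by default; blocks carry alternating
  4-fold case/control effects on the factor. Background genes are iid
  lognormal. The hit table maps 95 % of each block's genes to one
  synthetic species genome at configurable identity/overlap. Gene depths
  being lognormal is this package's choice; no distributional form is
  standard for depth data.
* **Taxon layer** — genus profiles are Dirichlet draws from one of two
  parameter vectors differing only in the dominant-genus mass
  (Bacteroides vs Prevotella, +40 concentration): the minimal model that
  produces two-cluster JSD geometry. Per-group enterotype counts are the
  *rounded* configured fractions (default 82 %/18 % cases, 50 %/50 %
  controls → a 41/9 vs 25/25 contingency), not Bernoulli draws, so the
  planted association is exact. Five named genera carry 4-fold effects in
  the case group (three up, two down); further planted genera (for
  recovery experiments) alternate sign to keep the net compositional shift
  small. Species tables split each genus by a fixed Beta(5,5) proportion;
  phyla aggregate genera through a fixed map.
* **Metabolome layer** — lognormal peak areas; 27 named compounds are
  differential in both compartments (16 with concordant sign, 11
  discordant), 13 shared names carry no effect, and each planted compound
  also appears in the minor mode at a square-root-attenuated fold so the
  lower-p merge rule has real work to do. Five serum features are
  multiplicatively coupled to named genera (`exp(0.8 * z(taxon))`).
* **Clinical layer** — group-specific normal/lognormal/binomial draws
  with literature-shaped parameters (e.g. total cholesterol 4.13 ± 1.05
  vs 4.82 ± 0.96 mmol/L).

What the generator does **not** emulate: sequencing reads, assembly or
mapping noise, compositional zeros/sparsity of real taxon tables (Dirichlet
components are never exactly zero, so prevalence filtering is rarely
binding), batch effects, chromatographic drift, missing metabolite
identifications, or covariate structure (age/sex confounding). Passing
tests therefore demonstrate correctness of the statistical machinery on
data of the right shape and planted effect structure — not robustness to
the full messiness of real cohorts.

## Problem sizes and determinism

Default simulation sizes (400 genes, 16–200 genera, 150 metabolites per
table, 100 samples) were chosen so that a full `simulate` + `run-all`
completes in about ninety seconds on one CPU and the acceptance script in well
under a minute, while keeping every planted-recovery margin wide. All
randomness flows from a single integer seed per generator/stage; two runs
with the same seeds produce byte-identical numeric outputs (the run log,
which records input paths, is the only file that may differ between
differently-located runs).

## Known limitations

* The Wilcoxon exact path enumerates C(n, n1) label assignments; it is
  only engaged for pooled n ≤ 20.
* The distance-based CH index inherits the 1-D oversplitting caveat above.
* The canopy procedure is greedy; a gene correlating ≥ r with two seed
  profiles joins whichever canopy is formed first (descending seed
  abundance order). Planted-block purity is asserted ≥ 0.95, not 1.0.
* DeLong's CI is asymptotic; with fewer than ~10 samples per class the
  bootstrap comparison in the tests is the better guide.
* OPLS-DA here is single-response (two classes only), as is PLS1.
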