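# Methods

This note documents the statistical conventions, model assumptions,
default parameters and numerical choices in `popkit`, and what the
synthetic benchmark does and does not establish.

## Data model

Genotypes are diploid, biallelic, unphased: each locus carries an
insertion allele (code 1) and a deletion allele (code 0), the convention
used when recoding PLINK text PED extracts of InDel markers. Missing data
is the PED code `0` on disk and a sentinel (−1) in memory; a genotype
with one missing allele is treated as wholly missing, since a half-typed
capillary-electrophoresis genotype is not interpretable. Population
labels live outside the PED file (two TSV maps, sample→population and
population→superpopulation), matching reference-panel practice. All
downstream statistics consume either the genotype table or the derived
long-format frequency table `(population, locus_id, p_ins, n)`, where `n`
counts individuals with a non-missing genotype at that locus.

## Forensic parameters

Conventions follow the common forensic-software defaults, since the
formula choices (unbiased vs plug-in He, observed vs expected genotype
frequencies in MP) are rarely printed alongside published tables:

- **He** uses Nei's small-sample correction `2n/(2n−1) · (1 − p² − q²)`.
- **MP** sums squared *observed* genotype frequencies; PD = 1 − MP.
- **PE** is Brenner's trio-exclusion formula `h²(1 − 2hH²)` on observed
  heterozygosity.
- **CPD/CPE** accumulate `1 − Π(1 − x_i)` in log space (`log1p`/`expm1`),
  so a 56-locus panel with PD near 1 at many loci cannot underflow.

A practical benchmark used in panel validation: a panel supports
individual identification when CPD > 0.9999 and paternity testing when
CPE > 0.9999. Biallelic panels of this size clear the first hurdle and
miss the second; the test suite asserts exactly that pattern on the
synthetic panel.

## Screening tests

**HWE.** The exact test conditions on the observed allele counts; under
the null every placement of the insertion alleles among the 2n allele
slots is equally likely, giving the Levene distribution over heterozygote
counts (same parity as the insertion-allele count). The two-sided p-value
sums the probabilities of all heterozygote counts no more probable than
the observed one, with a 1e−9 log-space tolerance so exact ties are kept
together; a mid-p variant is deliberately not the default. Monomorphic
loci return p = 1. The implementation is checked against brute-force
enumeration of allele placements for small n, and its null rejection rate
is calibrated by simulation (exact-test p-values are super-uniform, so
the rejection rate at α sits below α).

**LD.** With unphased biallelic data and unlinked loci the natural
statistic is the squared Pearson correlation of insertion dosages,
n·r² (a Burrows composite-LD style quantity needing no haplotype phase or
EM step). Significance comes from a seeded permutation test,
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, vectorized by recomputing only
the cross-product (permutation leaves each margin's mean and sum of
squares unchanged). Default `n_perm` is 9,999 for single tests; the
table-level screen defaults lower (199–999) because it runs thousands of
pairs. A zero-variance locus yields p = 1 with a warning. The Bonferroni
denominator is always the number of tests actually run; the screens
report it rather than assuming a published count.

## Kinship likelihood ratios

Pairwise relationships are parameterized by IBD coefficients (k0,k1,k2).
Under HWE with insertion frequency p, the one-shared-allele transition
kernel T copies one uniformly chosen allele from the first individual and
draws the other from the population. The per-locus LR of a hypothesis
against unrelatedness is `k0 + k1·T(g2|g1)/P(g2) + k2·[g1=g2]/P(g2)`;
combined LRs multiply across loci (justified by the LD screen) and are
accumulated in log10. Mutation, silent alleles and genotyping error are
not modeled, matching the defaults of pedigree-simulation software in
validation studies. Monomorphic loci contribute LR = 1 and are skipped
with a warning.

Two computational routes exist on purpose:

1. **Monte Carlo**: draw the IBD state per pair and locus, then shared /
   independent alleles; fully vectorized; deterministic given a seed.
2. **Exact convolution**: each locus has at most 9 (genotype-pair) atoms
   with known joint probability and log10-LR value; atoms are rounded to
   a grid (default step 1e−3, so 56 loci displace a combined value by at
   most 0.028 in log10) and convolved. This gives threshold sensitivities
   free of simulation noise and serves as the oracle for the simulator in
   the tests.

"Accuracy" at an LR threshold is reported as the proportion of simulated
*related* pairs reaching the threshold (sensitivity), with the unrelated
pairs' exceedance reported separately as a false-positive rate. A
two-class reading is untenable for published tables of this kind: at
LR ≥ 10,000 reported rates fall below 50%, impossible for a balanced
two-class accuracy when unrelated pairs essentially never exceed such a
threshold. Whether published half-sibling runs reuse the unrelated pairs
of the full-sibling runs is unknowable from the outside; independent
draws are used here.

## Differentiation and informativeness

**F_ST.** Default is the two-population Nei G_ST with unweighted means:
per locus Hs = mean(2p_i q_i), Ht = 2p̄q̄, aggregated as a ratio of sums
across loci and clamped at 0. Under the Balding–Nichols model with both
populations at divergence F from a common ancestor,
E[Ht − Hs] = E[(p₁−p₂)²]/2 = F·p(1−p) while E[Ht] ≈ 2p(1−p), so the
two-population G_ST converges to **F/(2−F)**, not F. The Weir–Cockerham
θ estimator (available via `estimator="wc"`, with HWE-expected
heterozygote frequencies since only allele frequencies are carried) is
the one whose expectation is F itself; the test suite verifies both
mappings at F = 0.05 with 500 loci and 200 diploids per population
(tolerance ±0.015). Published F_ST tables from other software are not
asserted against, because the exact estimator flavor behind them is
generally unstated.

**D_A.** Nei's 1983 distance, `(1/L) Σ_l (1 − Σ_alleles √(x y))` over the
insertion and deletion alleles; 0 for identical frequency vectors, 1 at a
fixed difference in every locus.

**I_n.** Rosenberg's informativeness for assignment, in nats, with the
unweighted mean frequency across groups and 0·ln 0 ≡ 0; bounded by ln K.
PSD = I_n / ln 2. For continental summaries the default grouping is
one-vs-rest at K = 2 — the focal superpopulation's mean frequencies
against the unweighted mean of the remaining superpopulations — which
matches the "distinguish one continental group from the others" reading;
a pairwise two-group mode covers between-continent comparisons, and a
K-group mode over all populations is also exposed. I_n is additive over
loci, so cumulative values are plain sums.

**Ordination and trees.** PCA is centered (and optionally standardized)
SVD with a deterministic sign convention; cos2 values are squared
feature–score correlations (correlation-circle semantics, chosen because
that is how such plots are drawn) and contributions are normalized
squared loadings. Classical MDS is Torgerson double-centering with
negative eigenvalues truncated and a warning when fewer than the
requested components are positive. Neighbor joining uses the Saitou–Nei
agglomeration via scikit-bio with negative branch lengths clamped to
zero; heatmap ordering uses average-linkage (UPGMA) clustering on
Euclidean distances of rows and columns. The dendrogram settings behind
published heatmaps (distance, linkage) are typically unstated, so the
defaults here are documented rather than claimed to replicate any
specific figure.

## Ancestry classification and label noise

Features are insertion dosages (0/1/2); missing genotypes are imputed
with per-locus *training-set* means recorded by the encoder, so no test
information leaks into the fit. The classifier is an RBF-kernel SVM; the
classification target is the five continental groups, not the individual
populations. Hyperparameters are searched log-uniformly over
C ∈ [1e−2, 1e3] and γ ∈ [1e−4, 1e1] with a budget of 40 candidates
(default), each scored by 4-fold stratified cross-validated weighted F1,
best refit on the full training set; the search is a seeded random
search, which keeps results reproducible and dependency-free while
covering the same space a sequential optimizer would. The 80/20
train/test split is stratified by continental group with a fixed seed.

The noise protocol selects ⌈fraction·N⌉ training samples uniformly and
shuffles their labels among themselves ("randomly shuffled" semantics;
a replace-with-uniform-class mechanism is available behind a flag). Since
a shuffle can return a label to its owner, the *realized* mismatch
fraction is below the nominal fraction — in expectation
`fraction · (1 − Σ c_i²)` for class proportions c — and is logged for
every repetition rather than asserted, because the exact mechanism behind
any published realized-noise figure cannot be pinned down. Default noise
fractions are 0.01, 0.10, 0.20, 0.40, 0.50, 0.60, 0.70, 0.80 (the
99:1 … 2:8 normal-to-noisy ratios), 10 repetitions each, noise injected
into training labels only, evaluation always on clean test/external sets.

## Synthetic data generator

The generator is a first-class module: it produces panels with exactly
the properties the analyses assume, so calibrations and recoveries are
meaningful.

- **Model**: hierarchical Balding–Nichols. Ancestral insertion frequency
  uniform on (0.1, 0.5), reflected to (0.5, 0.9) with probability ½;
  superpopulations diverge at F_between = 0.15; sub-populations at
  F_within = 0.005 around their superpopulation; target groups at
  F = 0.01 inside the East-Asian-analogue cluster. F_between = 0.15 is
  deliberately above genome-average human continental divergence because
  ancestry-informative loci are *selected* for extreme differentiation;
  together with the selection filter it yields the frequency spreads such
  panels show. F_within = 0.005 and the target F = 0.01 reproduce the
  within-continent scale of differentiation (target-to-nearest-reference
  F_ST ≈ 0.01).
- **Selection filter**: global MAF ≥ 0.1; max frequency difference among
  the three major continental analogues (African, East-Asian, European)
  > 0.5; max difference in pairs involving the remaining two groups
  > 0.2. The published wording for the second criterion ("South American
  and American populations") is internally odd and is read here as "the
  remaining two continental groups". Loci are generated in batches and
  filtered until 56 survive.
- **Layout**: 7 African-, 5 East-Asian-, 5 European-, 4 American- and 5
  South-Asian-analogue sub-populations (26, mirroring the usual reference
  panel) plus 3 target groups; default 20 individuals per population
  (~580 total) so the full pipeline runs in seconds; full-size cohorts
  are a parameter away.
- **Genotypes**: binomial HWE draws within each population, loci
  independent (no LD), deterministic from the seed.

What the generator does **not** emulate: real haplotype LD, demographic
history (growth, migration, admixture), genotyping error and allelic
dropout, and the particular frequency vectors of any real population.
Consequently, passing tests establish the *correctness and calibration*
of the statistics and the *qualitative* behaviors (screen calibration,
sensitivity orderings, classifier robustness patterns, cluster recovery)
— not the numerical values any specific real cohort would produce. The
sibling-LR working ranges reproduced in the acceptance tests show that a
56-locus panel with this design operates in the published regime; they
are not a re-analysis of the original cohorts, whose genotypes are not
public.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately scaled problem sizes chosen to
keep the suite fast while leaving Monte-Carlo tolerances meaningful:
1,000 pairs per kinship run (matching published simulation sizes), 2,000
replicates for HWE calibration, 200 seeds × 999 permutations for LD
uniformity, 500 loci × 200 diploids for divergence recovery, and reduced
noise-protocol grids (3–10 repetitions, search budgets 5–15) for the
classifier properties. Stage seeds in the pipeline derive from
CRC32(global_seed, stage name), so disabling a stage never shifts another
stage's randomness and identical configs give byte-identical CSVs.

Tie-breaks and degenerate inputs: exact-test ties are grouped with a
1e−9 log tolerance; permutation p-values use the add-one estimator and
so never return 0; monomorphic loci yield p = 1 (HWE), LR = 1 (kinship)
or are dropped with warnings (PCA standardization, encoder); distance
matrices are symmetrized and clamped at 0 after validation; PCA signs
follow a largest-loading-positive convention for determinism.

## Known limitations

- PE covers the trio (both-parents) exclusion case only; paternity-index
  systems and multi-allelic extensions are out of scope.
- The kinship module handles pairwise IBD hypotheses, not full pedigree
  likelihoods, linked markers or mutation models.
- G_ST/θ and D_A operate on allele frequencies, so sample-size effects
  enter only through θ's variance components; published tables computed
  by other tools may differ by estimator flavor.
- The SVM protocol fixes the kernel to RBF; comparing classifier families
  is out of scope.
- Newick output carries no bootstrap support values.
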