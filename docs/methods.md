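# Methods

This note documents the models and procedures implemented in `rumenmark`,
the choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Data preparation

**OTU retention.** Features whose total count is ≤ 2 (doubletons and below)
are removed first; the survivors must each exceed 0.001 % of the remaining
grand total. The rule is idempotent because removing features only raises
the relative share of those kept.

**Taxonomic aggregation.** Lineages are `;`-delimited strings ordered
domain → genus. Counts are summed over features sharing the label at the
requested rank; features whose lineage stops short are pooled into an
`unclassified_<deepest known rank>` bucket, so the grand total is conserved.

**Genotype QC.** Per SNP: minor allele frequency ≥ 0.05, missing rate
≤ 0.10, and a 1-df chi-square Hardy-Weinberg test (no continuity correction)
at p ≥ 0.001. Each rule is evaluated on the full input and the failure sets
are unioned, so removal is independent of SNP order. Missing dosages are
never imputed at QC time; the GRM imputes them to 2p, their expectation.

**Transforms.** `to_relative` divides each sample by its library size;
`clr` is ln(count + 1) minus the per-sample mean log (natural log,
pseudocount 1 — the pseudocount is a convention, not an estimate, and 1 on
raw counts keeps the transform monotone in the count); `css_normalize` uses
a per-sample scaling factor equal to the sum of counts not exceeding the
chosen quantile of the sample's nonzero counts, with values
log2(count/scale × 1000 + 1). The quantile defaults to a fixed 0.5 for
reproducibility; an adaptive relative-difference rule is available behind
`quantile="adaptive"` but is deliberately not the default because adaptive
quantile choices are sensitive to the tail of the count distribution.

**Phenotypes.** CH4y = CH4/DMI (g per kg dry matter intake). Traits are
adjusted for the contemporary group by subtracting the batch × period cell
mean, i.e. the residual of a one-way fixed-effects model; residuals sum to
zero within every cell and a singleton cell yields residual 0 (warned).

## Ruminotyping

Profiles are genus-level relative abundances. The dissimilarity is
√JSD with natural logs; zeros are replaced by 1e-9 and profiles
renormalised. The square root is used because it is a metric (the triangle
inequality is property-tested), matching the established enterotyping
practice; raw JSD is available via `sqrt=False`.

PAM is implemented as greedy BUILD seeding followed by steepest-descent
SWAP. The swap neighbourhood has genuine local optima even on tiny
instances, so for small problems (n ≤ 32 by default) the swap phase is
restarted from alternative greedy seedings (each sample forced as first
medoid) and the cheapest local optimum kept. All tie-breaks go to the lowest
sample index; the algorithm uses no randomness at all, which makes the
bootstrap the only stochastic element of the clustering stage. Against an
exhaustive enumeration of all medoid subsets on 100 random instances
(n ≤ 8, k ≤ 3) the solver attains the optimum in at least 95.

The number of clusters maximises the Calinski-Harabasz index over k = 2..8.
Because CH is variance-based and √JSD matrices are not Euclidean, CH is
computed by default on the classical-MDS (PCoA) embedding with negative
eigenvalues dropped; a `direct` mode computes the between/within sums of
squares straight from pairwise distances (the two agree exactly when the
matrix is Euclidean). Silhouette widths are reported alongside but do not
drive the choice.

Cluster stability follows the cluster-wise Jaccard bootstrap: each of 100
resamples (with replacement) is re-clustered, the bootstrap medoids classify
*all* original samples, and each original cluster is matched to the
best-Jaccard bootstrap cluster. Extending the bootstrap solution to the full
sample set (rather than intersecting index sets) is what makes the statistic
discriminate: separated clusters score ≥ 0.85 while a forced k = 3 on an
isotropic cloud scores ≤ 0.6.

Cluster-phenotype association uses least-squares means with a pooled
residual variance and all pairwise contrasts; multiplicity is handled by
Tukey's studentized-range adjustment (with two clusters this reduces exactly
to the pooled two-sample t-test).

## Differential abundance

The ZIG mixture treats each css-log2 value as either a Gaussian draw around
a per-feature linear predictor on the group, or (only where the raw count is
zero) a structural zero whose probability follows one logistic model on log
library size shared across features. EM alternates exact M-steps (per-feature
weighted least squares, pooled Newton logistic) with responsibilities for the
observed zeros; the observed-data log-likelihood is non-decreasing by
construction and asserted in tests. Inference on the group coefficient is a
weighted t-test with degrees of freedom Σw − 2; with no zeros the procedure
collapses exactly to an ordinary per-feature linear model. The moderated
(empirical-Bayes) variance used by some implementations is deliberately
omitted — a plain weighted t keeps the null calibrated (type-I error within
[0.03, 0.07] at α = 0.05 in the null simulation) without borrowing strength
assumptions. Benjamini-Hochberg is applied across features per comparison.

The presence-absence screen is Fisher's exact test (two-sided by the
probability-mass rule) per feature per cluster pair, with the
Haldane-Anscombe-corrected sample odds ratio; fold changes are ratios of
group means on the back-transformed css linear scale with a pseudocount
guard for all-zero groups.

## Sparse PLS

Each component takes the dominant singular pair of the deflated
cross-covariance X'Y, soft-thresholds the X-weight to at most `keep_x`
nonzero entries (the largest excluded magnitude is the threshold), and
renormalises; X and Y are deflated by regression on the X-score in both
modes, making successive scores orthogonal. With dense weights the first
component equals standard PLS, and with Y = X the components reproduce PCA
loadings — both used as test oracles. The discriminant mode one-hot-encodes
the labels and predicts by max.dist (largest predicted indicator).

Tuning uses repeated (stratified, in discriminant mode) 5-fold
cross-validation. Regression reports Q²_h = 1 − PRESS_h/RSS_{h−1}, with
PRESS from out-of-fold predictions of the h-component model and RSS from the
full fit with h − 1 components (RSS₀ = total sum of squares); components are
retained while Q² ≥ 0.0975, the classical threshold. Classification reports
the overall error rate and the balanced error rate (mean of per-class error
rates); BER is the tuning loss, ties prefer fewer features. AUROC is
one-vs-rest on predicted indicator values (Mann-Whitney rank form with
midranks); when computed on training data it is a resubstitution AUC and is
labelled as such.

The biomarker set is the intersection of the discriminant and regression
selections — a deliberately conservative rule keeping only features
associated with both the community structure and the phenotype.

## Variance components

G is VanRaden's first GRM, ZZ'/(2Σp(1−p)) on dosages centred by 2p. The
Bray-Curtis microbial kernel is 1 − dissimilarity on relative abundances;
such similarity matrices need not be PSD, so negative eigenvalues are
truncated at zero and the reconstruction flagged with the maximal
elementwise change. The log-std kernel is SS'/m on the ln(count+1) matrix
with features standardised (sd with n−1 denominator), giving mean diagonal
(n−1)/n exactly.

The Gibbs sampler updates: the intercept (flat prior); the kernel effects in
the eigenbasis of each kernel, where the full conditional precision is
diagonal (1/σe² + 1/(σ² d_i)) — distributionally equivalent to sampling the
effects directly at O(n²) per sweep; and the three variances from
scaled-inverse-chi-square full conditionals. Defaults: 30,000 iterations,
2,000 burn-in, thinning 1; h² and m² are computed per retained draw and
summarised by posterior mean and SD.

**Priors.** Variances carry scaled-inverse-χ² priors with df 5. The scale is
set so each variance has prior mean var(y)/6. The split between σg² and σe²
is only weakly identified when the GRM's eigenvalue spectrum is narrow — the
situation with a few thousand SNPs on unrelated animals — and an
equal-thirds prior budget was found to dominate the posterior in that
regime, inflating h² under a pure-noise phenotype and upward-biasing
recovery. The var(y)/6 scale keeps the prior gently regularising (total
prior budget half the phenotypic variance) while letting the likelihood
dominate: under a pure-noise phenotype at n = 300 the posterior mean of h²
stays below 0.10, and simulated h² = 0.15 / m² = 0.20 are recovered within
a few points. Both scales remain overridable per component.

**Repeated records** (an animal measured in two periods) are averaged to one
record per animal before modelling.

## Synthetic study generator

The generator reproduces the *structure* the analyses assume, with defaults
chosen once to mirror a realistic methane-phenotyping experiment:

- 65 cows in three contemporary-group cells (21/21/23), batch effects
  N(0, 1) g/kg;
- 100 genera on a Zipf-like rank-abundance curve, Dirichlet concentration 45
  (moderate overdispersion across animals); three community types whose
  Dirichlet base measures multiply 10 disjoint "driver" genera each
  (interleaved among the 30 most abundant ranks) by 1 + separation, with
  separation 4 — enough that community types are unambiguous, as in
  enterotype-style analyses where types differ in their dominant taxa;
  deterministic largest-remainder cluster sizes 30/16/19;
- 1,200 OTUs allocated to genera proportionally to genus abundance, with a
  fixed within-genus composition; sequencing depth lognormal with median
  ~22,000 reads and CV ≈ 50 %, which produces the depth-driven zeros the
  CSS/ZIG stages are designed for;
- 2,000 independent SNPs with allele frequencies uniform on (0.05, 0.5) in
  Hardy-Weinberg proportions;
- phenotype mean 24.1, SD 3.1 g/kg (typical methane-yield magnitudes); the
  genetic part spreads σg² = h²·SD² over all SNPs on centred dosages, and
  the microbial budget σb² = m²·SD² is split between a per-cluster shift
  (default +2 g/kg on the second cluster, its realised variance counted
  against the budget) and continuous effects on the clr abundances of 30
  causal OTUs. Causal OTUs are drawn from the driver genera by default,
  making the microbial signal simultaneously compositional and structural —
  the joint association the biomarker intersection exploits. Variances are
  solved so *expected* fractions hit the targets; the *realised* fractions
  of each draw are recorded in the ground truth (across 20 seeds the mean
  realised h² is within 0.02 of target at n = 1000).

What passing tests on these data do **not** show: robustness to
phylogenetic correlation among OTUs, to compositional effects stronger than
the Dirichlet-multinomial allows, to related animals (the SNPs are
independent and the animals unrelated, so the GRM spectrum is narrower than
in a half-sib cattle population), or to per-OTU effect sizes large enough to
be individually detectable at n = 65 — with m² = 0.20 spread over 30 OTUs,
individual abundance-phenotype correlations (~0.06) sit below the sampling
noise at that size, which is precisely why the pipeline aggregates evidence
through clusters and kernels rather than per-OTU regressions.

## Problem sizes used in validation

The test suite validates at the generator's native scale where the claim
concerns that scale (65 × 1,198 sPLS-DA recovery; 50-seed cluster-number
selection; 2,000-feature ZIG calibration; 1,000 × 999-permutation PERMANOVA
type-I calibration) and at n = 300 with 500 SNPs for variance-component
recovery, where the 500-SNP GRM has a well-dispersed spectrum
(Marchenko-Pastur half-width √(n/m) ≈ 0.77) so the two kernels are cleanly
identifiable — the regime in which parameter recovery is a meaningful test
of sampler correctness rather than of prior choice.

## Known limitations

- The PERMANOVA permutes raw sample labels with the design fixed (the common
  adonis convention); residual-permutation schemes for covariates are not
  implemented.
- The ZIG zero model is shared across features; a per-feature zero model
  would need many more samples to be estimable.
- The sampler reports marginal posterior summaries only; no convergence
  diagnostics beyond the split-half check in the tests.
- nMDS ordination and figure generation are out of scope; outputs are plain
  TSV/JSON.
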