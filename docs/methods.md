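# Methods

`mica` implements a two-stage Microbiome Co-occurrence Analysis: discovery
of *microbial cliques* — small sets of taxa whose joint presence pattern
predicts an outcome — followed by covariate-adjusted permutation inference
on a per-sample clique indicator, run separately within strata of an
effect modifier (here, food-security status). The package targets the
epidemiological setting of a population-based adult cohort with 16S rRNA
stool profiles and a brief cognitive screen, but every stage is generic
over a sample x taxon relative-abundance table, a continuous outcome, and
a binary stratifier.

## Outcome and exposures

The cognitive outcome is a 0–3 word-recall count (mini-cog). For
regression it is inverted and log-transformed: `rci = ln(4 − score)`, so
higher values indicate higher risk of cognitive impairment (RCI) and the
transform is finite at perfect recall. Food insecurity is derived from
three survey questions (emergency food use, worry about having enough
food, Food Stamp authorization over the last 12 months): any "yes" codes
the participant as food insecure.

Microbiome exposures are per-individual relative abundances. Taxa present
(abundance > 0) in at most 5% of samples are removed (strictly-greater
rule); remaining abundances are deliberately **not** rescaled, so each
retained taxon keeps its original proportion of the individual's
community. Shannon diversity `H = −Σ p ln p` (natural log) is computed on
the unfiltered composition. For the per-taxon association scans each
taxon is recoded to quartiles 1–4 by type-7 sample quantiles so that
coefficients are comparable across taxa; values tied with a cut-point go
to the lower quartile, and when one value carries more than 25% of the
mass (zero-inflation) that entire mass takes code 1 while the remaining
values are quartiled among themselves.

## Adjusted models

All regressions are OLS of `rci` on the exposure plus age, race/ethnicity
(non-Hispanic-White vs other), BMI, gender, pet ownership, smoking
history, dietary fiber (g), and past-year antibiotic use. Confidence
intervals are normal-theory `beta ± 1.96·se`. Per-taxon scans are
corrected by Benjamini–Hochberg FDR within stratum and displayed as
volcano tables/plots with reference lines at p = 0.05 and 0.01.
Descriptive tables use the Wilcoxon rank-sum test (asymptotic, tie
corrected, no continuity correction) for continuous variables and
Fisher's exact test (two-sided by summing table probabilities at most as
likely as the observed) for binary ones.

## Stage 1 — repeated-holdout signed-iterative random forest (rh-SiRF)

Within one stratum, with relative abundances as predictors and `rci` as
outcome:

1. **Weighted forests.** Regression trees whose candidate split features
   at every node are sampled with probability proportional to a feature
   weight vector. The trees are built in-package (numba kernels) because
   node-level weighted feature sampling and raw decision-path access are
   not available in off-the-shelf forests. Split search uses 32-bin
   equal-width histograms per candidate feature (the standard
   gradient-boosting approximation); for zero-inflated abundances the
   first bin boundary is effectively the presence/absence split. Defaults:
   100 trees per bootstrap forest, 300 trees for reweighting/guard
   forests, depth 5, minimum leaf 5, mtry = ceil(sqrt(p)).
2. **Iterative reweighting (iRF).** Starting from uniform weights, a
   forest is grown and the weights are replaced by its normalized
   out-of-bag permutation importances (clipped at zero), mixed with a
   uniform floor (weight 0.25) so one unlucky draw cannot permanently
   retire a taxon; three iterations by default. OOB permutation
   importance is used rather than split-gain importance because gain
   importance assigns every overfit noise split a positive score and
   therefore never concentrates on weak signals, whereas permutation
   importance is approximately zero-mean for noise taxa; the
   gain-importance variant remains available (`importance='impurity'`).
3. **Signed itemsets.** Every root-to-leaf path of a forest yields the set
   of (taxon, side-of-threshold) pairs on the path — "high" is the side
   above the split threshold, which for sparse abundances usually means
   presence — weighted by the number of training samples in the leaf.
4. **Random intersection trees.** Itemsets are repeatedly intersected
   (depth 5, 2 children, 50 RIT trees, sampling proportional to itemset
   weight); every non-empty intersection of at least two *distinct*
   sampled itemsets with at least two distinct taxa is a candidate, and
   its prevalence (weighted fraction of itemsets containing it) is
   recorded. A child never re-samples its parent's own itemset, so a lone
   itemset cannot survive by self-intersection.
5. **Repeated holdouts.** The stratum is split 60/40 train/test (default
   1000 repeats at full scale; 50 for desk-scale work). Weights are
   iterated on the training partition; a guard forest grown with the
   final weights must achieve positive prediction–outcome correlation on
   the held-out 40%, otherwise the repeat contributes no candidates (this
   is what keeps pure-noise runs clean). Each of the (default 250,
   desk-scale 20) bootstraps of the training partition grows one weighted
   forest and runs RIT. A candidate is identified by its **taxon set**
   (signs kept as metadata, reported as the modal sign pattern);
   its *stability* is the fraction of repeats recovering it in at least
   one bootstrap. Ranking is by stability, then bootstrap-level support,
   then set size, then lexicographic taxon IDs.
6. **Clique selection.** Candidates at or above `min_stability` (default
   0.5) are merged into overlap-connected components — the closed-loop
   network of co-occurring taxa — which are the final cliques. Raising
   the threshold can only remove cliques.

## Stage 2 — clique-indicator permutation inference

Each clique of k taxa becomes a per-sample integer 0..k counting members
present (abundance > 0); "harboring" the clique means indicator ≥ 1. The
indicator enters the adjusted OLS as a continuous exposure. Its p-value
permutes the outcome vector wholesale (default 10^5 draws; exhaustive
enumeration when n! is within budget), comparing the exposure |t| via the
bounded equivalent statistic t²/(t² + dof), with add-one smoothing
`p = (1 + #{as extreme}) / (1 + B)` so p ≥ 1/(B+1). Fits are run per
stratum with harboring prevalences, and a clique discovered in one
stratum is validated by the same regression in the other stratum's
samples.

## Sensitivity machinery

Missing covariate cells (a few percent at most) are filled by predictive
mean matching: a linear model of each incomplete column on the others
(complete cases; mean-filled predictors), with each missing cell taking
the observed value of one of the k = 5 nearest-prediction donors, so
imputations preserve the observed support. Covariate balance for each
clique regression (exposure: harboring yes/no) is checked by linear
propensity-score subclassification into quintiles; standardized mean
differences (SMD, pooled-SD denominator) are reported raw and as
subclass-size-weighted averages, sorted as a love plot. Subclasses
lacking an exposure group merge into a neighbor with a warning.

## Synthetic cohort generator

The generator reproduces the statistical shape of the target cohort with
known ground truth: n = 360 adults, 18.9% food insecure, 100 taxa, <2%
covariate missingness (MCAR). Abundances are one symmetric Dirichlet(1)
draw per sample with each taxon zeroed independently at the sparsity rate
(default 0.70) and renormalized — simple, compositional, zero-inflated.
Covariates are anchored to the cohort's marginals: age ~ N(61.5, 13.4),
BMI ~ N(31, 7.4), fiber ~ N(19, 10) truncated at 0, binaries at their
observed frequencies. The latent outcome adds a food-insecurity effect
(default 0.06), stratum-specific planted-clique terms (defaults mirror
the motivating analysis: a 2-taxon clique at 0.29 insecure / 0.05 secure
and a 4-taxon clique at 0.07 / 0.10; linear in the member-presence count,
or all-present-only when `joint=True`), small covariate effects, and
Gaussian noise.

The mini-cog score discretizes the latent outcome at its empirical
55/88/97th percentiles into scores 3/2/1/0, fixing the marginal
distribution at (.55, .33, .09, .03) — mean 2.40, matching the cohort.
The default noise scale is a derived quantity, not a free dial: for a
normal latent variable cut at those quantiles and mapped to
ln(4 − score), the regression slope of the mapped outcome on the latent
scale is 0.375/σ_latent, so `noise_sd = 0.35` (total latent SD ≈ 0.375)
makes the discretized, log-transformed outcome preserve planted
coefficients approximately unbiasedly. This is why stage-2 regressions on
the synthetic cohort recover 0.29/0.05 within sampling error.

What the generator does **not** emulate: phylogenetic correlation among
taxa, read-depth/compositional coupling beyond the Dirichlet, informative
missingness, survey weighting, and measurement error in the covariates.
Passing tests therefore demonstrate the machinery's correctness and
calibration under a clean data-generating process, not performance on
real microbiome data.

## Validation study conditions

The test suite runs four simulation studies (sizes chosen to keep the
whole suite desk-scale):

- **Calibration.** 2000 null replicates (n = 40, two covariates, 1000
  permutations each): the permutation test's type-I error at nominal 0.05
  must lie within 3 binomial SE.
- **Stratified recovery.** 20 default cohorts: stage-2 betas within 3 SE
  of the planted 0.29/0.05 and the stronger-insecure ordering recovered,
  each in ≥ 90% of seeds.
- **Planted discovery.** One fixed cohort (n = 360, 100 taxa, presence
  50%) with a single 2-taxon clique raising the latent outcome by 0.3 —
  the magnitude of the stronger stratum effect in the motivating analysis
  — when both members are present; rh-SiRF at 50 repeats x 20 bootstraps
  must rank the planted pair as the top size-2 candidate for ≥ 80% of 10
  discovery master seeds. The continuous latent outcome is used here so
  the condition tests the discovery operation itself rather than the
  outcome coarsening.
- **Null discovery.** The same cohort with the effect zeroed: no
  candidate may reach the 0.5 stability threshold in ≥ 90% of master
  seeds.

## Numerical and degenerate-input choices

Zero-total samples are rejected by name in relative-abundance conversion;
all-zero compositions are rejected in diversity; constant exposure
vectors are rejected in permutation regression; rank-deficient designs
fail naming the collinear columns; constant vectors quartile-encode to
all-1 with a warning; a stratum smaller than covariates + 2 is an error.
Every stochastic component is deterministic under its seed (numpy
`default_rng` / `SeedSequence` throughout; numba kernels seed their own
RNG), and repeated pipeline runs with the same configuration are
bit-identical.

## Known limitations

- The rh-SiRF chain's sensitivity is bounded by the per-taxon marginal
  signal; cliques whose members have individually negligible marginal
  association (pure epistasis at small effect) are not reliably
  discoverable at desk scale, and weak-signal datasets can promote a
  clique member paired with a correlated noise taxon.
- Stability is a selection frequency, not an error rate; no p-value is
  attached to discovery.
- Single imputation only (appropriate for the per-mille missingness
  modeled); no Rubin's-rules variance combination.
- The stratified contrast compares stratum-specific fits; no formal
  interaction test is computed.
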