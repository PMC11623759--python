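# mica — microbiome co-occurrence (clique) analysis

`mica` identifies **microbial cliques** — small groups of gut taxa whose
joint presence pattern predicts a health outcome — and tests whether their
association with the outcome differs across strata of an effect modifier.
The motivating setting is the gut–brain axis in a population-based adult
cohort: stool 16S ASV profiles, a brief word-recall screen for risk of
cognitive impairment (RCI), and food-insecurity status as the modifier.
The package is for epidemiologists and microbiome statisticians who want
the full chain — synthetic cohorts with ground truth, feature-table
preparation, adjusted per-taxon scans, machine-learning clique discovery,
and permutation-based stratified inference — as tested, reusable library
code.

## The method

The outcome is the inverted, log-transformed recall score,
`rci = ln(4 − score)` (higher = more impairment). Analysis runs in two
stages within each stratum (MiCA):

**Stage 1 — rh-SiRF.** A repeated-holdout signed-iterative Random Forest
discovers candidate cliques: regression forests whose node-level feature
sampling is iteratively reweighted toward informative taxa (iRF, using
out-of-bag permutation importances), decision paths read out as *signed
itemsets* of (taxon, high/low) pairs, random intersection trees (RIT)
distilling frequently co-occurring sets, all stabilized over repeated
60/40 train/test holdouts (1000 at full scale) with bootstrap resampling
(250) inside each training partition. A candidate's *stability* is the
fraction of holdouts recovering it; overlapping candidates above a
stability threshold merge into the final cliques.

**Stage 2 — clique-indicator regression.** A clique of k taxa becomes a
per-sample count 0..k of members present. The count enters an OLS of RCI
adjusted for age, race/ethnicity, BMI, gender, pet ownership, smoking,
dietary fiber and antibiotic use; its p-value comes from permuting the
outcome (10^5 draws by default) rather than normal asymptotics,

&nbsp;&nbsp;&nbsp;&nbsp;p = (1 + #{|t_perm| ≥ |t_obs|}) / (1 + B).

Cliques discovered in one stratum are validated by the same regression in
the other stratum. Sensitivity machinery covers predictive-mean-matching
imputation of sparse covariate missingness and propensity-subclass
balance diagnostics (love plots).

A synthetic-cohort generator with known ground truth (planted cliques
with stratum-specific coefficients) drives all validation; see
`docs/methods.md` for the generative model and the calibration that makes
the discretized cognitive score preserve planted effect sizes.

## Worked example

Discovery on a benchmark cohort (360 samples, 100 taxa at 50% presence,
one planted 2-taxon clique raising the outcome by 0.3 when both members
are present), at the desk-scale preset (50 holdouts × 20 bootstraps):

```python
from mica import (SimulationConfig, PlantedClique, generate_cohort,
                  DiscoveryConfig, repeated_holdout_discovery, select_cliques)

cfg = SimulationConfig(
    n_samples=360, n_taxa=100, sparsity=0.5,
    p_food_insecure=0.0, beta_food_insecurity=0.0, covariate_effects={},
    planted_cliques=[PlantedClique((0, 1), 0.3, 0.3, joint=True)],
    missing_rate=0.0, seed=0)
table, meta, truth = generate_cohort(cfg)
cands = repeated_holdout_discovery(table.values, truth.latent,
                                   DiscoveryConfig.fast(seed=0),
                                   taxon_ids=table.taxon_ids)
for c in cands[:3]:
    print(f"{sorted(c.taxa)}  stability={c.stability:.2f}")
```

```
['ASV0000', 'ASV0001']  stability=0.86
['ASV0001', 'ASV0059']  stability=0.60
['ASV0001', 'ASV0077']  stability=0.56
```

The planted pair tops the ranking. Stage-2 inference on the default
cohort (two planted cliques; the first at β = 0.29 in the food-insecure
stratum vs 0.05 in the food-secure stratum):

```python
from mica import (SimulationConfig, generate_cohort, prepare_metadata,
                  pmm_impute, stratified_effects, COVARIATE_COLUMNS)

table, meta, truth = generate_cohort(SimulationConfig(seed=1))
meta = prepare_metadata(meta)
meta[COVARIATE_COLUMNS] = pmm_impute(meta[COVARIATE_COLUMNS], seed=1)
res = stratified_effects(table, meta, set(truth.clique_taxa[0]),
                         n_permutations=10_000, seed=1)
for stratum, fit in res.results.items():
    nh, ns = res.prevalence[stratum]
    print(f"{stratum:9s} beta={fit.beta:+.3f} "
          f"CI=[{fit.ci95[0]:+.3f}, {fit.ci95[1]:+.3f}] "
          f"p_robust={fit.p_robust:.4f}  harboring {nh}/{ns}")
```

```
secure    beta=+0.021 CI=[-0.051, +0.093] p_robust=0.5682  harboring 155/300
insecure  beta=+0.373 CI=[+0.193, +0.554] p_robust=0.0002  harboring 37/60
```

The stratified fits recover the planted effect modification: a strong,
permutation-significant association in the small food-insecure stratum
and a near-null one in the food-secure stratum.

A command-line interface mirrors the library
(`mica simulate | prep | scan | discover | infer | balance | run`); try
`mica run --fast --seed 3 --out demo/` for an end-to-end synthetic run.

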