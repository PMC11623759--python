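from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
import pytest

from mica.cohort import PlantedClique, SimulationConfig, generate_cohort
from mica.inference import (
    build_indicator,
    cross_stratum_validate,
    permutation_regression,
    stratified_effects,
)
from mica.prep import FeatureTable, prepare_metadata


def make_table(rows, taxa):
    return FeatureTable(pd.DataFrame(rows, columns=taxa,
                                     index=[f"s{i}" for i in range(len(rows))]))


class TestIndicator:
    def test_partial_presence(self):
        tab = make_table([[0.1, 0.0]], ["A", "B"])
        ind = build_indicator(tab, {"A", "B"})
        assert list(ind.values) == [1]

    def test_all_and_none_present(self):
        tab = make_table([[0.2, 0.3], [0.0, 0.0]], ["A", "B"])
        ind = build_indicator(tab, {"A", "B"})
        assert list(ind.values) == [2, 0]
        assert list(ind.harboring) == [True, False]

    def test_range_contract(self, small_cohort):
        table, _, _ = small_cohort
        for k in (2, 4):
            clique = set(table.taxon_ids[:k])
            ind = build_indicator(table, clique)
            assert ind.values.min() >= 0
            assert ind.values.max() <= k
            presence = (table.data[sorted(clique)] > 0).sum(axis=1).to_numpy()
            assert np.array_equal(ind.values, presence)

    def test_unknown_taxon_named(self):
        tab = make_table([[0.1]], ["A"])
        with pytest.raises(KeyError, match="GHOST"):
            build_indicator(tab, {"A", "GHOST"})

    def test_empty_clique_rejected(self):
        tab = make_table([[0.1]], ["A"])
        with pytest.raises(ValueError):
            build_indicator(tab, set())


def brute_force_perm_p(y, x, covariates=None):
    """Enumerate all n! outcome orderings; add-one smoothed p on |t|."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    n = len(y)
    cols = [x] if covariates is None else [x] + list(np.asarray(covariates).T)
    X = sm.add_constant(np.column_stack(cols))

    def abs_t(yy):
        fit = sm.OLS(yy, X).fit()
        return abs(fit.tvalues[1])

    t_obs = abs_t(y)
    exceed = sum(abs_t(y[list(p)]) >= t_obs - 1e-12 for p in permutations(range(n)))
    return (1 + exceed) / (1 + factorial(n))


class TestPermutationRegression:
    def test_exhaustive_three_point_example(self):
        # perfect line: only the identity and the reversal reach |t| = inf
        res = permutation_regression([1, 2, 3], np.array([1.0, 2, 3]),
                                     n_permutations=1000)
        assert res.exhaustive
        assert res.p_robust == pytest.approx(3 / 7)

    def test_exhaustive_matches_brute_force(self, rng):
        for trial in range(3):
            n = 6
            y = rng.standard_normal(n)
            x = rng.standard_normal(n)
            res = permutation_regression(y, x, n_permutations=100_000)
            assert res.exhaustive
            assert res.p_robust == pytest.approx(brute_force_perm_p(y, x), abs=1e-12)

    def test_add_one_lower_bound(self, rng):
        n = 60
        x = np.linspace(0, 1, n)
        y = 5 * x + 0.01 * rng.standard_normal(n)
        res = permutation_regression(y, x, n_permutations=500, seed=3)
        assert res.p_robust >= 1 / 501
        assert res.p_robust == pytest.approx(1 / 501)

    def test_deterministic_under_seed(self, rng):
        y = rng.standard_normal(40)
        x = rng.standard_normal(40)
        r1 = permutation_regression(y, x, n_permutations=300, seed=11)
        r2 = permutation_regression(y, x, n_permutations=300, seed=11)
        assert r1.p_robust == r2.p_robust
        assert r1.beta == r2.beta

    def test_constant_indicator_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            permutation_regression(rng.standard_normal(30), np.ones(30))

    def test_beta_equals_ols(self, rng):
        import statsmodels.api as sm

        n = 80
        y = rng.standard_normal(n)
        x = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        res = permutation_regression(y, x, cov, n_permutations=200, seed=0)
        ols = sm.OLS(y, sm.add_constant(np.column_stack([x, cov]))).fit()
        assert res.beta == pytest.approx(ols.params[1], abs=1e-10)
        assert res.se == pytest.approx(ols.bse[1], abs=1e-10)


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(
        n_samples=360,
        planted_cliques=[PlantedClique((0, 1), 0.05, 0.29)],
        missing_rate=0.0,
        seed=5,
    )
    table, meta, truth = generate_cohort(cfg)
    return table, prepare_metadata(meta), truth


class TestStratifiedEffects:
    def test_recovery_within_3se(self, cohort):
        table, meta, truth = cohort
        res = stratified_effects(table, meta, {"ASV0000", "ASV0001"},
                                 n_permutations=200, seed=0)
        for stratum, true_beta in (("secure", 0.05), ("insecure", 0.29)):
            fit = res.results[stratum]
            assert abs(fit.beta - true_beta) <= 3 * fit.se

    def test_forest_table_structure(self, cohort):
        table, meta, _ = cohort
        res = stratified_effects(table, meta, {"ASV0000", "ASV0001"},
                                 n_permutations=200, seed=0)
        tab = res.forest_table()
        assert set(tab["stratum"]) == {"secure", "insecure"}
        assert (tab["null_line"] == 0).all()
        assert ((tab["prevalence_pct"] >= 0) & (tab["prevalence_pct"] <= 100)).all()

    def test_identical_strata_give_identical_betas(self, cohort):
        table, meta, _ = cohort
        half = meta.iloc[:100].copy()
        dup = pd.concat([half.assign(food_insecure=0),
                         half.assign(food_insecure=1)])
        dup.index = [f"d{i}" for i in range(len(dup))]
        both = FeatureTable(
            pd.concat([table.data.iloc[:100]] * 2).set_axis(dup.index)
        )
        res = stratified_effects(both, dup, {"ASV0000", "ASV0001"},
                                 n_permutations=200, seed=1)
        assert res.results["secure"].beta == pytest.approx(
            res.results["insecure"].beta, abs=1e-12
        )

    def test_absent_clique_flagged(self, cohort):
        table, meta, _ = cohort
        absent = table.data.copy()
        absent.loc[meta["food_insecure"] == 1, ["ASV0000", "ASV0001"]] = 0.0
        with pytest.raises(ValueError, match="absent"):
            stratified_effects(FeatureTable(absent), meta,
                               {"ASV0000", "ASV0001"}, n_permutations=200)


class TestCrossStratumValidation:
    def _cohort(self, eff_secure, eff_insecure, seed):
        cfg = SimulationConfig(
            n_samples=360,
            planted_cliques=[PlantedClique((0, 1), eff_secure, eff_insecure)],
            missing_rate=0.0,
            seed=seed,
        )
        table, meta, _ = generate_cohort(cfg)
        return table, prepare_metadata(meta)

    def test_one_sided_effect_rarely_validates(self):
        nonsig = 0
        for seed in range(10):
            table, meta = self._cohort(0.0, 0.6, seed)
            res = cross_stratum_validate(table, meta, {"ASV0000", "ASV0001"},
                                         discovered_in="insecure",
                                         n_permutations=500, seed=seed)
            assert res.stratum == "secure"
            nonsig += res.p_robust > 0.05
        assert nonsig >= 9

    def test_shared_effect_validates_in_both(self):
        sig = 0
        for seed in range(5):
            table, meta = self._cohort(0.5, 0.5, 100 + seed)
            for origin in ("secure", "insecure"):
                res = cross_stratum_validate(table, meta, {"ASV0000", "ASV0001"},
                                             discovered_in=origin,
                                             n_permutations=500, seed=seed)
                sig += res.p_robust < 0.05
        assert sig >= 8  # of 10 regressions

    def test_empty_clique_rejected(self):
        table, meta = self._cohort(0.1, 0.1, 0)
        with pytest.raises(ValueError):
            cross_stratum_validate(table, meta, set(), discovered_in="secure")
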