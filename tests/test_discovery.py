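import numpy as np
import pytest

from mica._forest import WeightedRandomForest
from mica.cohort import PlantedClique, SimulationConfig, generate_cohort
from mica.discovery import (
    Clique,
    CliqueCandidate,
    DiscoveryConfig,
    SignedItem,
    grow_weighted_forest,
    iterate_importance,
    random_intersection_trees,
    repeated_holdout_discovery,
    select_cliques,
    signed_itemsets,
)


def cand(taxa, stability, signs=None):
    items = frozenset(
        SignedItem(t, (signs or {}).get(t, "high")) for t in taxa
    )
    return CliqueCandidate(items=items, stability=stability)


class TestWeightedForest:
    def test_single_weight_forces_feature(self, rng):
        X = rng.random((60, 8))
        y = rng.standard_normal(60)
        w = np.zeros(8)
        w[3] = 1.0
        f = WeightedRandomForest(n_trees=10).fit(X, y, feature_weights=w, seed=0)
        assert f.split_features() <= {3}

    def test_uniform_weights_use_many_features(self, rng):
        X = rng.random((200, 10))
        y = rng.standard_normal(200)
        f = WeightedRandomForest(n_trees=50, mtry=3).fit(X, y, seed=1)
        assert len(f.split_features()) >= 8

    def test_step_function_feature_has_max_importance(self, rng):
        X = rng.random((300, 12))
        y = (X[:, 7] > 0.5).astype(float)
        f = grow_weighted_forest(X, y, n_trees=50, seed=2)
        assert f.feature_importances_.argmax() == 7

    def test_deterministic_under_seed(self, rng):
        X = rng.random((80, 6))
        y = rng.standard_normal(80)
        a = WeightedRandomForest(n_trees=20).fit(X, y, seed=9)
        b = WeightedRandomForest(n_trees=20).fit(X, y, seed=9)
        assert np.array_equal(a.feat_, b.feat_)
        assert np.allclose(a.thr_, b.thr_)
        assert np.allclose(a.predict(X), b.predict(X))

    def test_all_zero_weights_rejected(self, rng):
        X = rng.random((30, 4))
        with pytest.raises(ValueError):
            WeightedRandomForest(n_trees=2).fit(X, X[:, 0], feature_weights=np.zeros(4))

    def test_oob_importance_flags_signal_feature(self, rng):
        X = rng.random((300, 10))
        y = 2.0 * X[:, 4] + 0.1 * rng.standard_normal(300)
        f = WeightedRandomForest(n_trees=100).fit(X, y, seed=3)
        imp = f.oob_permutation_importance(seed=0)
        assert imp.argmax() == 4
        assert imp[4] > 0


class TestIterateImportance:
    def test_single_iteration_is_normalized_uniform_forest_importance(self, rng):
        X = rng.random((150, 8))
        y = X[:, 2] + 0.2 * rng.standard_normal(150)
        w = iterate_importance(X, y, 1, DiscoveryConfig(), seed=5)
        assert w.shape == (8,)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()
        assert w.argmax() == 2

    def test_pure_noise_stays_near_uniform(self, rng):
        # impurity-mode reweighting on pure noise should not concentrate
        ratios = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.random((500, 10))
            y = r.standard_normal(500)
            w = iterate_importance(X, y, 1, DiscoveryConfig(n_iteration_trees=100),
                                   seed=seed, importance="impurity")
            ratios.append(w.max() / w.min())
        assert np.median(ratios) < 5

    def test_interaction_concentrates_weights(self, rng):
        # y depends only on the joint high/high pattern of two features
        # among 50 noise features: their combined weight should dominate
        X = rng.random((400, 52))
        y = ((X[:, 0] > 0.5) & (X[:, 1] > 0.5)).astype(float)
        w = iterate_importance(X, y, 3, DiscoveryConfig(), seed=0)
        assert w[0] + w[1] > 0.5

    def test_zero_iterations_rejected(self, rng):
        with pytest.raises(ValueError):
            iterate_importance(rng.random((30, 3)), rng.standard_normal(30), 0)


class TestSignedItemsets:
    def test_stump_yields_low_and_high(self, rng):
        X = rng.random((100, 1))
        y = (X[:, 0] > 0.5).astype(float)
        f = WeightedRandomForest(n_trees=1, max_depth=1, bootstrap=False).fit(
            X, y, seed=0
        )
        sets = {frozenset(s) for s, _ in signed_itemsets(f, ["f"])}
        assert sets == {
            frozenset({SignedItem("f", "low")}),
            frozenset({SignedItem("f", "high")}),
        }

    def test_depth_two_paths_have_both_features(self, rng):
        X = rng.random((400, 2))
        y = 2.0 * (X[:, 0] > 0.5) + (X[:, 1] > 0.5)
        f = WeightedRandomForest(n_trees=1, max_depth=2, bootstrap=False, mtry=2).fit(
            X, y, seed=1
        )
        sets = [s for s, _ in signed_itemsets(f, ["a", "b"])]
        assert any(len({it.taxon for it in s}) == 2 for s in sets)

    def test_matches_independent_traversal_oracle(self, rng):
        X = rng.random((120, 5))
        y = rng.standard_normal(120)
        f = WeightedRandomForest(n_trees=5).fit(X, y, seed=7)

        def oracle(forest):
            out = []
            for t in range(forest.n_trees):
                def walk(nid, path):
                    feat = forest.feat_[t, nid]
                    if feat < 0:
                        out.append((frozenset(path), int(forest.nnode_[t, nid])))
                        return
                    walk(int(forest.left_[t, nid]), path | {(int(feat), "low")})
                    walk(int(forest.right_[t, nid]), path | {(int(feat), "high")})
                walk(0, frozenset())
            return sorted((tuple(sorted(s)), w) for s, w in out)

        taxa = [0, 1, 2, 3, 4]
        got = sorted(
            (tuple(sorted((it.taxon, it.sign) for it in s)), w)
            for s, w in signed_itemsets(f, taxa)
        )
        assert got == oracle(f)

    def test_leaf_weights_sum_to_training_size_per_tree(self, rng):
        X = rng.random((90, 4))
        f = WeightedRandomForest(n_trees=3).fit(X, rng.standard_normal(90), seed=2)
        total = sum(w for _, w in signed_itemsets(f))
        assert total == 3 * 90


class TestRIT:
    def test_worked_prevalences(self):
        found = random_intersection_trees(
            [frozenset({1, 2}), frozenset({1, 2}), frozenset({1, 3})],
            rit_trees=200, seed=0,
        )
        assert found[frozenset({1, 2})] == pytest.approx(2 / 3)
        assert frozenset({1, 3}) not in found or found[frozenset({1, 3})] == pytest.approx(1 / 3)

    def test_identical_itemsets_survive_with_prevalence_one(self):
        s = frozenset({"a", "b", "c"})
        found = random_intersection_trees([s, s, s], rit_trees=20, seed=1)
        assert found[s] == pytest.approx(1.0)
        assert all(k <= s for k in found)

    def test_disjoint_itemsets_yield_nothing(self):
        found = random_intersection_trees(
            [frozenset({1, 2}), frozenset({3, 4}), frozenset({5, 6})],
            rit_trees=50, seed=2,
        )
        assert found == {}

    def test_prevalence_matches_brute_force(self, rng):
        universe = list(range(6))
        itemsets = [
            frozenset(rng.choice(universe, size=rng.integers(2, 5), replace=False))
            for _ in range(30)
        ]
        found = random_intersection_trees(itemsets, rit_trees=100, seed=3)
        for s, prev in found.items():
            brute = sum(1 for it in itemsets if s <= it) / len(itemsets)
            assert prev == pytest.approx(brute, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            random_intersection_trees([])


class TestSelectCliques:
    def test_overlap_merge_worked_example(self):
        cliques = select_cliques(
            [cand({"A", "B"}, 0.9), cand({"B", "C"}, 0.8), cand({"D", "E"}, 0.7)],
            min_stability=0.6,
        )
        assert [c.taxa for c in cliques] == [("A", "B", "C"), ("D", "E")]
        assert cliques[0].stability == 0.9

    def test_single_candidate(self):
        cliques = select_cliques([cand({"A", "B"}, 0.8)], min_stability=0.5)
        assert [c.taxa for c in cliques] == [("A", "B")]

    def test_all_below_threshold(self):
        assert select_cliques([cand({"A", "B"}, 0.3)], min_stability=0.5) == []

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            assert select_cliques([], 0.5) == []

    def test_raising_threshold_never_adds_cliques(self, rng):
        taxa = list("ABCDEFGH")
        cands = [
            cand(set(rng.choice(taxa, size=2, replace=False)), float(rng.random()))
            for _ in range(15)
        ]
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            got = {c.taxa for c in select_cliques(cands, thr)}
            if prev is not None:
                covered = {t for cl in prev for t in cl}
                assert all(set(cl) <= covered for cl in got)
                assert len(got) <= len(prev) or sum(map(len, got)) <= sum(map(len, prev))
            prev = got


@pytest.fixture(scope="module")
def strong_cohort():
    cfg = SimulationConfig(
        n_samples=150, n_taxa=12, sparsity=0.5, noise_sd=0.2,
        p_food_insecure=0.0, beta_food_insecurity=0.0, covariate_effects={},
        planted_cliques=[PlantedClique((0, 1), 0.8, 0.8)],
        missing_rate=0.0, seed=21,
    )
    return generate_cohort(cfg)


class TestRepeatedHoldout:
    def test_deterministic_under_master_seed(self, strong_cohort):
        table, _, truth = strong_cohort
        cfg = DiscoveryConfig(n_repeats=4, n_bootstraps=3, seed=5)
        a = repeated_holdout_discovery(table.values, truth.latent, cfg,
                                       taxon_ids=table.taxon_ids)
        b = repeated_holdout_discovery(table.values, truth.latent, cfg,
                                       taxon_ids=table.taxon_ids)
        assert [(c.items, c.stability) for c in a] == [(c.items, c.stability) for c in b]

    def test_recovers_strong_planted_pair(self, strong_cohort):
        table, _, truth = strong_cohort
        cfg = DiscoveryConfig(n_repeats=10, n_bootstraps=5, seed=1)
        cands = repeated_holdout_discovery(table.values, truth.latent, cfg,
                                           taxon_ids=table.taxon_ids)
        assert cands, "no candidates on a strong planted clique"
        assert {"ASV0000", "ASV0001"} <= set().union(*(c.taxa for c in cands[:3]))

    def test_stability_bounds_and_ranking(self, strong_cohort):
        table, _, truth = strong_cohort
        cfg = DiscoveryConfig(n_repeats=5, n_bootstraps=3, seed=2)
        cands = repeated_holdout_discovery(table.values, truth.latent, cfg,
                                           taxon_ids=table.taxon_ids)
        stabs = [c.stability for c in cands]
        assert all(0 <= s <= 1 for s in stabs)
        assert stabs == sorted(stabs, reverse=True)
        assert all(len(c.taxa) >= 2 for c in cands)

    def test_too_small_training_partition_rejected(self, rng):
        X = rng.random((20, 5))
        with pytest.raises(ValueError, match="train"):
            repeated_holdout_discovery(
                X, rng.standard_normal(20), DiscoveryConfig(n_repeats=2, n_bootstraps=2)
            )
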