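"""Stage 1 of MiCA: repeated-holdout signed-iterative Random Forest.

Microbial cliques — small sets of taxa whose joint presence pattern
predicts the outcome — are discovered by (i) iteratively reweighting a
regression forest toward informative taxa (iRF), (ii) reading every
root-to-leaf decision path as a *signed itemset* of (taxon, high/low)
pairs, (iii) distilling frequently co-occurring itemsets with random
intersection trees (RIT), and (iv) stabilizing the recovered sets over
many repeated 60/40 train/test holdouts with bootstrap resampling inside
each training partition.  A candidate's stability is the fraction of
repeats in which it is recovered; candidates above a stability threshold
are merged into overlap-connected components (the closed-loop network of
co-occurring taxa) to form the final cliques.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._forest import WeightedRandomForest
from .prep import FeatureTable


@dataclass(frozen=True, order=True)
class SignedItem:
    """A taxon together with the side of the split threshold a decision
    path takes: 'high' (abundance above threshold; with zero-inflated
    relative abundances, effectively presence) or 'low'."""

    taxon: str
    sign: str

    def __post_init__(self):
        if self.sign not in ("low", "high"):
            raise ValueError("sign must be 'low' or 'high'")


@dataclass
class CliqueCandidate:
    """A signed taxon set with its repeated-holdout stability, its
    bootstrap-level support, and its mean prevalence among the RIT
    itemsets that produced it.

    ``stability`` is the fraction of repeated holdouts recovering the set
    (in at least one bootstrap); ``bootstrap_support`` is the fraction of
    all (repeat, bootstrap) runs recovering it — a finer recurrence signal
    used to break ranking ties among sets recovered equally often."""

    items: frozenset
    stability: float
    bootstrap_support: float = 0.0
    mean_prevalence: float = float("nan")

    def __post_init__(self):
        if len(self.items) < 2:
            raise ValueError("a clique candidate needs at least 2 items")
        if not (0.0 <= self.stability <= 1.0):
            raise ValueError("stability must be in [0, 1]")

    @property
    def taxa(self) -> frozenset:
        return frozenset(it.taxon for it in self.items)

    def sort_key(self):
        # rank: stability desc, bootstrap support desc, then larger sets,
        # then lexicographic taxa
        return (
            -self.stability,
            -self.bootstrap_support,
            -len(self.items),
            tuple(sorted(self.taxa)),
        )


@dataclass
class Clique:
    """A merged component of overlapping high-stability candidates."""

    taxa: tuple
    stability: float
    members: list = field(default_factory=list)


@dataclass
class DiscoveryConfig:
    """Knobs of the discovery stage.

    The repeated-holdout scheme defaults to the full-scale protocol (1000
    repeats x 250 bootstraps on a 60/40 partition); ``fast()`` gives the
    desk-scale preset (50 x 20) used for testing and simulation studies.
    Forest and RIT settings follow iRF-literature conventions.
    """

    n_repeats: int = 1000
    n_bootstraps: int = 250
    train_fraction: float = 0.60
    n_irf_iterations: int = 3
    n_trees: int = 100
    #: larger forests for the reweighting iterations and the holdout guard:
    #: importance estimates drive the whole chain, and their Monte-Carlo
    #: noise shrinks with tree count
    n_iteration_trees: int = 300
    max_depth: int = 5
    min_leaf: int = 5
    mtry: int | None = None
    rit_depth: int = 5
    rit_children: int = 2
    rit_trees: int = 50
    min_stability: float = 0.5
    #: uniform mixing weight of the iRF reweighting step; keeps every taxon
    #: sampleable so a taxon with one unlucky importance draw can re-enter
    weight_smoothing: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        for name in (
            "n_repeats",
            "n_bootstraps",
            "n_irf_iterations",
            "n_trees",
            "max_depth",
            "min_leaf",
            "rit_depth",
            "rit_children",
            "rit_trees",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def fast(cls, **overrides) -> "DiscoveryConfig":
        return replace(cls(n_repeats=50, n_bootstraps=20), **overrides)


# ---------------------------------------------------------------------------
# forest growth and iterative reweighting
# ---------------------------------------------------------------------------


def grow_weighted_forest(
    X, y, feature_weights=None, n_trees: int = 100, seed: int = 0, **params
) -> WeightedRandomForest:
    """Grow a regression forest whose node-level candidate split features
    are sampled with probability proportional to ``feature_weights``
    (uniform when None).  Deterministic under a fixed seed."""
    forest = WeightedRandomForest(n_trees=n_trees, **params)
    return forest.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float),
                      feature_weights=feature_weights, seed=seed)


def iterate_importance(X, y, n_iterations: int, config: DiscoveryConfig | None = None,
                       seed: int = 0, importance: str = "oob_permutation") -> np.ndarray:
    """iRF reweighting loop: starting from uniform weights, repeatedly grow
    a weighted forest and replace the weights with its normalized feature
    importances.  Returns the weights after the last iteration.

    The default importance is out-of-bag permutation importance (clipped at
    zero): noise features score ~0 in expectation, so the loop can
    concentrate weight on genuinely predictive taxa even when their
    individual effects are modest.  ``importance='impurity'`` uses the
    split-gain importances instead; these are biased upward for overfit
    noise splits and concentrate far more slowly.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if importance not in ("oob_permutation", "impurity"):
        raise ValueError("importance must be 'oob_permutation' or 'impurity'")
    cfg = config or DiscoveryConfig()
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    weights = np.full(p, 1.0 / p)
    rng = np.random.default_rng(seed)
    for _ in range(n_iterations):
        forest = grow_weighted_forest(
            X,
            y,
            feature_weights=weights,
            n_trees=cfg.n_iteration_trees,
            seed=int(rng.integers(0, 2**31 - 1)),
            max_depth=cfg.max_depth,
            min_leaf=cfg.min_leaf,
            mtry=cfg.mtry,
        )
        if importance == "oob_permutation":
            new = np.clip(
                forest.oob_permutation_importance(seed=int(rng.integers(0, 2**31 - 1))),
                0.0,
                None,
            )
        else:
            new = forest.importances_.copy()
        if new.sum() > 0:
            alpha = cfg.weight_smoothing
            weights = (1.0 - alpha) * (new / new.sum()) + alpha / p
        # else: keep previous weights (pure-noise degenerate forest)
    return weights


# ---------------------------------------------------------------------------
# signed itemsets and random intersection trees
# ---------------------------------------------------------------------------


def _mask_to_items(mask: int, taxon_ids) -> frozenset:
    items = []
    f = 0
    while mask:
        if mask & 1:
            items.append(SignedItem(taxon_ids[f // 2], "high" if f % 2 else "low"))
        mask >>= 1
        f += 1
    return frozenset(items)


def _items_to_mask(items, vocab: dict) -> int:
    mask = 0
    for it in items:
        mask |= 1 << vocab[it]
    return mask


def signed_itemsets(forest: WeightedRandomForest, taxon_ids=None):
    """One signed itemset per leaf of every tree: the deduplicated set of
    (taxon, side) pairs on the root-to-leaf path, weighted by the number of
    training samples reaching the leaf."""
    if taxon_ids is None:
        taxon_ids = [f"T{i}" for i in range(forest.n_features_)]
    return [
        (_mask_to_items(mask, taxon_ids), weight)
        for mask, weight in forest.iter_leaf_paths()
    ]


def _popcount(x: int) -> int:
    return bin(x).count("1")


def _rit_masks(masks, weights, rit_depth, rit_children, rit_trees, rng) -> dict:
    """RIT on bitmask itemsets: returns {mask: prevalence} for surviving
    intersections of size >= 2.  Every non-empty node set at depth >= 1
    (an intersection of at least two sampled itemsets) is a survivor;
    a child never re-samples its parent's own itemset, so a lone itemset
    cannot survive by self-intersection.  Prevalence is the weighted
    fraction of itemsets containing the set."""
    weights = np.asarray(weights, dtype=float)
    total_w = float(np.sum(weights))
    if total_w <= 0 or len(masks) == 0:
        return {}
    cum = np.cumsum(weights) / total_w
    # pre-draw itemset indices in bulk: cheaper than one searchsorted per node
    per_tree = sum(rit_children**d for d in range(rit_depth + 1))
    draws = np.searchsorted(cum, rng.random(2 * rit_trees * per_tree + 16),
                            side="right")
    pos = 0
    n_draws = len(draws)

    def draw(exclude: int) -> int:
        nonlocal pos, draws
        for _ in range(8):
            if pos >= n_draws:
                break
            j = int(draws[pos])
            pos += 1
            if j != exclude:
                return j
        # fall back to direct sampling if the buffer ran dry or kept
        # colliding (e.g., one itemset carries nearly all the weight)
        for _ in range(8):
            j = int(np.searchsorted(cum, rng.random(), side="right"))
            if j != exclude:
                return j
        return -1

    survivors = set()
    for _ in range(rit_trees):
        if pos >= n_draws:
            break
        root_idx = int(draws[pos])
        pos += 1
        stack = [(masks[root_idx], root_idx, 0)]
        while stack:
            node, idx, depth = stack.pop()
            if depth >= rit_depth:
                continue
            for _ in range(rit_children):
                j = draw(exclude=idx)
                if j < 0:
                    continue
                child = node & masks[j]
                if child:
                    if _popcount(child) >= 2:
                        survivors.add(child)
                    stack.append((child, j, depth + 1))

    # merge duplicates for the containment count
    agg: dict = {}
    for m, w in zip(masks, weights):
        agg[m] = agg.get(m, 0.0) + float(w)
    out = {}
    for s in survivors:
        contain = 0.0
        for m, w in agg.items():
            if s & m == s:
                contain += w
        out[s] = contain / total_w
    return out


def random_intersection_trees(
    itemsets, rit_depth: int = 5, rit_children: int = 2, rit_trees: int = 50,
    seed: int = 0,
) -> dict:
    """Random intersection trees over a (possibly weighted) collection of
    itemsets.

    Each RIT node intersects a sampled itemset with its parent's set, down
    to ``rit_depth`` with ``rit_children`` branches per node; sampling is
    proportional to itemset weight (uniform over the weighted multiset).
    Returns {frozenset: prevalence} for surviving sets of size >= 2, where
    prevalence is the weighted fraction of itemsets containing the set.
    """
    if not itemsets:
        raise ValueError("itemsets must be non-empty")
    pairs = [(s, 1.0) if not isinstance(s, tuple) else s for s in itemsets]
    vocab: dict = {}
    for s, _ in pairs:
        for it in s:
            if it not in vocab:
                vocab[it] = len(vocab)
    rev = {v: k for k, v in vocab.items()}
    masks = [_items_to_mask(s, vocab) for s, _ in pairs]
    weights = np.array([w for _, w in pairs], dtype=float)
    rng = np.random.default_rng(seed)
    found = _rit_masks(masks, weights, rit_depth, rit_children, rit_trees, rng)

    def unmask(mask: int) -> frozenset:
        items, f = [], 0
        while mask:
            if mask & 1:
                items.append(rev[f])
            mask >>= 1
            f += 1
        return frozenset(items)

    return {unmask(m): p for m, p in found.items()}


# ---------------------------------------------------------------------------
# repeated-holdout stability loop
# ---------------------------------------------------------------------------


def repeated_holdout_discovery(X, y, config: DiscoveryConfig, taxon_ids=None):
    """Full rh-SiRF discovery: repeated 60/40 holdouts, iRF reweighting on
    each training partition, bootstrap forests feeding RIT, stability
    ranking across repeats.

    A repeat only contributes candidates when the forest grown on its
    training partition achieves a positive prediction-outcome correlation
    on the held-out 40% — a guard against pure-noise discoveries.  A
    candidate's stability is the
    fraction of all repeats in which it is recovered by at least one
    bootstrap.  Returns CliqueCandidates ranked by stability (ties: larger
    sets, then lexicographic taxon IDs).  Deterministic under the master
    seed.
    """
    config.validate()
    if isinstance(X, FeatureTable):
        taxon_ids = X.taxon_ids if taxon_ids is None else taxon_ids
        X = X.values
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if taxon_ids is None:
        taxon_ids = [f"T{i}" for i in range(p)]
    n_train = int(round(config.train_fraction * n))
    if n_train < 20:
        raise ValueError(f"training partition too small (n_train={n_train} < 20)")

    master = np.random.default_rng(config.seed)
    repeat_seeds = master.integers(0, 2**31 - 1, size=config.n_repeats)

    forest_params = dict(max_depth=config.max_depth, min_leaf=config.min_leaf,
                         mtry=config.mtry)
    # candidates are keyed by their (unsigned) taxon set; the split signs
    # are tracked as metadata and the modal sign pattern is reported
    even_mask = sum(1 << (2 * i) for i in range(p))
    hit_counts: dict = {}
    boot_counts: dict = {}
    prev_sum: dict = {}
    prev_n: dict = {}
    sign_votes: dict = {}

    def _taxa_key(signed_mask: int) -> int:
        return (signed_mask | (signed_mask >> 1)) & even_mask

    for r in range(config.n_repeats):
        rng = np.random.default_rng(repeat_seeds[r])
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        Xtr, ytr = X[tr], y[tr]

        weights = iterate_importance(
            Xtr, ytr, config.n_irf_iterations, config,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        guard = grow_weighted_forest(
            Xtr, ytr, weights, n_trees=config.n_iteration_trees,
            seed=int(rng.integers(0, 2**31 - 1)), **forest_params,
        )
        yte = y[te]
        pred = guard.predict(X[te])
        if yte.std() <= 0 or pred.std() <= 0:
            continue
        if float(np.corrcoef(pred, yte)[0, 1]) <= 0.0:
            continue

        repeat_sets: dict = {}
        repeat_signs: dict = {}
        repeat_boot_hits: dict = {}
        for _ in range(config.n_bootstraps):
            bs = rng.integers(0, n_train, size=n_train)
            forest = grow_weighted_forest(
                Xtr[bs], ytr[bs], weights, n_trees=config.n_trees,
                seed=int(rng.integers(0, 2**31 - 1)), **forest_params,
            )
            masks = []
            wts = []
            for mask, w in forest.iter_leaf_paths():
                masks.append(mask)
                wts.append(float(w))
            found = _rit_masks(masks, np.asarray(wts), config.rit_depth,
                               config.rit_children, config.rit_trees, rng)
            boot_keys = set()
            for mask, prev in found.items():
                key = _taxa_key(mask)
                if _popcount(key) < 2:
                    continue  # one taxon with both split sides is not a clique
                boot_keys.add(key)
                if key not in repeat_sets or prev > repeat_sets[key]:
                    repeat_sets[key] = prev
                    repeat_signs[key] = mask
            for key in boot_keys:
                repeat_boot_hits[key] = repeat_boot_hits.get(key, 0) + 1

        for key, prev in repeat_sets.items():
            hit_counts[key] = hit_counts.get(key, 0) + 1
            boot_counts[key] = boot_counts.get(key, 0) + repeat_boot_hits[key]
            prev_sum[key] = prev_sum.get(key, 0.0) + prev
            prev_n[key] = prev_n.get(key, 0) + 1
            votes = sign_votes.setdefault(key, {})
            smask = repeat_signs[key]
            votes[smask] = votes.get(smask, 0) + 1

    candidates = []
    n_runs = config.n_repeats * config.n_bootstraps
    for key in hit_counts:
        votes = sign_votes[key]
        modal_sign = max(votes.items(), key=lambda kv: (kv[1], kv[0]))[0]
        candidates.append(
            CliqueCandidate(
                items=_mask_to_items(modal_sign, taxon_ids),
                stability=hit_counts[key] / config.n_repeats,
                bootstrap_support=boot_counts[key] / n_runs,
                mean_prevalence=prev_sum[key] / prev_n[key],
            )
        )
    candidates.sort(key=CliqueCandidate.sort_key)
    return candidates


def select_cliques(candidates, min_stability: float = 0.5) -> list:
    """Merge high-stability candidates into final cliques.

    Candidates are taken in stability order until stability falls below
    ``min_stability`` (ties broken by larger set size, then lexicographic
    taxon IDs); retained candidates sharing at least one taxon are merged
    into a single overlap-connected component — the closed-loop network of
    co-occurring taxa.  Raising ``min_stability`` can only remove cliques.
    """
    if not candidates:
        warnings.warn("no clique candidates to select from")
        return []
    ranked = sorted(candidates, key=CliqueCandidate.sort_key)
    retained = [c for c in ranked if c.stability >= min_stability]
    if not retained:
        return []

    # union-find over taxa
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for c in retained:
        taxa = sorted(c.taxa)
        for t in taxa:
            parent.setdefault(t, t)
        for t in taxa[1:]:
            union(taxa[0], t)

    comps: dict = {}
    for c in retained:
        root = find(sorted(c.taxa)[0])
        comps.setdefault(root, []).append(c)
    cliques = [
        Clique(
            taxa=tuple(sorted({t for m in members for t in m.taxa})),
            stability=max(m.stability for m in members),
            members=members,
        )
        for members in comps.values()
    ]
    cliques.sort(key=lambda cl: (-cl.stability, cl.taxa))
    return cliques


def candidates_to_frame(candidates) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxa": [",".join(sorted(c.taxa)) for c in candidates],
            "signs": [
                ";".join(f"{it.taxon}:{it.sign}" for it in sorted(c.items))
                for c in candidates
            ],
            "stability": [c.stability for c in candidates],
            "mean_rit_prevalence": [c.mean_prevalence for c in candidates],
        }
    )
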