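"""Weighted-split regression forest kernels.

A small CART-style regression forest in which the candidate split features
at every node are sampled with probability proportional to a supplied
feature-weight vector — the reweighting primitive of the iterative Random
Forest.  scikit-learn's forests cannot weight node-level feature sampling,
and the signed decision-path extraction downstream needs direct access to
the tree arrays, so the trees are built here with numba-jitted kernels.

Split search uses equal-width histogram binning (32 bins per candidate
feature) instead of an exact sort, the standard approximation of
gradient-boosting tree libraries; for zero-inflated abundance features the
first bin boundary is exactly the presence/absence split.  Internal nodes
send ``x < thr`` left ("low" side); ``feat[t, node] == -1`` marks a leaf
predicting ``value[t, node]``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: histogram resolution of the split search
NBINS = 32


@njit(cache=True)
def _sample_features(cum_w, mtry, out):
    """Draw up to ``mtry`` distinct feature indices with probability
    proportional to the weights behind the normalized cumulative ``cum_w``.
    Rejection sampling; zero-weight features are never drawn."""
    count = 0
    attempts = 0
    limit = 20 * mtry + 100
    p = cum_w.shape[0]
    while count < mtry and attempts < limit:
        r = np.random.random()
        f = np.searchsorted(cum_w, r, side="right")
        if f >= p:
            f = p - 1
        dup = False
        for i in range(count):
            if out[i] == f:
                dup = True
                break
        if not dup:
            out[count] = f
            count += 1
        attempts += 1
    return count


@njit(cache=True)
def _build_forest(XT, y, cum_w, mtry, max_depth, min_leaf, n_trees, seed, bootstrap):
    """Grow ``n_trees`` regression trees on histogrammed SSE-reduction
    splits, each tree on its own bootstrap when requested.  ``XT`` is the
    transposed (feature-major) data matrix.  Importances accumulate the
    SSE decrease of every chosen split.  Deterministic under ``seed``."""
    np.random.seed(seed)
    p, n = XT.shape
    max_nodes = 2 ** (max_depth + 1) - 1
    feat = np.full((n_trees, max_nodes), -1, dtype=np.int64)
    thr = np.zeros((n_trees, max_nodes))
    left = np.zeros((n_trees, max_nodes), dtype=np.int64)
    right = np.zeros((n_trees, max_nodes), dtype=np.int64)
    value = np.zeros((n_trees, max_nodes))
    nnode = np.zeros((n_trees, max_nodes), dtype=np.int64)
    ncounts = np.zeros(n_trees, dtype=np.int64)
    importances = np.zeros(p)
    inbag = np.zeros((n_trees, n), dtype=np.int64)

    order = np.empty(n, dtype=np.int64)
    stack = np.empty((max_nodes + 2, 4), dtype=np.int64)
    cand = np.empty(mtry, dtype=np.int64)
    tmp = np.empty(n, dtype=np.int64)
    bin_cnt = np.empty(NBINS, dtype=np.int64)
    bin_sum = np.empty(NBINS)
    bin_ssq = np.empty(NBINS)

    for t in range(n_trees):
        if bootstrap:
            for i in range(n):
                j = np.random.randint(0, n)
                order[i] = j
                inbag[t, j] += 1
        else:
            for i in range(n):
                order[i] = i
                inbag[t, i] += 1

        stack[0, 0] = 0
        stack[0, 1] = 0
        stack[0, 2] = n
        stack[0, 3] = 0
        top = 1
        node_count = 1

        while top > 0:
            top -= 1
            nid = stack[top, 0]
            s = stack[top, 1]
            e = stack[top, 2]
            d = stack[top, 3]
            m = e - s

            sy = 0.0
            syy = 0.0
            for i in range(s, e):
                yi = y[order[i]]
                sy += yi
                syy += yi * yi
            value[t, nid] = sy / m
            nnode[t, nid] = m
            feat[t, nid] = -1
            sse_parent = syy - sy * sy / m

            if d >= max_depth or m < 2 * min_leaf or sse_parent <= 1e-12:
                continue

            k = _sample_features(cum_w, mtry, cand)
            best_gain = 1e-12
            best_f = -1
            best_thr = 0.0
            for ci in range(k):
                f = cand[ci]
                lo = XT[f, order[s]]
                hi = lo
                for i in range(s + 1, e):
                    v = XT[f, order[i]]
                    if v < lo:
                        lo = v
                    elif v > hi:
                        hi = v
                if hi <= lo:
                    continue
                inv = NBINS / (hi - lo)
                for q in range(NBINS):
                    bin_cnt[q] = 0
                    bin_sum[q] = 0.0
                    bin_ssq[q] = 0.0
                for i in range(s, e):
                    q = int((XT[f, order[i]] - lo) * inv)
                    if q >= NBINS:
                        q = NBINS - 1
                    yi = y[order[i]]
                    bin_cnt[q] += 1
                    bin_sum[q] += yi
                    bin_ssq[q] += yi * yi
                cl = 0
                sl = 0.0
                sll = 0.0
                for q in range(NBINS - 1):
                    cl += bin_cnt[q]
                    sl += bin_sum[q]
                    sll += bin_ssq[q]
                    if cl < min_leaf or m - cl < min_leaf:
                        continue
                    sse_l = sll - sl * sl / cl
                    sr = sy - sl
                    srr = syy - sll
                    sse_r = srr - sr * sr / (m - cl)
                    gain = sse_parent - sse_l - sse_r
                    if gain > best_gain:
                        best_gain = gain
                        best_f = f
                        best_thr = lo + (q + 1) * (hi - lo) / NBINS

            if best_f < 0:
                continue

            cnt = 0
            for i in range(s, e):
                if XT[best_f, order[i]] < best_thr:
                    tmp[cnt] = order[i]
                    cnt += 1
            if cnt == 0 or cnt == m:
                continue  # boundary rounding degenerated the split; stay a leaf
            cnt2 = cnt
            for i in range(s, e):
                if XT[best_f, order[i]] >= best_thr:
                    tmp[cnt2] = order[i]
                    cnt2 += 1
            for i in range(m):
                order[s + i] = tmp[i]

            feat[t, nid] = best_f
            thr[t, nid] = best_thr
            importances[best_f] += best_gain
            lid = node_count
            rid = node_count + 1
            node_count += 2
            left[t, nid] = lid
            right[t, nid] = rid
            stack[top, 0] = lid
            stack[top, 1] = s
            stack[top, 2] = s + cnt
            stack[top, 3] = d + 1
            top += 1
            stack[top, 0] = rid
            stack[top, 1] = s + cnt
            stack[top, 2] = e
            stack[top, 3] = d + 1
            top += 1

        ncounts[t] = node_count

    return feat, thr, left, right, value, nnode, ncounts, importances, inbag


@njit(cache=True)
def _oob_perm_importance(XT, y, feat, thr, left, right, value, inbag, seed):
    """Out-of-bag permutation importance: per tree, the increase in OOB
    mean squared error when one feature's OOB values are shuffled, averaged
    over trees.  Noise features score ~0 (often negative); only features a
    tree actually splits on are evaluated for that tree."""
    np.random.seed(seed)
    n_trees, max_nodes = feat.shape
    p, n = XT.shape
    imp = np.zeros(p)
    oob_idx = np.empty(n, dtype=np.int64)
    xs = np.empty(n)
    used = np.zeros(p, dtype=np.uint8)

    for t in range(n_trees):
        m = 0
        for i in range(n):
            if inbag[t, i] == 0:
                oob_idx[m] = i
                m += 1
        if m < 2:
            continue
        base = 0.0
        for ii in range(m):
            i = oob_idx[ii]
            nid = 0
            while feat[t, nid] >= 0:
                if XT[feat[t, nid], i] < thr[t, nid]:
                    nid = left[t, nid]
                else:
                    nid = right[t, nid]
            d = y[i] - value[t, nid]
            base += d * d
        base /= m

        for f in range(p):
            used[f] = 0
        for nid in range(max_nodes):
            if feat[t, nid] >= 0:
                used[feat[t, nid]] = 1

        for f in range(p):
            if used[f] == 0:
                continue
            for ii in range(m):
                xs[ii] = XT[f, oob_idx[ii]]
            for ii in range(m - 1, 0, -1):
                jj = np.random.randint(0, ii + 1)
                tmpv = xs[ii]
                xs[ii] = xs[jj]
                xs[jj] = tmpv
            err = 0.0
            for ii in range(m):
                i = oob_idx[ii]
                nid = 0
                while feat[t, nid] >= 0:
                    ff = feat[t, nid]
                    if ff == f:
                        v = xs[ii]
                    else:
                        v = XT[ff, i]
                    if v < thr[t, nid]:
                        nid = left[t, nid]
                    else:
                        nid = right[t, nid]
                d = y[i] - value[t, nid]
                err += d * d
            imp[f] += err / m - base
    return imp / n_trees


@njit(cache=True)
def _forest_predict(X, feat, thr, left, right, value):
    n_trees = feat.shape[0]
    out = np.zeros(X.shape[0])
    for t in range(n_trees):
        for i in range(X.shape[0]):
            nid = 0
            while feat[t, nid] >= 0:
                if X[i, feat[t, nid]] < thr[t, nid]:
                    nid = left[t, nid]
                else:
                    nid = right[t, nid]
            out[i] += value[t, nid]
    return out / n_trees


class WeightedRandomForest:
    """Regression forest with feature-weighted split sampling.

    Parameters follow iRF-literature defaults: 100 trees, depth 5, minimum
    leaf 5, mtry = ceil(sqrt(p)).  Each tree is grown on a bootstrap of the
    fitting data (standard bagging); determinism is guaranteed under a
    fixed ``seed``.
    """

    def __init__(self, n_trees=100, max_depth=5, min_leaf=5, mtry=None, bootstrap=True):
        self.n_trees = int(n_trees)
        self.max_depth = int(max_depth)
        self.min_leaf = int(min_leaf)
        self.mtry = mtry
        self.bootstrap = bool(bootstrap)
        self.n_features_ = None
        self.importances_ = None

    def fit(self, X, y, feature_weights=None, seed=0):
        X = np.asarray(X, dtype=np.float64)
        XT = np.ascontiguousarray(X.T)
        y = np.ascontiguousarray(y, dtype=np.float64)
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if feature_weights is None:
            w = np.full(p, 1.0 / p)
        else:
            w = np.asarray(feature_weights, dtype=np.float64)
            if w.shape != (p,):
                raise ValueError("feature_weights must have one entry per feature")
            if (w < 0).any():
                raise ValueError("feature_weights must be nonnegative")
            total = w.sum()
            if total <= 0:
                raise ValueError("feature_weights must not be all zero")
            w = w / total
        cum_w = np.cumsum(w)
        cum_w[-1] = 1.0

        mtry = self.mtry if self.mtry is not None else int(np.ceil(np.sqrt(p)))
        mtry = max(1, min(int(mtry), p))

        (
            self.feat_,
            self.thr_,
            self.left_,
            self.right_,
            self.value_,
            self.nnode_,
            self.ncounts_,
            self.importances_,
            self.inbag_,
        ) = _build_forest(
            XT, y, cum_w, mtry, self.max_depth, self.min_leaf,
            self.n_trees, int(seed) % (2**32 - 1), self.bootstrap,
        )
        self.n_features_ = p
        self._XT = XT
        self._y = y
        return self

    def oob_permutation_importance(self, seed: int = 0) -> np.ndarray:
        """OOB permutation importance on the fitting data (MSE increase per
        feature when its out-of-bag values are shuffled)."""
        if not self.bootstrap:
            raise ValueError("OOB importance requires bootstrap=True")
        return _oob_perm_importance(
            self._XT, self._y, self.feat_, self.thr_, self.left_, self.right_,
            self.value_, self.inbag_, int(seed) % (2**32 - 1),
        )

    def predict(self, X):
        X = np.ascontiguousarray(X, dtype=np.float64)
        return _forest_predict(
            X, self.feat_, self.thr_, self.left_, self.right_, self.value_
        )

    @property
    def feature_importances_(self):
        total = self.importances_.sum()
        if total <= 0:
            return np.full(self.n_features_, 1.0 / self.n_features_)
        return self.importances_ / total

    def split_features(self):
        """Set of feature indices used by any split in the forest."""
        used = set()
        for t in range(self.n_trees):
            for nid in range(self.ncounts_[t]):
                if self.feat_[t, nid] >= 0:
                    used.add(int(self.feat_[t, nid]))
        return used

    def iter_leaf_paths(self):
        """Yield (signed_mask, n_training_samples) per leaf of every tree.

        The mask sets bit ``2*f`` when the path takes the low (<) side of a
        split on feature f and bit ``2*f + 1`` for the high side; a feature
        appearing twice on one path with the same side is recorded once.
        Masks are Python ints, so any number of features is supported.
        """
        feat, left, right, nnode = self.feat_, self.left_, self.right_, self.nnode_
        for t in range(self.n_trees):
            stack = [(0, 0)]
            while stack:
                nid, mask = stack.pop()
                f = feat[t, nid]
                if f < 0:
                    yield mask, int(nnode[t, nid])
                    continue
                stack.append((int(left[t, nid]), mask | (1 << int(2 * f))))
                stack.append((int(right[t, nid]), mask | (1 << int(2 * f + 1))))
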