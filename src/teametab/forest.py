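"""Small random-forest regression engine with OOB permutation importance.

Stage modelling needs, per fitted forest: the out-of-bag (OOB) R2 and the
percentage increase in OOB mean squared error when each feature's values
are permuted (%IncMSE) — and it needs them for thousands of refits under
permuted responses.  General-purpose forest implementations expose neither
the OOB importance nor fit fast enough at that scale (samples here number
in the tens), so the whole fit/OOB/importance path is a single compiled
kernel specialised for small n:

* CART regression trees grown to purity on bootstrap samples, best split
  by SSE reduction among ``mtry`` randomly drawn features;
* OOB predictions accumulated per sample across trees (for R2);
* importance evaluated per tree only for the features that tree actually
  splits on — permuting a feature a tree never consults cannot change its
  predictions — which turns a p-sized loop into a tree-depth-sized one.

%IncMSE is aggregated at the forest level:
``100 * (sum_t SSE_t(feature permuted) - sum_t SSE_t) / sum_t SSE_t``
over each tree's OOB set, with unpermuted SSE substituted for trees that
do not use the feature.  Features used by no tree get exactly 0.

Everything is a pure function of (X, y, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@njit(cache=True)
def _forest_kernel(X, y, n_trees, mtry, seed, compute_importance):  # pragma: no cover
    n, p = X.shape
    np.random.seed(seed)
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, np.int64)
    sse_base_tot = 0.0
    sse_perm_tot = np.zeros(p)
    max_nodes = 2 * n + 1
    feat = np.empty(max_nodes, np.int64)
    thr = np.zeros(max_nodes)
    left = np.zeros(max_nodes, np.int64)
    right = np.zeros(max_nodes, np.int64)
    val = np.zeros(max_nodes)
    idx = np.empty(n, np.int64)
    stack = np.empty((max_nodes, 3), np.int64)
    cand = np.arange(p)
    inb = np.zeros(n, np.bool_)
    used = np.zeros(p, np.bool_)
    sidx = np.empty(n, np.int64)
    bidx = np.empty(n, np.int64)
    for _t in range(n_trees):
        for i in range(n):
            inb[i] = False
        for i in range(n):
            j = np.random.randint(0, n)
            idx[i] = j
            inb[j] = True
        for i in range(p):
            used[i] = False
        n_nodes = 1
        stack[0, 0] = 0
        stack[0, 1] = n
        stack[0, 2] = 0
        top = 1
        while top > 0:
            top -= 1
            s = stack[top, 0]
            e = stack[top, 1]
            node = stack[top, 2]
            m = e - s
            ysum = 0.0
            for i in range(s, e):
                ysum += y[idx[i]]
            mean = ysum / m
            sse = 0.0
            for i in range(s, e):
                d = y[idx[i]] - mean
                sse += d * d
            feat[node] = -1
            val[node] = mean
            if m < 2 or sse <= 1e-12:
                continue
            best_gain = -1.0
            best_f = -1
            best_thr = 0.0
            for k in range(mtry):
                r = k + np.random.randint(0, p - k)
                tmp = cand[k]
                cand[k] = cand[r]
                cand[r] = tmp
                f = cand[k]
                for i in range(m):
                    sidx[i] = idx[s + i]
                for i in range(1, m):
                    a = sidx[i]
                    xa = X[a, f]
                    j = i - 1
                    while j >= 0 and X[sidx[j], f] > xa:
                        sidx[j + 1] = sidx[j]
                        j -= 1
                    sidx[j + 1] = a
                sl = 0.0
                for i in range(m - 1):
                    sl += y[sidx[i]]
                    if X[sidx[i + 1], f] > X[sidx[i], f]:
                        nl = i + 1
                        nr = m - nl
                        sr = ysum - sl
                        gain = sl * sl / nl + sr * sr / nr
                        if gain > best_gain:
                            best_gain = gain
                            best_f = f
                            best_thr = 0.5 * (X[sidx[i], f] + X[sidx[i + 1], f])
            if best_f < 0:
                continue
            nl = 0
            for i in range(s, e):
                a = idx[i]
                if X[a, best_f] <= best_thr:
                    bidx[nl] = a
                    nl += 1
            nr = nl
            for i in range(s, e):
                a = idx[i]
                if X[a, best_f] > best_thr:
                    bidx[nr] = a
                    nr += 1
            for i in range(m):
                idx[s + i] = bidx[i]
            feat[node] = best_f
            thr[node] = best_thr
            left[node] = n_nodes
            right[node] = n_nodes + 1
            used[best_f] = True
            stack[top, 0] = s
            stack[top, 1] = s + nl
            stack[top, 2] = n_nodes
            top += 1
            stack[top, 0] = s + nl
            stack[top, 1] = e
            stack[top, 2] = n_nodes + 1
            top += 1
            n_nodes += 2
        # OOB predictions and per-tree baseline SSE
        n_oob = 0
        sse_base = 0.0
        for i in range(n):
            if not inb[i]:
                node = 0
                while feat[node] >= 0:
                    if X[i, feat[node]] <= thr[node]:
                        node = left[node]
                    else:
                        node = right[node]
                pred = val[node]
                oob_sum[i] += pred
                oob_cnt[i] += 1
                d = y[i] - pred
                sse_base += d * d
                sidx[n_oob] = i
                n_oob += 1
        sse_base_tot += sse_base
        if compute_importance:
            for f in range(p):
                sse_perm_tot[f] += sse_base
            if n_oob > 1:
                for f in range(p):
                    if not used[f]:
                        continue
                    perm = np.random.permutation(n_oob)
                    sse_f = 0.0
                    for q in range(n_oob):
                        i = sidx[q]
                        xsub = X[sidx[perm[q]], f]
                        node = 0
                        while feat[node] >= 0:
                            ff = feat[node]
                            xv = xsub if ff == f else X[i, ff]
                            if xv <= thr[node]:
                                node = left[node]
                            else:
                                node = right[node]
                        d = y[i] - val[node]
                        sse_f += d * d
                    sse_perm_tot[f] += sse_f - sse_base
    return oob_sum, oob_cnt, sse_base_tot, sse_perm_tot


@dataclass
class ForestFit:
    """A fitted regression forest summarised by its OOB statistics."""

    n_trees: int
    mtry: int
    seed: int
    oob_prediction: np.ndarray
    oob_r2: float
    inc_mse: np.ndarray | None  # %IncMSE per feature, None if not computed


def resolve_mtry(p: int, max_features) -> int:
    """Translate a max_features rule into a feature count.

    ``"third"`` (the regression-forest convention) gives floor(p/3),
    ``"sqrt"`` gives floor(sqrt(p)); ints pass through, floats are
    fractions of p.  Always at least 1 and at most p.
    """
    if max_features == "third":
        mtry = p // 3
    elif max_features == "sqrt":
        mtry = int(np.sqrt(p))
    elif isinstance(max_features, float):
        mtry = int(max_features * p)
    else:
        mtry = int(max_features)
    return max(1, min(p, mtry))


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 1000,
    max_features="third",
    seed: int = 0,
    compute_importance: bool = True,
) -> ForestFit:
    """Fit a seeded regression forest; return OOB R2 and %IncMSE.

    ``X`` is samples x features.  OOB R2 is 1 - MSE(oob)/Var(y) using
    per-sample OOB predictions averaged over the trees for which the
    sample was out of bag (samples never OOB are skipped from both sums).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n, p = X.shape
    if n != len(y):
        raise ValueError("X and y disagree on sample count")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; regression is undefined")
    if not np.isfinite(X).all():
        raise ValueError("X contains missing or non-finite intensities")
    mtry = resolve_mtry(p, max_features)
    oob_sum, oob_cnt, sse_base, sse_perm = _forest_kernel(
        X, y, n_trees, mtry, seed % (2**31), compute_importance
    )
    seen = oob_cnt > 0
    pred = np.full(n, np.nan)
    pred[seen] = oob_sum[seen] / oob_cnt[seen]
    resid = np.sum((y[seen] - pred[seen]) ** 2)
    total = np.sum((y[seen] - y[seen].mean()) ** 2)
    r2 = 1.0 - resid / total if total > 0 else np.nan
    inc_mse = None
    if compute_importance:
        inc_mse = (
            100.0 * (sse_perm - sse_base) / sse_base
            if sse_base > 0
            else np.zeros(p)
        )
    return ForestFit(
        n_trees=n_trees,
        mtry=mtry,
        seed=seed,
        oob_prediction=pred,
        oob_r2=float(r2),
        inc_mse=inc_mse,
    )
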