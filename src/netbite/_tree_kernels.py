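"""Compiled kernels for biased CART growth.

Everything that touches per-node work (weighted feature subsetting, the
variance-reduction split search, tree growth and traversal) lives here as
numba ``@njit`` functions so that ensembles with hundreds of trees and
mtry up to the full gene count stay fast on one CPU.  The public API in
:mod:`netbite.ensemble` wraps these kernels; the split-scan logic is a
single function (`_scan_sorted_feature`) shared by the standalone split
search and the tree grower, so there is no second implementation of the
same criterion.

Tree growth presorts every feature once per tree and keeps the
per-feature sorted sample order consistent through node partitions
(the classic CART presort scheme), which removes all per-node sorting.

Conventions:
- trees are stored flat: ``feature[i] == -1`` marks a leaf, otherwise
  ``feature``/``threshold``/``left``/``right`` describe an internal node;
  ``value`` holds the node mean (the prediction, for leaves), ``n_node``
  the training-sample count.
- RNG: numba's global NumPy-legacy state, seeded once per kernel call.
  Draw order inside a tree is fixed (LIFO stack, left child first), so a
  given seed yields a bit-identical tree.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# sentinel for "no split found"
NO_FEATURE = -1


@njit(cache=True)
def weighted_subset(weights, mtry):
    """Draw ``mtry`` distinct indices, sequentially, proportional to the
    remaining (not-yet-drawn) weights.  Caller must have seeded the RNG
    and guaranteed at least ``mtry`` strictly positive weights."""
    m = weights.shape[0]
    w = weights.copy()
    out = np.empty(mtry, dtype=np.int64)
    total = 0.0
    for i in range(m):
        total += w[i]
    for t in range(mtry):
        r = np.random.random() * total
        acc = 0.0
        idx = -1
        for i in range(m):
            wi = w[i]
            if wi > 0.0:
                acc += wi
                if r < acc:
                    idx = i
                    break
        if idx < 0:
            # float round-off pushed r past the running sum: take the
            # last positive-weight index.
            for i in range(m - 1, -1, -1):
                if w[i] > 0.0:
                    idx = i
                    break
        out[t] = idx
        total -= w[idx]
        w[idx] = 0.0
    return out


@njit(cache=True)
def weighted_subset_seeded(weights, mtry, seed):
    np.random.seed(seed)
    return weighted_subset(weights, mtry)


@njit(cache=True)
def weighted_subset_counts(weights, mtry, n_draws, seed):
    """Inclusion counts over repeated subset draws (test helper)."""
    np.random.seed(seed)
    m = weights.shape[0]
    counts = np.zeros(m, dtype=np.int64)
    for _ in range(n_draws):
        sub = weighted_subset(weights, mtry)
        for j in range(mtry):
            counts[sub[j]] += 1
    return counts


@njit(cache=True)
def _scan_sorted_feature(vs, ys, s1, s2, tps, f, best_f, best_thr, best_loss):
    """Scan one candidate feature, values presorted ascending.

    ``vs``/``ys`` are the node's feature values and responses in sorted
    order; ``s1``/``s2`` the node response sum and sum of squares.
    Thresholds are midpoints between consecutive distinct values; a
    split is legal when both children hold >= ``tps`` samples; the loss
    is the summed child SSE (child-size-weighted sum of variances).
    Ties break toward the lower feature index, then lower threshold.
    Returns the updated ``(best_f, best_thr, best_loss)``.
    """
    n = vs.shape[0]
    l1 = 0.0
    l2 = 0.0
    for p in range(n - 1):
        yp = ys[p]
        l1 += yp
        l2 += yp * yp
        n_left = p + 1
        if n_left < tps:
            continue
        n_right = n - n_left
        if n_right < tps:
            break
        if vs[p] == vs[p + 1]:
            continue
        loss_left = l2 - l1 * l1 / n_left
        r1 = s1 - l1
        r2 = s2 - l2
        loss_right = r2 - r1 * r1 / n_right
        loss = loss_left + loss_right
        if loss < 0.0:
            loss = 0.0
        thr = 0.5 * (vs[p] + vs[p + 1])
        if (loss < best_loss) or (
            loss == best_loss
            and (f < best_f or (f == best_f and thr < best_thr))
        ):
            best_loss = loss
            best_f = f
            best_thr = thr
    return best_f, best_thr, best_loss


@njit(cache=True)
def best_split_kernel(X, y, idx, cand, tps):
    """Exhaustive variance-reduction split search at one node.

    Returns ``(feature, threshold, loss, parent_sse)``;
    ``feature == NO_FEATURE`` means no legal loss-reducing split exists.
    """
    n = idx.shape[0]
    s1 = 0.0
    s2 = 0.0
    for i in range(n):
        yi = y[idx[i]]
        s1 += yi
        s2 += yi * yi
    parent_sse = s2 - s1 * s1 / n
    if parent_sse < 0.0:
        parent_sse = 0.0

    best_f = NO_FEATURE
    best_thr = np.nan
    best_loss = np.inf
    if n < 2 * tps or parent_sse <= 0.0:
        return best_f, best_thr, best_loss, parent_sse

    v = np.empty(n, dtype=np.float64)
    vs = np.empty(n, dtype=np.float64)
    ys = np.empty(n, dtype=np.float64)
    for c in range(cand.shape[0]):
        f = cand[c]
        for i in range(n):
            v[i] = X[idx[i], f]
        order = np.argsort(v)
        for i in range(n):
            vs[i] = v[order[i]]
            ys[i] = y[idx[order[i]]]
        best_f, best_thr, best_loss = _scan_sorted_feature(
            vs, ys, s1, s2, tps, f, best_f, best_thr, best_loss
        )
    # require a strict reduction over leaving the node whole
    if best_f != NO_FEATURE:
        tol = 1e-12 * (1.0 + parent_sse)
        if not (best_loss < parent_sse - tol):
            best_f = NO_FEATURE
            best_thr = np.nan
            best_loss = np.inf
    return best_f, best_thr, best_loss, parent_sse


@njit(cache=True)
def grow_tree(
    X,
    y,
    sample_idx,
    weights,
    mtry,
    tps,
    seed,
    feature,
    threshold,
    left,
    right,
    value,
    n_node,
):
    """Grow one CART regression tree with per-node biased feature subsets.

    ``sample_idx`` is the (possibly bootstrapped) training-sample index
    vector.  Output arrays must be preallocated with at least
    ``2 * len(sample_idx) - 1`` slots (worst case at tps=1); returns the
    number of nodes written.
    """
    np.random.seed(seed)
    n = sample_idx.shape[0]
    m = X.shape[1]

    # materialize the bootstrap draw, features contiguous per row
    xbt = np.empty((m, n), dtype=np.float64)
    yb = np.empty(n, dtype=np.float64)
    for i in range(n):
        si = sample_idx[i]
        yb[i] = y[si]
        for f in range(m):
            xbt[f, i] = X[si, f]

    # Two bookkeeping modes with identical split semantics: when mtry is
    # a sizable fraction of m, presort every feature once and keep the
    # per-feature order through (stable) partitions; when mtry is small,
    # presorting costs more than it saves, so keep a single member list
    # and argsort candidates per node.
    use_presort = mtry * 8 >= m
    n_rows = m if use_presort else 1
    sorted_pos = np.empty((n_rows, n), dtype=np.int64)
    if use_presort:
        for f in range(m):
            sorted_pos[f] = np.argsort(xbt[f])
    else:
        sorted_pos[0] = np.arange(n)

    full_subset = mtry == m  # every positive-weight gene is drawn anyway
    cand_all = np.arange(m)

    max_nodes = feature.shape[0]
    stack_node = np.empty(max_nodes, dtype=np.int64)
    stack_lo = np.empty(max_nodes, dtype=np.int64)
    stack_hi = np.empty(max_nodes, dtype=np.int64)

    node_count = 1
    top = 0
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n
    tmp = np.empty(n, dtype=np.int64)
    go_left = np.empty(n, dtype=np.bool_)
    vs = np.empty(n, dtype=np.float64)
    ys = np.empty(n, dtype=np.float64)

    while top >= 0:
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        top -= 1
        m_seg = hi - lo

        s1 = 0.0
        s2 = 0.0
        row0 = sorted_pos[0]
        for i in range(lo, hi):
            yi = yb[row0[i]]
            s1 += yi
            s2 += yi * yi
        value[node] = s1 / m_seg
        n_node[node] = m_seg
        feature[node] = NO_FEATURE
        threshold[node] = np.nan
        left[node] = -1
        right[node] = -1

        parent_sse = s2 - s1 * s1 / m_seg
        if m_seg < 2 * tps or parent_sse <= 0.0:
            continue
        cand = cand_all if full_subset else weighted_subset(weights, mtry)

        best_f = NO_FEATURE
        best_thr = np.nan
        best_loss = np.inf
        for c in range(cand.shape[0]):
            f = cand[c]
            if use_presort:
                row = sorted_pos[f]
                for i in range(m_seg):
                    p = row[lo + i]
                    vs[i] = xbt[f, p]
                    ys[i] = yb[p]
            else:
                row = sorted_pos[0]
                for i in range(m_seg):
                    vs[i] = xbt[f, row[lo + i]]
                order = np.argsort(vs[:m_seg])
                for i in range(m_seg):
                    p = row[lo + order[i]]
                    ys[i] = yb[p]
                for i in range(m_seg):
                    vs[i] = xbt[f, row[lo + order[i]]]
            best_f, best_thr, best_loss = _scan_sorted_feature(
                vs[:m_seg], ys[:m_seg], s1, s2, tps, f,
                best_f, best_thr, best_loss,
            )
        if best_f != NO_FEATURE:
            tol = 1e-12 * (1.0 + parent_sse)
            if not (best_loss < parent_sse - tol):
                best_f = NO_FEATURE
        if best_f == NO_FEATURE:
            continue

        # membership flags, then a stable partition of every kept row
        n_left = 0
        rowb = sorted_pos[best_f] if use_presort else sorted_pos[0]
        for i in range(lo, hi):
            p = rowb[i]
            is_left = xbt[best_f, p] <= best_thr
            go_left[p] = is_left
            if is_left:
                n_left += 1
        for f in range(n_rows):
            row = sorted_pos[f]
            a = lo
            k = 0
            for i in range(lo, hi):
                p = row[i]
                if go_left[p]:
                    row[a] = p
                    a += 1
                else:
                    tmp[k] = p
                    k += 1
            for i in range(k):
                row[a + i] = tmp[i]

        lid = node_count
        rid = node_count + 1
        node_count += 2
        feature[node] = best_f
        threshold[node] = best_thr
        left[node] = lid
        right[node] = rid
        # push right first so the left child is processed first (LIFO):
        # fixes RNG consumption order → determinism.
        top += 1
        stack_node[top] = rid
        stack_lo[top] = lo + n_left
        stack_hi[top] = hi
        top += 1
        stack_node[top] = lid
        stack_lo[top] = lo
        stack_hi[top] = lo + n_left
    return node_count


@njit(cache=True)
def predict_tree(X, feature, threshold, left, right, value, out):
    n = X.shape[0]
    for i in range(n):
        node = 0
        while feature[node] != NO_FEATURE:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]
    return out
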