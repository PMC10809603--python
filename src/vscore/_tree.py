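"""Low-level numba kernels for the cluster-aware honest regression forest.

A forest is stored as flat parallel arrays over nodes of all trees:

* ``feat``     int32   split variable index, ``-1`` for a leaf
* ``thr``      float64 split threshold (go left when ``x <= thr``)
* ``missl``    uint8   1 if missing values are routed left at this split
* ``lchild``   int32   tree-local index of the left child
* ``rchild``   int32   tree-local index of the right child
* ``val``      float64 node value (weighted outcome mean of estimation rows)
* ``offsets``  int64   ``offsets[t]`` = index of tree ``t``'s root; length n_trees+1
* ``clmat``    uint8   (n_trees, n_clusters) indicator of clusters in each tree's subsample

Split search maximizes the weighted between-child criterion
``WL*WR/(WL+WR) * (muL - muR)^2`` over midpoint thresholds of every candidate
variable, evaluating both missing-routing directions (missingness incorporated
in attributes). Ties are broken by lowest variable index, then smallest
threshold, then missing-left — all deterministic given the seed.
"""

import numpy as np
from numba import njit

LEAF = -1

# criterion must exceed this to produce a split; a constant-outcome node
# yields criterion ~ float rounding noise (<1e-30), well below.
_MIN_CRIT = 1e-12


@njit(cache=True)
def _partial_shuffle(arr, m):
    """Fisher-Yates the first m slots of arr in place (sampling w/o replacement)."""
    n = arr.shape[0]
    for i in range(m):
        j = i + np.random.randint(0, n - i)
        t = arr[i]
        arr[i] = arr[j]
        arr[j] = t


@njit(cache=True)
def fit_forest(X, y, w, cl_order, cl_start,
               n_trees, n_cl_samp, spc, honesty, hfrac,
               min_node, mtry, max_depth, seed):
    n, p = X.shape
    n_clusters = cl_start.shape[0] - 1

    cap = n_trees * (2 * n + 1)
    feat = np.full(cap, -1, np.int32)
    thr = np.zeros(cap)
    missl = np.zeros(cap, np.uint8)
    lchild = np.full(cap, -1, np.int32)
    rchild = np.full(cap, -1, np.int32)
    val = np.zeros(cap)
    offsets = np.zeros(n_trees + 1, np.int64)
    clmat = np.zeros((n_trees, n_clusters), np.uint8)

    # workspaces reused across trees
    clus_pool = np.empty(n_clusters, np.int64)
    rows = np.empty(n, np.int64)
    sidx = np.empty(n, np.int64)
    buf_l = np.empty(n, np.int64)
    buf_r = np.empty(n, np.int64)
    tmp = np.empty(n, np.int64)
    vals = np.empty(n)
    svals = np.empty(n)
    wv = np.empty(n)
    wyv = np.empty(n)
    cw = np.empty(n)
    cwy = np.empty(n)
    max_nodes = 2 * n + 1
    stack_node = np.empty(max_nodes, np.int64)
    stack_a = np.empty(max_nodes, np.int64)
    stack_b = np.empty(max_nodes, np.int64)
    stack_d = np.empty(max_nodes, np.int64)
    parent = np.empty(max_nodes, np.int64)
    wsum = np.empty(max_nodes)
    wysum = np.empty(max_nodes)
    fpool = np.empty(p, np.int64)

    # instrumentation: tree 0's subsample rows and half assignment
    # (1 = split half, 2 = estimation half), for honesty diagnostics
    dbg_half = np.zeros(n, np.int8)

    pos = 0
    for t in range(n_trees):
        offsets[t] = pos
        # per-tree seed: trees must be independent RNG streams so that one
        # tree's (data-dependent) number of draws cannot shift another tree's
        # randomness — OOB-by-cluster invariance relies on this
        np.random.seed((seed + (t + 1) * 2654435761) % 2147483647)

        # --- subsample clusters, then rows within clusters -------------------
        for c in range(n_clusters):
            clus_pool[c] = c
        _partial_shuffle(clus_pool, n_cl_samp)
        k = spc
        if k <= 0:  # default: size of smallest sampled cluster
            k = n
            for ci in range(n_cl_samp):
                c = clus_pool[ci]
                sz = cl_start[c + 1] - cl_start[c]
                if sz < k:
                    k = sz
        ns = 0
        for ci in range(n_cl_samp):
            c = clus_pool[ci]
            clmat[t, c] = 1
            s0 = cl_start[c]
            sz = cl_start[c + 1] - s0
            kk = k if k < sz else sz
            for i in range(sz):
                tmp[i] = cl_order[s0 + i]
            _partial_shuffle(tmp[:sz], kk)
            for i in range(kk):
                rows[ns] = tmp[i]
                ns += 1

        # --- honesty: disjoint split / estimation halves ---------------------
        _partial_shuffle(rows[:ns], ns)
        if honesty and ns >= 2:
            n_split = int(np.ceil(hfrac * ns))
            if n_split >= ns:
                n_split = ns - 1
            if n_split < 1:
                n_split = 1
            e0, e1 = n_split, ns
        else:
            n_split = ns
            e0, e1 = 0, ns
        for i in range(n_split):
            sidx[i] = rows[i]
        if t == 0:
            for i in range(n_split):
                dbg_half[rows[i]] = 1
            for i in range(e0, e1):
                dbg_half[rows[i]] = 2

        # --- grow ------------------------------------------------------------
        n_nodes = 1
        parent[0] = -1
        top = 0
        stack_node[0] = 0
        stack_a[0] = 0
        stack_b[0] = n_split
        stack_d[0] = 1
        while top >= 0:
            node = stack_node[top]
            a = stack_a[top]
            b = stack_b[top]
            d = stack_d[top]
            top -= 1
            g = pos + node
            m_node = b - a

            best_crit = _MIN_CRIT
            best_f = -1
            best_thr = 0.0
            best_ml = np.uint8(0)
            if m_node >= 2 * min_node and (max_depth <= 0 or d <= max_depth):
                for f in range(p):
                    fpool[f] = f
                _partial_shuffle(fpool, mtry)
                # evaluate candidates in ascending variable index (tie-break)
                fsub = np.sort(fpool[:mtry].copy())
                for fi in range(mtry):
                    f = fsub[fi]
                    m = 0
                    Wm = 0.0
                    Sm = 0.0
                    cntm = 0
                    for ii in range(a, b):
                        r = sidx[ii]
                        v = X[r, f]
                        if np.isnan(v):
                            Wm += w[r]
                            Sm += w[r] * y[r]
                            cntm += 1
                        else:
                            vals[m] = v
                            wv[m] = w[r]
                            wyv[m] = w[r] * y[r]
                            m += 1
                    if m < 2:
                        continue
                    order = np.argsort(vals[:m].copy())
                    acc_w = 0.0
                    acc_wy = 0.0
                    for i2 in range(m):
                        o = order[i2]
                        svals[i2] = vals[o]
                        acc_w += wv[o]
                        acc_wy += wyv[o]
                        cw[i2] = acc_w
                        cwy[i2] = acc_wy
                    Wtot = cw[m - 1] + Wm
                    Stot = cwy[m - 1] + Sm
                    cnt_tot = m + cntm
                    for i2 in range(m - 1):
                        if svals[i2 + 1] <= svals[i2]:
                            continue
                        tcand = 0.5 * (svals[i2] + svals[i2 + 1])
                        if tcand >= svals[i2 + 1]:  # midpoint rounded up
                            continue
                        Wl0 = cw[i2]
                        Sl0 = cwy[i2]
                        for dirm in range(2):  # 0: missing left, 1: missing right
                            if dirm == 0:
                                Wl = Wl0 + Wm
                                Sl = Sl0 + Sm
                                cl_ = i2 + 1 + cntm
                            else:
                                Wl = Wl0
                                Sl = Sl0
                                cl_ = i2 + 1
                            cr_ = cnt_tot - cl_
                            if cl_ < min_node or cr_ < min_node:
                                if cntm == 0:
                                    break
                                continue
                            Wr = Wtot - Wl
                            Sr = Stot - Sl
                            if Wl <= 0.0 or Wr <= 0.0:
                                if cntm == 0:
                                    break
                                continue
                            dmu = Sl / Wl - Sr / Wr
                            crit = Wl * Wr / (Wl + Wr) * dmu * dmu
                            if crit > best_crit:
                                best_crit = crit
                                best_f = f
                                best_thr = tcand
                                best_ml = np.uint8(1) if dirm == 0 else np.uint8(0)
                            if cntm == 0:
                                break  # both directions identical w/o missings

            if best_f >= 0:
                feat[g] = best_f
                thr[g] = best_thr
                missl[g] = best_ml
                nl = 0
                nr = 0
                for ii in range(a, b):
                    r = sidx[ii]
                    v = X[r, best_f]
                    if np.isnan(v):
                        goleft = best_ml == 1
                    else:
                        goleft = v <= best_thr
                    if goleft:
                        buf_l[nl] = r
                        nl += 1
                    else:
                        buf_r[nr] = r
                        nr += 1
                for i2 in range(nl):
                    sidx[a + i2] = buf_l[i2]
                for i2 in range(nr):
                    sidx[a + nl + i2] = buf_r[i2]
                lid = n_nodes
                rid = n_nodes + 1
                n_nodes += 2
                parent[lid] = node
                parent[rid] = node
                lchild[g] = lid
                rchild[g] = rid
                top += 1
                stack_node[top] = lid
                stack_a[top] = a
                stack_b[top] = a + nl
                stack_d[top] = d + 1
                top += 1
                stack_node[top] = rid
                stack_a[top] = a + nl
                stack_b[top] = b
                stack_d[top] = d + 1

        # --- populate node values from the estimation half -------------------
        for i in range(n_nodes):
            wsum[i] = 0.0
            wysum[i] = 0.0
        for ii in range(e0, e1):
            r = rows[ii]
            node = 0
            while True:
                wsum[node] += w[r]
                wysum[node] += w[r] * y[r]
                g = pos + node
                if feat[g] == LEAF:
                    break
                v = X[r, feat[g]]
                if np.isnan(v):
                    node = lchild[g] if missl[g] == 1 else rchild[g]
                else:
                    node = lchild[g] if v <= thr[g] else rchild[g]
        for i in range(n_nodes):
            g = pos + i
            if wsum[i] > 0.0:
                val[g] = wysum[i] / wsum[i]
            elif i == 0:
                val[g] = 0.5  # unreachable with positive weights; defensive
            else:
                val[g] = val[pos + parent[i]]  # empty leaf: nearest ancestor
        pos += n_nodes

    offsets[n_trees] = pos
    return (feat[:pos].copy(), thr[:pos].copy(), missl[:pos].copy(),
            lchild[:pos].copy(), rchild[:pos].copy(), val[:pos].copy(),
            offsets, clmat, dbg_half)


@njit(cache=True)
def predict_rows(Xn, feat, thr, missl, lchild, rchild, val, offsets):
    """Mean leaf value over all trees for each row of Xn."""
    nq = Xn.shape[0]
    n_trees = offsets.shape[0] - 1
    out = np.zeros(nq)
    for t in range(n_trees):
        base = offsets[t]
        for q in range(nq):
            node = 0
            while feat[base + node] != LEAF:
                g = base + node
                v = Xn[q, feat[g]]
                if np.isnan(v):
                    node = lchild[g] if missl[g] == 1 else rchild[g]
                else:
                    node = lchild[g] if v <= thr[g] else rchild[g]
            out[q] += val[base + node]
    return out / n_trees


@njit(cache=True)
def predict_oob_rows(X, row_cl, clmat, feat, thr, missl, lchild, rchild, val,
                     offsets):
    """OOB-by-cluster prediction: average only trees excluding the row's cluster.

    Returns (sum, count); callers turn count==0 into a flagged missing value.
    """
    nq = X.shape[0]
    n_trees = offsets.shape[0] - 1
    out = np.zeros(nq)
    cnt = np.zeros(nq, np.int64)
    for t in range(n_trees):
        base = offsets[t]
        for q in range(nq):
            if clmat[t, row_cl[q]] == 1:
                continue
            node = 0
            while feat[base + node] != LEAF:
                g = base + node
                v = X[q, feat[g]]
                if np.isnan(v):
                    node = lchild[g] if missl[g] == 1 else rchild[g]
                else:
                    node = lchild[g] if v <= thr[g] else rchild[g]
            out[q] += val[base + node]
            cnt[q] += 1
    return out, cnt
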