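"""CART-style regression trees with mixed continuous/categorical splits.

Splits minimize squared loss.  Continuous rules are thresholds at midpoints
of consecutive sorted distinct values; categorical rules are binary level-set
partitions found by ordering levels by their mean response, which is exact
for squared loss.  The best-split search is vectorized across all candidate
variables at once: categorical candidates are ordinally re-encoded by level
mean inside the node and then scanned with the same cumulative-sum pass as
continuous ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RegressionTree", "best_split", "grow_tree"]

_MIN_GAIN = 1e-12

try:  # jit scan kernel; the numpy path below is the reference implementation
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _scan_columns_numpy(Z: np.ndarray, yv: np.ndarray):
    """Per-column best SSE reduction and threshold (numpy reference)."""
    s, k = Z.shape
    order = np.argsort(Z, axis=0, kind="stable")
    zs = np.take_along_axis(Z, order, axis=0)
    ys = yv[order]
    csum = np.cumsum(ys, axis=0)
    csq = np.cumsum(ys * ys, axis=0)
    total, total2 = csum[-1], csq[-1]
    parent_sse = float(total2[0] - total[0] ** 2 / s)
    nl = np.arange(1, s)[:, None]
    left_sse = csq[:-1] - csum[:-1] ** 2 / nl
    right_sse = (total2 - csq[:-1]) - (total - csum[:-1]) ** 2 / (s - nl)
    red = parent_sse - left_sse - right_sse
    red[zs[:-1] == zs[1:]] = -np.inf  # only between distinct values
    pos = np.argmax(red, axis=0)  # first max => smallest threshold
    cols = np.arange(k)
    gain = red[pos, cols]
    thr = 0.5 * (zs[pos, cols] + zs[np.minimum(pos + 1, s - 1), cols])
    return gain, thr


if njit is not None:

    @njit(cache=False)
    def _split_kernel(X, rows, cand, catflags, L, yv):  # pragma: no cover
        """Full split search in one pass: gather, node-local level-mean
        encoding of categorical candidates, sort, cumulative-sum scan.
        Ties: larger gain, then smaller variable index, then smaller
        threshold (the ascending scan yields the smallest threshold)."""
        s = rows.shape[0]
        k = cand.shape[0]
        tot = 0.0
        tot2 = 0.0
        for i in range(s):
            tot += yv[i]
            tot2 += yv[i] * yv[i]
        parent = tot2 - tot * tot / s
        best_gain = -np.inf
        best_var = -1
        best_thr = 0.0
        best_iscat = False
        best_order = np.full(L, -1, np.int64)
        best_present = np.zeros(L, np.bool_)
        z = np.empty(s)
        counts = np.empty(L, np.int64)
        sums = np.empty(L)
        means = np.empty(L)
        order_lev = np.empty(L, np.int64)
        rank = np.empty(L, np.int64)
        for ci in range(k):
            c = cand[ci]
            iscat = catflags[c]
            if iscat:
                for a in range(L):
                    counts[a] = 0
                    sums[a] = 0.0
                for i in range(s):
                    code = int(X[rows[i], c])
                    counts[code] += 1
                    sums[code] += yv[i]
                for a in range(L):
                    means[a] = sums[a] / counts[a] if counts[a] > 0 else np.inf
                    order_lev[a] = a
                for a in range(1, L):  # stable insertion sort by mean
                    key = order_lev[a]
                    km = means[key]
                    b = a - 1
                    while b >= 0 and means[order_lev[b]] > km:
                        order_lev[b + 1] = order_lev[b]
                        b -= 1
                    order_lev[b + 1] = key
                for r in range(L):
                    rank[order_lev[r]] = r
                for i in range(s):
                    z[i] = rank[int(X[rows[i], c])]
            else:
                for i in range(s):
                    z[i] = X[rows[i], c]
            ord_ = np.argsort(z)
            cs = 0.0
            css = 0.0
            for i in range(s - 1):
                yy = yv[ord_[i]]
                cs += yy
                css += yy * yy
                z0 = z[ord_[i]]
                z1 = z[ord_[i + 1]]
                if z0 == z1:
                    continue
                nl = i + 1
                nr = s - nl
                ls = css - cs * cs / nl
                rs = (tot2 - css) - (tot - cs) * (tot - cs) / nr
                red = parent - ls - rs
                thr = 0.5 * (z0 + z1)
                better = red > best_gain
                if (not better) and red == best_gain and best_var >= 0:
                    if c < best_var:
                        better = True
                    elif c == best_var and thr < best_thr:
                        better = True
                if better:
                    best_gain = red
                    best_var = c
                    best_thr = thr
                    best_iscat = iscat
                    if iscat:
                        for a in range(L):
                            best_order[a] = order_lev[a]
                            best_present[a] = counts[a] > 0
        return best_var, best_gain, best_thr, best_iscat, best_order, \
            best_present
else:  # pragma: no cover
    _split_kernel = None


@dataclass
class Split:
    var: int
    threshold: float | None  # continuous rule: x <= threshold goes left
    left_levels: np.ndarray | None  # categorical rule: level in set goes left
    gain: float


@dataclass
class RegressionTree:
    """Flat-array binary regression tree.

    ``feature[i] == -1`` marks a leaf with prediction ``value[i]``.
    ``split_vars`` is the set of distinct variables split on anywhere in the
    tree (the unit of the interaction co-occurrence test).
    """

    feature: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    threshold: np.ndarray = field(default_factory=lambda: np.empty(0))
    left_levels: list = field(default_factory=list)
    children_left: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    children_right: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    value: np.ndarray = field(default_factory=lambda: np.empty(0))
    gain: np.ndarray = field(default_factory=lambda: np.empty(0))
    bootstrap_idx: np.ndarray | None = None
    oob_idx: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def split_vars(self) -> set[int]:
        return set(int(f) for f in self.feature if f >= 0)

    def predict(self, X: np.ndarray, rows: np.ndarray | None = None) -> np.ndarray:
        if rows is None:
            rows = np.arange(X.shape[0])
        out = np.empty(len(rows))
        stack = [(0, np.arange(len(rows)))]
        while stack:
            nid, idx = stack.pop()
            if idx.size == 0:
                continue
            f = self.feature[nid]
            if f < 0:
                out[idx] = self.value[nid]
                continue
            col = X[rows[idx], f]
            lv = self.left_levels[nid]
            if lv is not None:
                left = np.isin(col.astype(np.int64), lv)
            else:
                left = col <= self.threshold[nid]
            stack.append((self.children_left[nid], idx[left]))
            stack.append((self.children_right[nid], idx[~left]))
        return out

    def accumulate_importance(self, vi: np.ndarray) -> None:
        internal = self.feature >= 0
        np.add.at(vi, self.feature[internal], self.gain[internal])


def _encode_categorical(Z: np.ndarray, cat_pos: np.ndarray, y: np.ndarray,
                        n_levels_max: int):
    """Ordinally re-encode categorical columns of Z in place by node-local
    level mean response; returns (orders, present) for rule reconstruction."""
    s = Z.shape[0]
    kc = len(cat_pos)
    codes = Z[:, cat_pos].astype(np.int64)
    L = n_levels_max
    flat = codes + L * np.arange(kc)[None, :]
    counts = np.bincount(flat.ravel(), minlength=L * kc).reshape(kc, L)
    sums = np.bincount(flat.ravel(),
                       weights=np.broadcast_to(y[:, None], (s, kc)).ravel(),
                       minlength=L * kc).reshape(kc, L)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.inf)
    orders = np.argsort(means, axis=1, kind="stable")  # absent levels last
    ranks = np.empty_like(orders)
    np.put_along_axis(ranks, orders, np.arange(L)[None, :], axis=1)
    Z[:, cat_pos] = ranks[np.arange(kc)[None, :], codes]
    return orders, counts > 0


def best_split(X: np.ndarray, y: np.ndarray, rows: np.ndarray,
               candidates: np.ndarray, is_cat: np.ndarray,
               n_levels_max: int = 2) -> Split | None:
    """Best squared-loss split of ``rows`` among ``candidates``.

    Ties are broken by larger gain, then smaller variable index, then
    smaller threshold.  Returns None when no candidate yields a positive
    SSE reduction.
    """
    s = len(rows)
    if s < 2:
        return None
    yv = y[rows]
    if _split_kernel is not None:
        var, gain, thr, iscat, order_lev, present = _split_kernel(
            X, np.asarray(rows, np.int64), np.asarray(candidates, np.int64),
            is_cat, n_levels_max, yv)
        if var < 0 or not np.isfinite(gain) or gain <= _MIN_GAIN:
            return None
        if iscat:
            # encoded ranks <= thr go left, among levels present in the node
            left = np.array([lev for r, lev in enumerate(order_lev)
                             if r <= thr and lev >= 0 and present[lev]],
                            dtype=np.int64)
            return Split(int(var), None, left, float(gain))
        return Split(int(var), float(thr), None, float(gain))

    Z = X[np.ix_(rows, candidates)].astype(float)
    cat_pos = np.flatnonzero(is_cat[candidates])
    orders = present = None
    if cat_pos.size:
        orders, present = _encode_categorical(Z, cat_pos, yv, n_levels_max)
    col_gain, col_thr = _scan_columns_numpy(Z, yv)
    best_gain = col_gain.max()
    if not np.isfinite(best_gain) or best_gain <= _MIN_GAIN:
        return None
    tied = np.flatnonzero(col_gain == best_gain)
    # smaller global variable index wins ties
    c = int(tied[np.argmin(candidates[tied])])
    var = int(candidates[c])
    gain = float(col_gain[c])
    thr = float(col_thr[c])
    cat_slot = np.flatnonzero(cat_pos == c)
    if cat_slot.size:
        slot = int(cat_slot[0])
        ordr, pres = orders[slot], present[slot]
        left = np.array([lev for r, lev in enumerate(ordr)
                         if r <= thr and pres[lev]], dtype=np.int64)
        return Split(var, None, left, gain)
    return Split(var, thr, None, gain)


def grow_tree(X: np.ndarray, y: np.ndarray, rows: np.ndarray, sampler,
              rng: np.random.Generator, is_cat: np.ndarray,
              nodesize: int = 3, n_levels_max: int = 2) -> RegressionTree:
    """Grow one regression tree on the given row multiset (the bootstrap).

    Nodes with at most ``nodesize`` samples or zero response variance become
    leaves; otherwise the node draws candidates from the sampler and takes
    the best positive-gain split.
    """
    feature, threshold, left_levels = [], [], []
    child_l, child_r, value, gain = [], [], [], []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left_levels.append(None)
        child_l.append(-1)
        child_r.append(-1)
        value.append(0.0)
        gain.append(0.0)
        return len(feature) - 1

    root = new_node()
    stack = [(root, rows)]
    while stack:
        nid, ridx = stack.pop()
        yv = y[ridx]
        value[nid] = float(yv.mean())
        if len(ridx) <= nodesize or np.all(yv == yv[0]):
            continue
        cand = sampler.sample(rng)
        sp = best_split(X, y, ridx, cand, is_cat, n_levels_max)
        if sp is None:
            continue
        col = X[ridx, sp.var]
        if sp.left_levels is not None:
            lut = np.zeros(n_levels_max, dtype=bool)
            lut[sp.left_levels] = True
            mask = lut[col.astype(np.int64)]
        else:
            mask = col <= sp.threshold
        if not mask.any() or mask.all():
            continue
        feature[nid] = sp.var
        threshold[nid] = np.nan if sp.threshold is None else sp.threshold
        left_levels[nid] = sp.left_levels
        gain[nid] = sp.gain
        lid, rid = new_node(), new_node()
        child_l[nid], child_r[nid] = lid, rid
        # right pushed first so the left child is grown first (deterministic)
        stack.append((rid, ridx[~mask]))
        stack.append((lid, ridx[mask]))
    return RegressionTree(
        feature=np.asarray(feature, np.int64),
        threshold=np.asarray(threshold, float),
        left_levels=left_levels,
        children_left=np.asarray(child_l, np.int64),
        children_right=np.asarray(child_r, np.int64),
        value=np.asarray(value, float),
        gain=np.asarray(gain, float),
    )
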