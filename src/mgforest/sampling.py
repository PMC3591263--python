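"""Modified weighted sampling and two-stage candidate variable selection.

At every tree node, candidate split variables are drawn in two stages:
first a subset of modules, then exactly one representative variable per
chosen module -- so candidates always come from pairwise-distinct modules.
Both stages use the same modified weighted scheme: stage 1 draws N1 items
without replacement with per-draw probability proportional to the remaining
weights, stage 2 keeps a uniform subset of N2 survivors.  With uniform
weights this reduces to plain uniform sampling without replacement.
"""

from __future__ import annotations

import math

import numpy as np

from .modules import ModulePartition

__all__ = ["weighted_subset_sample", "two_stage_candidates", "CandidateSampler"]

_W_FLOOR = 1e-300  # zero weights sort after all positive ones, uniformly

try:
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _pick_vars_py(mods, offsets, members, keys, n1_arr, u):
    """One representative variable per chosen module: the r-th smallest
    exponential key with r uniform on the module's stage-1 survivor count
    (equivalent to 'weighted stage 1, then uniform stage 2 of one')."""
    out = np.empty(len(mods), dtype=np.int64)
    for t in range(len(mods)):
        mi = mods[t]
        a, b = offsets[mi], offsets[mi + 1]
        size = b - a
        if size == 1:
            out[t] = members[a]
            continue
        n1 = n1_arr[mi]
        r = int(u[t] * n1)
        if r >= n1:
            r = n1 - 1
        # partial selection: (r+1)-th smallest key among the module's vars
        vals = keys[members[a:b]].copy()
        idx = -1
        for _ in range(r + 1):
            best = np.inf
            idx = -1
            for j in range(size):
                if vals[j] < best:
                    best = vals[j]
                    idx = j
            vals[idx] = np.inf
        out[t] = members[a + idx]
    return out


_pick_vars = njit(cache=False)(_pick_vars_py) if njit is not None else _pick_vars_py


def _stage1_keys(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exponential sort keys: taking the N1 smallest keys is equivalent to
    N1 successive weighted draws without replacement (Efraimidis-Spirakis)."""
    e = rng.exponential(size=len(weights))
    return e / np.maximum(weights, _W_FLOOR)


def weighted_subset_sample(items, weights, n1: int, n2: int,
                           rng: np.random.Generator) -> list:
    """Draw ``n2`` items: stage 1 keeps ``n1`` by weighted sampling without
    replacement, stage 2 keeps ``n2`` of the survivors uniformly.

    All-zero weights degrade to uniform stage 1.
    """
    items = list(items)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(items):
        raise ValueError("items/weights length mismatch")
    if np.any(w < 0):
        raise ValueError("negative weights")
    if not (0 < n2 <= n1 <= len(items)):
        raise ValueError(f"need 0 < n2 <= n1 <= |items| (got {n1}, {n2})")
    keys = _stage1_keys(w, rng)
    if n1 < len(items):
        stage1 = np.argpartition(keys, n1 - 1)[:n1]
    else:
        stage1 = np.arange(len(items))
    if n2 < len(stage1):
        chosen = rng.choice(stage1, size=n2, replace=False)
    else:
        chosen = stage1
    return [items[i] for i in chosen]


def _stage1_size(n: int) -> int:
    """N1 = ceil(N/3), clipped to at least 1."""
    return max(1, math.ceil(n / 3))


def two_stage_candidates(part: ModulePartition, mod_weights, var_weights,
                         k_mod: int, rng: np.random.Generator) -> list[str]:
    """Sample ``k_mod`` candidate variables from pairwise-distinct modules.

    Module stage: N1 = max(ceil(#modules/3), k_mod), N2 = k_mod over module
    MI weights.  Variable stage within each module: N1 = ceil(size/3),
    N2 = 1 over VI weights.
    """
    members = part.module_members
    module_ids = sorted(members)
    if k_mod > len(module_ids):
        raise ValueError("k_mod exceeds module count")
    mw = np.array([float(mod_weights.get(m, 0.0)) for m in module_ids])
    n1 = max(_stage1_size(len(module_ids)), k_mod)
    chosen_modules = weighted_subset_sample(module_ids, mw, n1, k_mod, rng)
    out = []
    for m in chosen_modules:
        ids = members[m]
        if len(ids) == 1:
            out.append(ids[0])
            continue
        vw = np.array([float(var_weights.get(v, 0.0)) for v in ids])
        out.append(weighted_subset_sample(ids, vw, _stage1_size(len(ids)), 1, rng)[0])
    return out


class CandidateSampler:
    """Array-based node-level sampler used inside tree growth.

    Precomputes module membership index arrays and epsilon-smoothed weight
    vectors so the per-node cost is a couple of vectorized draws.  Learned
    weights get eps = 1e-6 * max(max weight, 1) added so zero-importance
    variables keep a non-zero selection probability across iterations.
    """

    def __init__(self, module_vars: list[np.ndarray], mod_weights: np.ndarray,
                 var_weights: np.ndarray, k_mod: int):
        self.module_vars = module_vars
        self.k_mod = int(k_mod)
        m = len(module_vars)
        if not (1 <= self.k_mod <= m):
            raise ValueError("k_mod must be in [1, #modules]")
        self.mod_w = self._smooth(np.asarray(mod_weights, dtype=float))
        self.var_w = self._smooth(np.asarray(var_weights, dtype=float))
        self.n1_mod = max(_stage1_size(m), self.k_mod)
        self.n1_var = np.array([_stage1_size(len(v)) for v in module_vars],
                               dtype=np.int64)
        self.all_singletons = all(len(v) == 1 for v in module_vars)
        if self.all_singletons:
            self._flat = np.array([v[0] for v in module_vars])
        self.members = np.concatenate(module_vars).astype(np.int64)
        self.offsets = np.zeros(m + 1, dtype=np.int64)
        np.cumsum([len(v) for v in module_vars], out=self.offsets[1:])
        if int(self.members.max()) >= len(self.var_w):
            raise ValueError("var_weights shorter than the variable index range")
        self.n_vars = len(self.var_w)
        self.inv_var_w = 1.0 / self.var_w  # smoothed, strictly positive

    @staticmethod
    def _smooth(w: np.ndarray) -> np.ndarray:
        eps = 1e-6 * max(float(w.max(initial=0.0)), 1.0)
        return w + eps

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        m = len(self.module_vars)
        keys = rng.exponential(size=m) / self.mod_w
        if self.n1_mod < m:
            s1 = np.argpartition(keys, self.n1_mod - 1)[:self.n1_mod]
        else:
            s1 = np.arange(m)
        if self.k_mod < len(s1):
            mods = rng.choice(s1, size=self.k_mod, replace=False)
        else:
            mods = s1
        if self.all_singletons:
            return self._flat[mods]
        keys = rng.exponential(size=self.n_vars) * self.inv_var_w
        u = rng.random(len(mods))
        return _pick_vars(np.asarray(mods, dtype=np.int64), self.offsets,
                          self.members, keys, self.n1_var, u)


class UniformSampler:
    """mtry-of-m uniform candidate sampler (module guidance off)."""

    def __init__(self, n_variables: int, mtry: int):
        if not (1 <= mtry <= n_variables):
            raise ValueError("mtry must be in [1, m]")
        self.m = n_variables
        self.mtry = mtry

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.m, size=self.mtry, replace=False)
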