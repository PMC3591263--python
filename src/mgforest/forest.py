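"""Module-guided Random Forest ensembles and importance measures.

``fit_forest`` grows one forest at fixed sampling weights; ``fit_mgrf``
iterates it: the first forest samples modules and variables uniformly, and
every later forest re-draws candidates with probabilities proportional to
the module importances (MI) and variable importances (VI) re-estimated from
the previous forest (not accumulated).  Iteration stops when the normalized
VI vector moves by less than ``vi_tol`` in L1, or after ``max_iters``.

Importance definitions:

* VI(v)  - summed SSE reduction of all nodes splitting on v, over all trees,
  divided by ntrees (impurity-decrease importance, the regression analog of
  Gini importance).
* MI(m)  - sum of VI over the module's member variables.
* cVI(v) - VI(v) plus the correlation-weighted VIs of v's network neighbors
  inside v's own module; computed once, from the final forest.  cVI undoes
  the dilution of importance across groups of correlated variables: the
  two-stage sampler admits at most one member of a module per node, and cVI
  re-aggregates the module-local evidence onto each member.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import OmicsDataset, PhenotypeVector
from .modules import ModulePartition
from .network import CorrelationNetwork
from .sampling import CandidateSampler, UniformSampler
from .tree import RegressionTree, grow_tree

__all__ = [
    "ForestParams", "ForestModel", "ImportanceReport",
    "fit_forest", "predict", "oob_error", "oob_predict",
    "variable_importance", "module_importance", "corrected_vi", "fit_mgrf",
]


@dataclass
class ForestParams:
    """Hyperparameters shared by conventional-RF and mgRF modes.

    ``k_mod`` ("auto" = max(1, ceil(#modules/3))) is the module-level mtry;
    ``mtry`` ("auto" = max(1, ceil(m/3))) applies when module guidance is
    off.  ``nodesize=3`` suits the small-sample regime (n < 200) these
    datasets live in.
    """

    ntrees: int = 1000
    k_mod: int | str = "auto"
    mtry: int | str = "auto"
    nodesize: int = 3
    max_iters: int = 10
    vi_tol: float = 0.01

    def resolved_k_mod(self, n_modules: int) -> int:
        if self.k_mod == "auto":
            return max(1, math.ceil(n_modules / 3))
        return min(int(self.k_mod), n_modules)

    def resolved_mtry(self, n_variables: int) -> int:
        if self.mtry == "auto":
            return max(1, math.ceil(n_variables / 3))
        return min(int(self.mtry), n_variables)


@dataclass
class ForestModel:
    """A fitted ensemble plus the metadata downstream analyses need."""

    trees: list[RegressionTree]
    variable_ids: list[str]
    is_cat: np.ndarray
    params: ForestParams
    n_samples: int
    iteration: int = 0

    @property
    def ntrees(self) -> int:
        return len(self.trees)

    def split_var_sets(self) -> list[set[int]]:
        """Per-tree sets of distinct split variables (interaction test input)."""
        return [t.split_vars for t in self.trees]

    def _check_variables(self, d: OmicsDataset) -> None:
        if d.variable_ids != self.variable_ids:
            missing = set(self.variable_ids) - set(d.variable_ids)
            if missing:
                raise ValueError(f"dataset lacks model variables: {sorted(missing)[:5]}")
            raise ValueError("dataset variables are ordered differently from model")

    def to_json(self) -> str:
        payload = {
            "variable_ids": self.variable_ids,
            "is_cat": self.is_cat.astype(int).tolist(),
            "n_samples": self.n_samples,
            "iteration": self.iteration,
            "params": self.params.__dict__,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": [None if np.isnan(x) else x for x in t.threshold],
                    "left_levels": [None if l is None else l.tolist()
                                    for l in t.left_levels],
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "value": t.value.tolist(),
                    "gain": t.gain.tolist(),
                    "oob_idx": None if t.oob_idx is None else t.oob_idx.tolist(),
                }
                for t in self.trees
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ForestModel":
        payload = json.loads(text)
        trees = []
        for t in payload["trees"]:
            trees.append(RegressionTree(
                feature=np.asarray(t["feature"], np.int64),
                threshold=np.asarray([np.nan if x is None else x
                                      for x in t["threshold"]], float),
                left_levels=[None if l is None else np.asarray(l, np.int64)
                             for l in t["left_levels"]],
                children_left=np.asarray(t["children_left"], np.int64),
                children_right=np.asarray(t["children_right"], np.int64),
                value=np.asarray(t["value"], float),
                gain=np.asarray(t["gain"], float),
                oob_idx=None if t["oob_idx"] is None
                else np.asarray(t["oob_idx"], np.int64),
            ))
        return cls(trees, payload["variable_ids"],
                   np.asarray(payload["is_cat"], bool),
                   ForestParams(**payload["params"]),
                   payload["n_samples"], payload["iteration"])


@dataclass
class ImportanceReport:
    """VI/MI/cVI maps plus percent-of-total columns."""

    vi: dict[str, float]
    mi: dict[int, float]
    cvi: dict[str, float]

    @staticmethod
    def _percent(d: dict) -> dict:
        total = sum(d.values())
        if total == 0:
            return {k: 0.0 for k in d}
        return {k: 100.0 * v / total for k, v in d.items()}

    @property
    def vi_percent(self) -> dict[str, float]:
        return self._percent(self.vi)

    @property
    def mi_percent(self) -> dict[int, float]:
        return self._percent(self.mi)

    @property
    def cvi_percent(self) -> dict[str, float]:
        return self._percent(self.cvi)

    def to_frame(self, part: ModulePartition | None = None) -> pd.DataFrame:
        cvip = self.cvi_percent
        rows = [
            {
                "variable_id": v,
                "module_id": part.assignment.get(v, -1) if part else -1,
                "VI": self.vi[v],
                "cVI": self.cvi[v],
                "cVI_percent": cvip[v],
            }
            for v in self.vi
        ]
        frame = pd.DataFrame(rows)
        return frame.sort_values("cVI", ascending=False, kind="stable",
                                 ignore_index=True)


def _build_sampler(d: OmicsDataset, part: ModulePartition | None,
                   mod_weights, var_weights, params: ForestParams):
    if part is None:
        return UniformSampler(d.n_variables, params.resolved_mtry(d.n_variables))
    vpos = {v: i for i, v in enumerate(d.variable_ids)}
    members = part.module_members
    module_ids = sorted(members)
    module_vars = [np.array([vpos[v] for v in members[m]], dtype=np.int64)
                   for m in module_ids]
    mw = np.array([float((mod_weights or {}).get(m, 0.0)) for m in module_ids])
    vw = np.zeros(d.n_variables)
    for v, w in (var_weights or {}).items():
        if v in vpos:
            vw[vpos[v]] = float(w)
    k_mod = params.resolved_k_mod(len(module_ids))
    return CandidateSampler(module_vars, mw, vw, k_mod)


def fit_forest(d: OmicsDataset, y: PhenotypeVector,
               part: ModulePartition | None, mod_weights, var_weights,
               params: ForestParams, rng: np.random.Generator) -> ForestModel:
    """Grow one forest of ``params.ntrees`` bootstrap trees.

    ``part=None`` disables module guidance (plain RF with uniform mtry
    candidates, same split engine).
    """
    if d.sample_ids != y.sample_ids:
        raise ValueError("dataset and phenotype are not aligned (align_phenotype)")
    n = d.n_samples
    if n < 2 * params.nodesize:
        raise ValueError(f"need at least {2 * params.nodesize} samples")
    X = d.values
    yv = y.values
    is_cat = np.array([v.kind == "categorical" for v in d.variables])
    n_levels_max = max([v.n_levels or 2 for v in d.variables], default=2)
    sampler = _build_sampler(d, part, mod_weights, var_weights, params)

    trees = []
    seeds = rng.spawn(params.ntrees)
    for t_rng in seeds:
        boot = t_rng.integers(0, n, size=n)
        tree = grow_tree(X, yv, boot, sampler, t_rng, is_cat,
                         nodesize=params.nodesize, n_levels_max=n_levels_max)
        tree.bootstrap_idx = boot
        tree.oob_idx = np.setdiff1d(np.arange(n), boot)
        trees.append(tree)
    return ForestModel(trees, d.variable_ids, is_cat, params, n)


def predict(model: ForestModel, X: OmicsDataset) -> np.ndarray:
    """Per-sample mean of tree predictions."""
    model._check_variables(X)
    if X.n_samples == 0:
        return np.empty(0)
    acc = np.zeros(X.n_samples)
    for t in model.trees:
        acc += t.predict(X.values)
    return acc / model.ntrees


def oob_predict(model: ForestModel, d: OmicsDataset) -> np.ndarray:
    """Average each sample only over trees where it is out-of-bag.

    Samples never out-of-bag get NaN (with a warning in oob_error).
    """
    model._check_variables(d)
    acc = np.zeros(d.n_samples)
    cnt = np.zeros(d.n_samples)
    for t in model.trees:
        if t.oob_idx is None or t.oob_idx.size == 0:
            continue
        acc[t.oob_idx] += t.predict(d.values, rows=t.oob_idx)
        cnt[t.oob_idx] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


def oob_error(model: ForestModel, d: OmicsDataset, y: PhenotypeVector) -> float:
    """Out-of-bag RMSE; the standard internal generalization-error estimate."""
    pred = oob_predict(model, d)
    mask = np.isfinite(pred)
    if not mask.all():
        warnings.warn(f"{int((~mask).sum())} samples never out-of-bag; excluded")
    if not mask.any():
        raise ValueError("no sample is out-of-bag in any tree")
    return float(np.sqrt(np.mean((pred[mask] - y.values[mask]) ** 2)))


def variable_importance(model: ForestModel) -> dict[str, float]:
    """Impurity-decrease VI per variable (total SSE reduction / ntrees)."""
    acc = np.zeros(len(model.variable_ids))
    for t in model.trees:
        t.accumulate_importance(acc)
    acc /= model.ntrees
    return {v: float(x) for v, x in zip(model.variable_ids, acc)}


def module_importance(vi: dict[str, float],
                      part: ModulePartition) -> dict[int, float]:
    """MI(m) = sum of member VIs."""
    out = {m: 0.0 for m in set(part.assignment.values())}
    for v, x in vi.items():
        if v not in part.assignment:
            raise ValueError(f"variable {v!r} is not assigned to a module")
        out[part.assignment[v]] += x
    return out


def corrected_vi(vi: dict[str, float], part: ModulePartition,
                 net: CorrelationNetwork) -> dict[str, float]:
    """cVI(v) = VI(v) + sum over same-module network neighbors j of
    c_vj * VI(j), with c the absolute association edge weight."""
    out = {}
    for v, x in vi.items():
        total = x
        mv = part.assignment.get(v)
        if mv is not None and net.graph.has_node(v):
            for u in net.graph.neighbors(v):
                if part.assignment.get(u) == mv and u in vi:
                    total += net.graph[v][u]["weight"] * vi[u]
        out[v] = total
    return out


def _l1_change(prev: dict[str, float], cur: dict[str, float]) -> float:
    keys = list(cur)
    a = np.array([prev.get(k, 0.0) for k in keys])
    b = np.array([cur[k] for k in keys])
    if a.sum() > 0:
        a = a / a.sum()
    if b.sum() > 0:
        b = b / b.sum()
    return float(np.abs(a - b).sum())


def fit_mgrf(d: OmicsDataset, y: PhenotypeVector, part: ModulePartition,
             net: CorrelationNetwork, params: ForestParams,
             rng: np.random.Generator):
    """Iterated module-guided forest construction.

    Returns ``(model, report, trace)`` where ``trace`` is a list of per-
    iteration dicts (OOB RMSE, L1 change of the normalized VI vector).
    The sampling weights of iteration t are the raw VI/MI re-estimated from
    iteration t-1; cVI is computed only from the final forest.
    """
    mod_weights: dict[int, float] = {}
    var_weights: dict[str, float] = {}
    prev_vi: dict[str, float] = {}
    trace = []
    model = None
    vi: dict[str, float] = {}
    for it in range(params.max_iters):
        model = fit_forest(d, y, part, mod_weights, var_weights, params, rng)
        model.iteration = it
        vi = variable_importance(model)
        mi = module_importance(vi, part)
        change = _l1_change(prev_vi, vi) if it > 0 else float("inf")
        trace.append({
            "iteration": it,
            "oob_rmse": oob_error(model, d, y),
            "vi_l1_change": None if it == 0 else change,
        })
        if it > 0 and change < params.vi_tol:
            break
        prev_vi = vi
        mod_weights, var_weights = mi, vi
    mi = module_importance(vi, part)
    cvi = corrected_vi(vi, part, net) if net is not None else dict(vi)
    report = ImportanceReport(vi=vi, mi=mi, cvi=cvi)
    return model, report, trace
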