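"""Cross-validated benchmark harness for the three-way data-type comparison.

The protocol repeats k-fold cross-validation over several trials; within a
trial every method and data-type arm sees the identical train/test splits
(paired design), so per-fold RMSEs can be compared with a one-tail paired
t-test.  By default the correlation network and modules are rebuilt on the
training fold only, so no test information reaches module detection or the
importance weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import pairwise_associations
from .data import OmicsDataset, PhenotypeVector, merge_datasets
from .forest import ForestParams, fit_forest, fit_mgrf, predict
from .modules import ModulePartition, detect_modules
from .network import build_network

__all__ = ["kfold_splits", "rmse", "r_squared", "paired_one_tail_t",
           "CVResult", "run_benchmark"]

_P_FLOOR = 1e-300


def kfold_splits(n_samples: int, folds: int = 10, trials: int = 10,
                 seed: int = 0) -> list[list[np.ndarray]]:
    """Per trial, a random partition of samples into near-equal test folds.

    Deterministic per seed; trials use independent substreams of the seed.
    """
    if n_samples < folds:
        raise ValueError("need n_samples >= folds")
    children = np.random.SeedSequence(seed).spawn(trials)
    out = []
    for child in children:
        perm = np.random.default_rng(child).permutation(n_samples)
        out.append([np.sort(a) for a in np.array_split(perm, folds)])
    return out


def rmse(pred, truth) -> float:
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape or pred.size < 1:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def r_squared(pred, truth) -> float:
    """1 - SSE/SST about the truth mean; undefined for constant truth."""
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    sst = float(((truth - truth.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("R^2 undefined: truth has zero variance")
    sse = float(((pred - truth) ** 2).sum())
    return 1.0 - sse / sst


def paired_one_tail_t(a, b) -> float:
    """One-sided paired t-test of H1: mean(a) < mean(b).

    Zero-variance differences use the documented convention: p=1 when the
    mean difference is >= 0, a numeric floor otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length vectors of size >= 2")
    d = a - b
    if np.all(d == d[0]):
        return 1.0 if d[0] >= 0 else _P_FLOOR
    return float(stats.ttest_rel(a, b, alternative="less").pvalue)


@dataclass
class CVResult:
    """Per-fold RMSE grid: trials x folds x arms, plus the fold layout."""

    arms: list[str]
    errors: np.ndarray  # trials x folds x arms
    folds: list[list[np.ndarray]]
    seed: int = 0

    def mean_rmse(self) -> dict[str, float]:
        return {arm: float(self.errors[:, :, i].mean())
                for i, arm in enumerate(self.arms)}

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, arm in enumerate(self.arms):
            e = self.errors[:, :, i]
            rows.append({"arm": arm, "mean_rmse": e.mean(), "sd_rmse": e.std(ddof=1)})
        return pd.DataFrame(rows)

    def compare(self, arm_a: str, arm_b: str) -> float:
        """p-value that arm_a's per-fold RMSE is smaller than arm_b's."""
        ia, ib = self.arms.index(arm_a), self.arms.index(arm_b)
        return paired_one_tail_t(self.errors[:, :, ia].ravel(),
                                 self.errors[:, :, ib].ravel())


def _fit_predict(train_ds: OmicsDataset, train_y: PhenotypeVector,
                 test_ds: OmicsDataset, params: ForestParams,
                 method: str, rng: np.random.Generator,
                 net_kwargs: dict) -> np.ndarray:
    if method == "rf":
        model = fit_forest(train_ds, train_y, None, None, None, params, rng)
        return predict(model, test_ds)
    A = pairwise_associations(train_ds)
    net = build_network(A, **net_kwargs)
    part = detect_modules(net)
    model, _, _ = fit_mgrf(train_ds, train_y, part, net, params, rng)
    return predict(model, test_ds)


def run_benchmark(genotypes: OmicsDataset | None,
                  expression: OmicsDataset | None,
                  y: PhenotypeVector,
                  folds: int = 10, trials: int = 10, seed: int = 0,
                  params: ForestParams | None = None,
                  method: str = "mgrf",
                  arms: list[str] | None = None,
                  net_kwargs: dict | None = None) -> CVResult:
    """Paired k-fold CV over data-type arms (genotype / expression /
    combined), rebuilding network and modules inside each training fold."""
    params = params or ForestParams()
    net_kwargs = net_kwargs or {}
    datasets: dict[str, OmicsDataset] = {}
    if genotypes is not None:
        datasets["genotype"] = genotypes
    if expression is not None:
        datasets["expression"] = expression
    if genotypes is not None and expression is not None:
        datasets["combined"] = merge_datasets(genotypes, expression)
    if arms is not None:
        datasets = {a: datasets[a] for a in arms}
    if not datasets:
        raise ValueError("no data-type arm available")
    arm_names = list(datasets)
    base = next(iter(datasets.values()))
    for ds in datasets.values():
        if ds.sample_ids != base.sample_ids:
            raise ValueError("arms must share sample order")
    if y.sample_ids != base.sample_ids:
        raise ValueError("phenotype not aligned to datasets")

    splits = kfold_splits(base.n_samples, folds, trials, seed)
    errors = np.zeros((trials, folds, len(arm_names)))
    master = np.random.SeedSequence(seed).spawn(trials * folds * len(arm_names))
    s = 0
    for t, fold_sets in enumerate(splits):
        all_idx = np.arange(base.n_samples)
        for f, test_idx in enumerate(fold_sets):
            train_idx = np.setdiff1d(all_idx, test_idx)
            for a, arm in enumerate(arm_names):
                ds = datasets[arm]
                rng = np.random.default_rng(master[s]); s += 1
                pred = _fit_predict(
                    ds.select_samples(train_idx),
                    PhenotypeVector([ds.sample_ids[i] for i in train_idx],
                                    y.values[train_idx]),
                    ds.select_samples(test_idx), params, method, rng,
                    net_kwargs)
                errors[t, f, a] = rmse(pred, y.values[test_idx])
    return CVResult(arm_names, errors, splits, seed)
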