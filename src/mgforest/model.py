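"""Model/Results interface for module-guided Random Forests.

:class:`ModuleGuidedForest` bundles the full pipeline -- association
network, module detection, iterated guided forest -- behind a fit() call
that returns a :class:`MGRFResults` object carrying the importance
estimates (VI, MI, cVI), diagnostics (OOB RMSE, iteration trace) and a
summary table, with prediction and the interaction test hanging off it.

Example
-------
>>> geno, expr, y, truth = simulate_bxh(None, np.random.default_rng(0))
>>> data = merge_datasets(geno, expr)
>>> res = ModuleGuidedForest(data, y, ntrees=300).fit()
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import pairwise_associations
from .crossval import r_squared, rmse
from .data import OmicsDataset, PhenotypeVector, align_phenotype
from .forest import (ForestModel, ForestParams, ImportanceReport, fit_forest,
                     fit_mgrf, oob_error, predict)
from .interactions import interactions_frame, test_all_pairs
from .modules import ModulePartition, detect_modules
from .network import CorrelationNetwork, build_network

__all__ = ["ModuleGuidedForest", "MGRFResults"]


class ModuleGuidedForest:
    """Module-guided Random Forest regression model.

    Parameters
    ----------
    data : OmicsDataset
        Samples x variables predictors (mixed categorical/continuous).
    y : PhenotypeVector
        Continuous response; realigned to ``data`` by sample id.
    network, partition : optional precomputed CorrelationNetwork /
        ModulePartition.  When omitted, fit() builds them from ``data``.
    guided : bool
        False turns module guidance off: a conventional RF with uniform
        mtry-of-m candidate sampling, same tree engine.
    net_kwargs : dict
        Edge-criteria overrides (r1, t1, r2, t2) for network construction.
    Remaining keyword arguments populate :class:`ForestParams`.
    """

    def __init__(self, data: OmicsDataset, y: PhenotypeVector,
                 network: CorrelationNetwork | None = None,
                 partition: ModulePartition | None = None,
                 guided: bool = True, net_kwargs: dict | None = None,
                 **params):
        self.data = data
        self.y = align_phenotype(data, y)
        self.network = network
        self.partition = partition
        self.guided = guided
        self.net_kwargs = net_kwargs or {}
        self.params = ForestParams(**params)

    @classmethod
    def from_dataframes(cls, X: pd.DataFrame, y: pd.Series,
                        kind_map="auto", source="other", **kwargs
                        ) -> "ModuleGuidedForest":
        data = OmicsDataset.from_frame(X, kind_map=kind_map, source=source)
        pheno = PhenotypeVector([str(i) for i in y.index],
                                y.to_numpy(dtype=float))
        return cls(data, pheno, **kwargs)

    def fit(self, seed: int = 0,
            rng: np.random.Generator | None = None) -> "MGRFResults":
        rng = rng or np.random.default_rng(seed)
        if not self.guided:
            model = fit_forest(self.data, self.y, None, None, None,
                               self.params, rng)
            from .forest import module_importance, variable_importance
            vi = variable_importance(model)
            part = ModulePartition.singletons(self.data.variable_ids)
            report = ImportanceReport(vi=vi,
                                      mi=module_importance(vi, part),
                                      cvi=dict(vi))
            return MGRFResults(self, model, report, [], None, part)
        if self.network is None:
            self.network = build_network(pairwise_associations(self.data),
                                         **self.net_kwargs)
        if self.partition is None:
            self.partition = detect_modules(self.network)
        model, report, trace = fit_mgrf(self.data, self.y, self.partition,
                                        self.network, self.params, rng)
        return MGRFResults(self, model, report, trace, self.network,
                           self.partition)


class MGRFResults:
    """Fitted mgRF: importance estimates, diagnostics and reporting."""

    def __init__(self, model_spec: ModuleGuidedForest, forest: ForestModel,
                 report: ImportanceReport, trace: list,
                 network: CorrelationNetwork | None,
                 partition: ModulePartition):
        self.model = model_spec
        self.forest = forest
        self.report = report
        self.trace = trace
        self.network = network
        self.partition = partition

    # -- estimates -------------------------------------------------------------

    @property
    def vi(self) -> dict[str, float]:
        return self.report.vi

    @property
    def mi(self) -> dict[int, float]:
        return self.report.mi

    @property
    def cvi(self) -> dict[str, float]:
        return self.report.cvi

    @property
    def importances(self) -> pd.DataFrame:
        return self.report.to_frame(self.partition)

    # -- diagnostics -----------------------------------------------------------

    @property
    def oob_rmse(self) -> float:
        return oob_error(self.forest, self.model.data, self.model.y)

    @property
    def n_iterations(self) -> int:
        return self.forest.iteration + 1

    def predict(self, X: OmicsDataset) -> np.ndarray:
        return predict(self.forest, X)

    def training_r_squared(self) -> float:
        return r_squared(self.predict(self.model.data), self.model.y.values)

    # -- interactions ----------------------------------------------------------

    def test_interactions(self, ntrees: int = 6000, min_presence: int = 5,
                          seed: int = 0,
                          rng: np.random.Generator | None = None
                          ) -> pd.DataFrame:
        """Grow a dedicated large ensemble at the converged weights and run
        the hypergeometric co-occurrence test on its per-tree split sets."""
        rng = rng or np.random.default_rng(seed)
        from .forest import module_importance
        params = ForestParams(**{**self.forest.params.__dict__,
                                 "ntrees": ntrees})
        part = self.partition
        mod_w = module_importance(self.vi, part)
        big = fit_forest(self.model.data, self.model.y,
                         part if self.model.guided else None,
                         mod_w, self.vi, params, rng)
        sources = {v.id: v.source for v in self.model.data.variables}
        recs = test_all_pairs(big, min_presence=min_presence, sources=sources)
        return interactions_frame(recs)

    # -- reporting -------------------------------------------------------------

    def summary(self, top: int = 10) -> str:
        d = self.model.data
        lines = [
            "Module-guided Random Forest regression",
            "=" * 54,
            f"Samples:            {d.n_samples}",
            f"Variables:          {d.n_variables}",
            f"Modules:            {self.partition.n_modules}"
            + (f" (Q = {self.partition.modularity:.4f})"
               if self.network is not None else ""),
            f"Trees:              {self.forest.ntrees}",
            f"Iterations:         {self.n_iterations}",
            f"OOB RMSE:           {self.oob_rmse:.4f}",
            "",
            f"Top {top} variables by corrected importance (cVI):",
        ]
        frame = self.importances.head(top)
        lines.append(frame.to_string(
            index=False, float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<MGRFResults: {self.forest.ntrees} trees, "
                f"{self.partition.n_modules} modules>")
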