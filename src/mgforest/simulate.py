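"""Synthetic genotype/expression/phenotype generators with known truth.

These emulate the structure of an F2 mouse intercross resource: chromosomes
of linked markers (genotype dosage 0/1/2, expected 1:2:1), transcript
modules of correlated genes partly driven by eQTL markers, and a continuous
trait built from a small set of additive and pairwise-interaction terms
plus Gaussian noise.  A separate correlated-group benchmark probes the
importance-dilution bias, and a planted-partition graph generator feeds the
module-detection tests.  Everything is deterministic under a fixed rng.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data import OmicsDataset, PhenotypeVector, VariableDescriptor
from .network import CorrelationNetwork

__all__ = [
    "SimulationSpec", "GroundTruth", "bxh_spec",
    "simulate_f2_genotypes", "simulate_expression", "simulate_phenotype",
    "simulate_bxh", "make_group_benchmark", "planted_partition_network",
]


@dataclass
class SimulationSpec:
    """Generative blueprint for one synthetic cross.

    ``chromosomes`` lists (n_markers, recombination fraction r) per
    chromosome; r=0 gives perfect linkage along the chromosome, r=0.5
    independence.  ``eqtl_links`` are (marker_id, module_index, effect)
    triples; effects act on the standardized genotype dosage.  Phenotype
    terms reference variable ids; interaction terms multiply centered
    columns so they carry no marginal signal by construction.
    """

    n_samples: int = 150
    chromosomes: list[tuple[int, float]] = field(
        default_factory=lambda: [(10, 0.1)] * 19)
    n_modules: int = 60
    genes_per_module: int = 10
    rho: float = 0.7
    eqtl_links: list[tuple[str, int, float]] = field(default_factory=list)
    additive: list[tuple[str, float]] = field(default_factory=list)
    interactions: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for nm, r in self.chromosomes:
            if not (0.0 <= r <= 0.5):
                raise ValueError("recombination fraction must be in [0, 0.5]")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    relevant: list[str]
    module_labels: dict[str, int]
    params: dict


def marker_id(chrom: int, idx: int) -> str:
    return f"chr{chrom + 1}_m{idx + 1}"


def gene_id(module: int, idx: int) -> str:
    return f"g{module + 1}_{idx + 1}"


def bxh_spec(n_samples: int = 150, n_chromosomes: int = 19,
             markers_per_chromosome: int = 10, r: float = 0.1,
             n_modules: int = 60, genes_per_module: int = 10,
             rho: float = 0.7, n_eqtl: int = 15, eqtl_effect: float = 0.8,
             noise_sd: float = 1.9) -> SimulationSpec:
    """Desk-scale blueprint shaped like the mouse cross: markers spread over
    autosomes with LD, many more genes than samples, gene modules partly
    eQTL-driven, and a trait mixing marker, transcript and interaction terms.
    """
    chroms = [(markers_per_chromosome, r)] * n_chromosomes
    # one eQTL driver per early module, on the middle marker of successive
    # chromosomes (wrapping)
    links = []
    for m in range(min(n_eqtl, n_modules)):
        c = m % n_chromosomes
        links.append((marker_id(c, markers_per_chromosome // 2), m, eqtl_effect))
    trait_modules = [m for m in range(n_modules) if m >= min(n_eqtl, n_modules)]
    gm = trait_modules[:3] if len(trait_modules) >= 3 else list(range(min(3, n_modules)))
    additive = [
        (marker_id(n_chromosomes - 1, 1), 1.5),
        (marker_id(n_chromosomes - 2, 7), 1.5),
        (gene_id(gm[0], 0), 1.0),
        (gene_id(gm[1 % len(gm)], 0), 1.0),
        (gene_id(gm[2 % len(gm)], 0), 1.0),
    ]
    interactions = [
        (marker_id(0, 5), gene_id(gm[0], 1), 1.2),
        (gene_id(gm[1 % len(gm)], 1), gene_id(gm[2 % len(gm)], 1), 1.2),
    ]
    return SimulationSpec(
        n_samples=n_samples, chromosomes=chroms, n_modules=n_modules,
        genes_per_module=genes_per_module, rho=rho, eqtl_links=links,
        additive=additive, interactions=interactions, noise_sd=noise_sd,
    )


def simulate_f2_genotypes(spec: SimulationSpec,
                          rng: np.random.Generator) -> OmicsDataset:
    """F2 genotypes: per sample, two parental gametes follow Markov chains
    along each chromosome with crossover probability r between adjacent
    markers; the genotype code is the allele dosage in {0, 1, 2}."""
    n = spec.n_samples
    cols = []
    variables = []
    for c, (nm, r) in enumerate(spec.chromosomes):
        gametes = np.empty((2, n, nm), dtype=np.int64)
        for g in range(2):
            gametes[g, :, 0] = rng.integers(0, 2, size=n)
            for j in range(1, nm):
                flip = rng.random(n) < r
                gametes[g, :, j] = np.where(flip, 1 - gametes[g, :, j - 1],
                                            gametes[g, :, j - 1])
        dosage = gametes.sum(axis=0)
        for j in range(nm):
            variables.append(VariableDescriptor(
                marker_id(c, j), "categorical", "marker", n_levels=3,
                chromosome=str(c + 1), position_mb=float(j * 10)))
        cols.append(dosage)
    values = np.hstack(cols).astype(float)
    sample_ids = [f"s{i + 1}" for i in range(n)]
    return OmicsDataset(sample_ids, variables, values)


def simulate_expression(genotypes: OmicsDataset, spec: SimulationSpec,
                        rng: np.random.Generator) -> OmicsDataset:
    """Module-structured expression: each module has a latent factor
    (optionally loaded on an eQTL marker's standardized dosage); each gene
    is sqrt(rho)*factor + sqrt(1-rho)*noise, giving within-module pairwise
    Pearson correlation ~ rho and near-zero between-module correlation."""
    n = genotypes.n_samples
    eqtl_by_module: dict[int, list[tuple[str, float]]] = {}
    for mk, mod, eff in spec.eqtl_links:
        eqtl_by_module.setdefault(mod, []).append((mk, eff))
    variables = []
    cols = np.empty((n, spec.n_modules * spec.genes_per_module))
    j = 0
    for m in range(spec.n_modules):
        factor = rng.normal(size=n)
        for mk, eff in eqtl_by_module.get(m, []):
            g = genotypes.column(mk)
            gs = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
            factor = eff * gs + factor
        factor = (factor - factor.mean()) / (factor.std() or 1.0)
        load = math.sqrt(spec.rho)
        uniq = math.sqrt(1.0 - spec.rho)
        for k in range(spec.genes_per_module):
            cols[:, j] = load * factor + uniq * rng.normal(size=n)
            variables.append(VariableDescriptor(gene_id(m, k), "continuous",
                                                "transcript"))
            j += 1
    return OmicsDataset(list(genotypes.sample_ids), variables, cols)


def _column(genotypes: OmicsDataset, expression: OmicsDataset | None,
            var_id: str) -> np.ndarray:
    if var_id in genotypes.variable_ids:
        return genotypes.column(var_id)
    if expression is not None and var_id in expression.variable_ids:
        return expression.column(var_id)
    raise ValueError(f"unknown variable id in phenotype terms: {var_id!r}")


def simulate_phenotype(genotypes: OmicsDataset,
                       expression: OmicsDataset | None,
                       spec: SimulationSpec,
                       rng: np.random.Generator) -> tuple[PhenotypeVector,
                                                          GroundTruth]:
    """y = sum beta*x + sum gamma*(x_i - mean)(x_j - mean) + N(0, sigma^2)."""
    n = genotypes.n_samples
    y = np.zeros(n)
    relevant = []
    for var, beta in spec.additive:
        y += beta * _column(genotypes, expression, var)
        relevant.append(var)
    for u, v, gamma in spec.interactions:
        xu = _column(genotypes, expression, u)
        xv = _column(genotypes, expression, v)
        y += gamma * (xu - xu.mean()) * (xv - xv.mean())
        relevant.extend([u, v])
    y += rng.normal(scale=spec.noise_sd, size=n)
    seen = set()
    relevant = [v for v in relevant if not (v in seen or seen.add(v))]
    truth = GroundTruth(relevant=relevant, module_labels={},
                        params={"additive": spec.additive,
                                "interactions": spec.interactions,
                                "noise_sd": spec.noise_sd})
    return PhenotypeVector(list(genotypes.sample_ids), y), truth


def simulate_bxh(spec: SimulationSpec | None, rng: np.random.Generator):
    """Convenience: genotypes + expression + phenotype for one blueprint."""
    spec = spec or bxh_spec()
    geno = simulate_f2_genotypes(spec, rng)
    expr = simulate_expression(geno, spec, rng)
    y, truth = simulate_phenotype(geno, expr, spec, rng)
    truth.module_labels = {v.id: spec.n_modules if v.source == "marker"
                           else int(v.id[1:].split("_")[0]) - 1
                           for v in geno.variables + expr.variables}
    return geno, expr, y, truth


def make_group_benchmark(g1_size: int, rng: np.random.Generator,
                         n_samples: int = 200, g2_size: int = 10,
                         n_relevant: int = 110, n_noise: int = 1000,
                         rho: float = 0.9,
                         target_r2: float = 0.7) -> tuple[OmicsDataset,
                                                          GroundTruth]:
    """Correlated-group importance benchmark.

    Variables: group G1 (``g1_size`` members, pairwise correlation ~ rho,
    all carrying the same latent signal), group G2 (fixed-size correlated
    group), independent relevant singletons filling up to ``n_relevant``
    relevant variables, and ``n_noise`` pure-noise variables.  The response
    is additive over the two group latent factors and the singletons, with
    noise scaled for an oracle R-squared near ``target_r2``.
    """
    if g1_size < 2:
        raise ValueError("g1_size must be >= 2")
    n_single = n_relevant - g1_size - g2_size
    if n_single < 0:
        raise ValueError("groups exceed n_relevant")
    n = n_samples
    load, uniq = math.sqrt(rho), math.sqrt(1 - rho)

    def group(f: np.ndarray, size: int) -> np.ndarray:
        return load * f[:, None] + uniq * rng.normal(size=(n, size))

    f1 = rng.normal(size=n)
    f2 = rng.normal(size=n)
    g1 = group(f1, g1_size)
    g2 = group(f2, g2_size)
    singles = rng.normal(size=(n, n_single))
    noise = rng.normal(size=(n, n_noise))

    b_group, b_single = 1.0, 0.2
    signal = b_group * f1 + b_group * f2 + b_single * singles.sum(axis=1)
    var_signal = 2 * b_group ** 2 + n_single * b_single ** 2
    sigma = math.sqrt(var_signal * (1 - target_r2) / target_r2)
    y = signal + rng.normal(scale=sigma, size=n)

    ids = ([f"G1_{i + 1}" for i in range(g1_size)]
           + [f"G2_{i + 1}" for i in range(g2_size)]
           + [f"S_{i + 1}" for i in range(n_single)]
           + [f"noise_{i + 1}" for i in range(n_noise)])
    values = np.hstack([g1, g2, singles, noise])
    variables = [VariableDescriptor(v, "continuous", "transcript") for v in ids]
    ds = OmicsDataset([f"s{i + 1}" for i in range(n)], variables, values)
    truth = GroundTruth(
        relevant=ids[:n_relevant],
        module_labels={},
        params={"g1_size": g1_size, "g2_size": g2_size, "rho": rho,
                "sigma": sigma, "b_group": b_group, "b_single": b_single,
                "phenotype": y},
    )
    return ds, truth


def planted_partition_network(blocks: list[int], p_in: float, p_out: float,
                              rng: np.random.Generator
                              ) -> tuple[CorrelationNetwork, dict[str, int]]:
    """Stochastic-block-model graph with unit edge weights."""
    if not p_in > p_out:
        raise ValueError("need p_in > p_out")
    labels = {}
    nodes = []
    for b, size in enumerate(blocks):
        for i in range(size):
            v = f"b{b}_n{i}"
            labels[v] = b
            nodes.append(v)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            p = p_in if labels[u] == labels[v] else p_out
            if rng.random() < p:
                g.add_edge(u, v, weight=1.0, pair_type="cont-cont")
    return CorrelationNetwork(g, nodes), labels
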