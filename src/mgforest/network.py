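"""Sparse correlation network built from an association matrix.

An edge joins two variables when their absolute association is strong both
in value and in rank: either (1) |score| > t1 and one variable is within the
other's top-r1 most associated partners, or (2) |score| > t2 and one is
within the other's top-r2.  Rankings are computed separately within each
(source_i, source_j) block (marker-marker, transcript-transcript,
marker-transcript), because association scales differ across data types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationMatrix

__all__ = ["CorrelationNetwork", "build_network", "audit_edges",
           "write_network", "read_network"]


@dataclass
class CorrelationNetwork:
    """Weighted undirected graph over variables; weight = |association|.

    All dataset variables appear as nodes; variables failing both edge
    criteria everywhere are isolated.
    """

    graph: nx.Graph
    node_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_order:
            self.node_order = list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: str) -> list[str]:
        return list(self.graph.neighbors(node))

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]


def _block_ranks(s: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """rank[i, j]: 1-based rank of column j among row i's partners in this
    block, ordered by descending score with ties broken by ascending column
    index (variable order)."""
    sub = s[np.ix_(rows, cols)].copy()
    if rows is cols or np.array_equal(rows, cols):
        # exclude self-pairs from each row's ranking
        for k in range(len(rows)):
            sub[k, k] = -np.inf
    order = np.lexsort((np.broadcast_to(np.arange(sub.shape[1]), sub.shape), -sub),
                       axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, sub.shape[1] + 1)[None, :], axis=1)
    return ranks


def build_network(
    A: AssociationMatrix,
    r1: int = 5,
    t1: float = 0.5,
    r2: int = 50,
    t2: float = 0.8,
) -> CorrelationNetwork:
    """Apply the rank/value edge criteria to an association matrix."""
    m = A.n
    s = np.abs(A.values).copy()
    np.fill_diagonal(s, 0.0)

    keep = np.zeros((m, m), dtype=bool)
    sources = np.asarray(A.sources)
    for src_i in np.unique(sources):
        rows = np.flatnonzero(sources == src_i)
        for src_j in np.unique(sources):
            cols = np.flatnonzero(sources == src_j)
            ranks = _block_ranks(s, rows, cols)
            sub = s[np.ix_(rows, cols)]
            ok = ((sub > t1) & (ranks <= r1)) | ((sub > t2) & (ranks <= r2))
            keep[np.ix_(rows, cols)] |= ok
    # "one of the variables is ranked among the top r of the other": OR over
    # the two directions
    keep |= keep.T
    np.fill_diagonal(keep, False)

    g = nx.Graph()
    g.add_nodes_from(A.ids)
    ii, jj = np.nonzero(np.triu(keep, 1))
    for i, j in zip(ii, jj):
        g.add_edge(A.ids[i], A.ids[j], weight=float(s[i, j]),
                   pair_type=A.pair_type(i, j))
    return CorrelationNetwork(g, list(A.ids))


def audit_edges(net: CorrelationNetwork, A: AssociationMatrix,
                r1: int = 5, t1: float = 0.5,
                r2: int = 50, t2: float = 0.8) -> list[tuple[str, str]]:
    """Independently re-check every edge against the criteria; returns the
    list of violating edges (empty when the network is consistent).

    The re-check enumerates rank lists pair by pair rather than reusing the
    vectorized construction path.
    """
    s = np.abs(A.values).copy()
    np.fill_diagonal(s, 0.0)
    idx = {v: i for i, v in enumerate(A.ids)}
    sources = np.asarray(A.sources)

    def rank_of(i: int, j: int) -> int:
        block = np.flatnonzero(sources == sources[j])
        partners = [p for p in block if p != i]
        better = sum(
            1 for p in partners
            if (s[i, p], -p) > (s[i, j], -j)
        )
        return better + 1

    bad = []
    for u, v in net.graph.edges:
        i, j = idx[u], idx[v]
        score = s[i, j]
        c1 = score > t1 and (rank_of(i, j) <= r1 or rank_of(j, i) <= r1)
        c2 = score > t2 and (rank_of(i, j) <= r2 or rank_of(j, i) <= r2)
        if not (c1 or c2):
            bad.append((u, v))
    return bad


def write_network(net: CorrelationNetwork, path) -> None:
    rows = [
        {"source": u, "target": v, "weight": d["weight"],
         "pair_type": d.get("pair_type", "")}
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "pair_type"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


def read_network(path, nodes: list[str] | None = None) -> CorrelationNetwork:
    frame = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for row in frame.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight),
                   pair_type=row.pair_type)
    return CorrelationNetwork(g, nodes or list(g.nodes))
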