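"""Network module detection by Newman modularity maximization.

The default ``spectral`` method recursively bipartitions each connected
component using the leading eigenvector of the (generalized) weighted
modularity matrix, refines each split with Kernighan-Lin-style single-node
moves, and stops when no split increases Q -- so the number of modules is
determined automatically.  A ``greedy`` agglomerative fallback (CNM) is
provided for robustness.  Isolated nodes become singleton modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import CorrelationNetwork

__all__ = ["ModulePartition", "modularity", "detect_modules",
           "write_partition", "read_partition"]

_TOL = 1e-12


@dataclass
class ModulePartition:
    """Non-overlapping assignment of variables to modules.

    ``assignment`` maps variable id to a dense integer module id starting at
    0; ``modularity`` is Newman's Q for this partition on the network it was
    derived from.
    """

    assignment: dict[str, int]
    modularity: float = 0.0

    @property
    def n_modules(self) -> int:
        return max(self.assignment.values()) + 1 if self.assignment else 0

    @property
    def module_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for v, m in self.assignment.items():
            out.setdefault(m, []).append(v)
        return out

    def module_of(self, var_id: str) -> int:
        return self.assignment[var_id]

    @classmethod
    def from_labels(cls, ids: list[str], labels) -> "ModulePartition":
        uniq: dict[int, int] = {}
        assignment = {}
        for v, lab in zip(ids, labels):
            assignment[v] = uniq.setdefault(int(lab), len(uniq))
        return cls(assignment)

    @classmethod
    def singletons(cls, ids: list[str]) -> "ModulePartition":
        """One module per variable (disables module guidance downstream)."""
        return cls({v: i for i, v in enumerate(ids)}, 0.0)


def modularity(net: CorrelationNetwork, part: ModulePartition) -> float:
    """Q = sum_c [ w_in(c)/W - (s(c)/2W)^2 ].

    W is the total edge weight, w_in(c) the intra-module edge weight and
    s(c) the summed weighted degree of module c.  An empty network has Q=0.
    """
    g = net.graph
    W = g.size(weight="weight")
    if W == 0:
        return 0.0
    missing = [v for v in g.nodes if v not in part.assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    w_in: dict[int, float] = {}
    strength: dict[int, float] = {}
    for u, v, w in g.edges(data="weight", default=1.0):
        mu, mv = part.assignment[u], part.assignment[v]
        if mu == mv:
            w_in[mu] = w_in.get(mu, 0.0) + w
        strength[mu] = strength.get(mu, 0.0) + w
        strength[mv] = strength.get(mv, 0.0) + w
    q = 0.0
    for c in set(w_in) | set(strength):
        q += w_in.get(c, 0.0) / W - (strength.get(c, 0.0) / (2 * W)) ** 2
    return q


def _refine_split(B: np.ndarray, s: np.ndarray, max_sweeps: int = 50) -> np.ndarray:
    """Single-node moves between the two sides while any move increases
    s^T B s; each sweep is guaranteed non-decreasing."""
    n = len(s)
    for _ in range(max_sweeps):
        moved = False
        Bs = B @ s
        for i in range(n):
            # flipping s_i changes s^T B s by -4 s_i (Bs_i - B_ii s_i)
            gain = -4.0 * s[i] * (Bs[i] - B[i, i] * s[i])
            if gain > _TOL:
                side = np.sum(s == s[i])
                if side <= 1:
                    continue  # never empty a side
                s[i] = -s[i]
                Bs += 2.0 * s[i] * B[:, i]
                moved = True
        if not moved:
            break
    return s


def _split_group(A: np.ndarray, k: np.ndarray, two_w: float,
                 group: np.ndarray, labels: np.ndarray, next_label: int) -> int:
    """Recursive leading-eigenvector bipartition of one index group."""
    if len(group) < 2:
        return next_label
    sub = A[np.ix_(group, group)]
    kk = k[group]
    B = sub - np.outer(kk, kk) / two_w
    # generalized modularity matrix for splitting a subgroup
    Bg = B - np.diag(B.sum(axis=1))
    evals, evecs = np.linalg.eigh(Bg)
    lead = evecs[:, -1]
    if evals[-1] <= _TOL:
        return next_label
    s = np.where(lead >= -_TOL, 1.0, -1.0)  # near-zero components go positive
    if np.all(s == s[0]):
        return next_label
    s = _refine_split(Bg, s)
    dq = float(s @ Bg @ s) / (2.0 * two_w)
    if dq <= _TOL or np.all(s == s[0]):
        return next_label
    left = group[s > 0]
    right = group[s < 0]
    labels[right] = next_label
    next_label += 1
    next_label = _split_group(A, k, two_w, left, labels, next_label)
    next_label = _split_group(A, k, two_w, right, labels, next_label)
    return next_label


def detect_modules(net: CorrelationNetwork,
                   method: str = "spectral") -> ModulePartition:
    """Partition the network into modules; module count is automatic.

    ``spectral`` is deterministic (seedless linear algebra with fixed tie
    rules); ``greedy`` delegates to CNM agglomeration.
    """
    g = net.graph
    nodes = list(net.node_order)
    if not nodes:
        raise ValueError("empty network")
    if method == "greedy":
        comms = nx.community.greedy_modularity_communities(g, weight="weight")
        lab = {}
        for c, comm in enumerate(comms):
            for v in comm:
                lab[v] = c
        part = ModulePartition.from_labels(nodes, [lab[v] for v in nodes])
        part.modularity = modularity(net, part)
        return part
    if method != "spectral":
        raise ValueError(f"unknown method {method!r}")

    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v, w in g.edges(data="weight", default=1.0):
        A[index[u], index[v]] = w
        A[index[v], index[u]] = w
    k = A.sum(axis=1)
    two_w = k.sum()
    labels = np.zeros(n, dtype=int)
    next_label = 0
    if two_w == 0:
        labels = np.arange(n)  # all isolated
    else:
        # components are split independently; modules never span components
        for comp in nx.connected_components(g):
            idx = np.array(sorted(index[v] for v in comp))
            labels[idx] = next_label
            next_label += 1
            if len(idx) >= 2:
                next_label = _split_group(A, k, two_w, idx, labels, next_label)
    part = ModulePartition.from_labels(nodes, labels)
    part.modularity = modularity(net, part)
    return part


def write_partition(part: ModulePartition, path, summary_path=None) -> None:
    frame = pd.DataFrame(
        {"variable_id": list(part.assignment),
         "module_id": list(part.assignment.values())}
    )
    frame.to_csv(path, sep="\t", index=False)
    if summary_path is not None:
        sizes = frame.groupby("module_id").size().rename("size").reset_index()
        sizes["Q"] = part.modularity
        sizes.to_csv(summary_path, sep="\t", index=False)


def read_partition(path) -> ModulePartition:
    frame = pd.read_csv(path, sep="\t", dtype={"variable_id": str})
    return ModulePartition(
        dict(zip(frame["variable_id"], frame["module_id"].astype(int)))
    )
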