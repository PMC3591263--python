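"""Hypergeometric co-occurrence test of pairwise variable interactions.

Regression trees condition later splits on earlier ones, so two interacting
variables tend to be split on in the same trees.  For variables u, v present
in n and m of the N trees (present = split on at least once in that tree),
the overlap count k follows a hypergeometric distribution under
independence; the right-tail probability P(K >= k) is the interaction
p-value.  A large dedicated ensemble (N = 6000 by default upstream) gives a
stable ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .forest import ForestModel

__all__ = ["PairInteraction", "tree_presence", "hypergeom_right_tail",
           "bh_adjust", "test_all_pairs", "interactions_frame"]

_SOURCE_LABEL = {"marker": "SNP", "transcript": "gene", "other": "other"}


@dataclass
class PairInteraction:
    u: str
    v: str
    pair_type: str
    n: int
    m: int
    k: int
    N: int
    p: float
    q: float = float("nan")


def tree_presence(model: ForestModel) -> dict[str, set[int]]:
    """Map each variable to the set of trees in which it is split on.

    A variable splitting several nodes of one tree counts once for that
    tree (set semantics).
    """
    out: dict[str, set[int]] = {}
    for t_idx, vars_in_tree in enumerate(model.split_var_sets()):
        for v in vars_in_tree:
            out.setdefault(model.variable_ids[v], set()).add(t_idx)
    return out


def hypergeom_right_tail(N: int, n: int, m: int, k: int) -> float:
    """P(K >= k) for K ~ Hypergeom(N, n, m).

    p = sum_{j=k}^{min(n,m)} C(n,j) C(N-n, m-j) / C(N,m).
    """
    if not (0 <= n <= N and 0 <= m <= N):
        raise ValueError("need 0 <= n, m <= N")
    if not (max(0, n + m - N) <= k <= min(n, m)):
        raise ValueError(f"k={k} outside [{max(0, n + m - N)}, {min(n, m)}]")
    # scipy evaluates the tail sum in log space; sf(k-1) = P(K >= k)
    return float(min(1.0, hypergeom.sf(k - 1, N, n, m)))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pair_type(src_u: str, src_v: str) -> str:
    a, b = sorted([_SOURCE_LABEL.get(src_u, "other"),
                   _SOURCE_LABEL.get(src_v, "other")])
    return f"{a}-{b}"


def test_all_pairs(model: ForestModel, min_presence: int = 5,
                   types: set[str] | None = None,
                   sources: dict[str, str] | None = None) -> list[PairInteraction]:
    """Test every variable pair with both presence counts >= min_presence.

    Returns records sorted ascending by p (ties by ids); BH q-values are
    computed over the full tested family.  ``sources`` maps variable id to
    its data source ('marker'/'transcript') for pair typing; when omitted it
    is taken as 'other'.
    """
    presence = tree_presence(model)
    N = model.ntrees
    qualifying = sorted(v for v, s in presence.items() if len(s) >= min_presence)
    records = []
    src = sources or {}
    for u, v in combinations(qualifying, 2):
        pt = _pair_type(src.get(u, "other"), src.get(v, "other"))
        if types is not None and pt not in types:
            continue
        n, m = len(presence[u]), len(presence[v])
        k = len(presence[u] & presence[v])
        p = hypergeom_right_tail(N, n, m, k)
        records.append(PairInteraction(u, v, pt, n, m, k, N, p))
    if not records:
        return []
    q = bh_adjust([r.p for r in records])
    for r, qi in zip(records, q):
        r.q = float(qi)
    records.sort(key=lambda r: (r.p, r.u, r.v))
    return records


# the name starts with "test_" but this is library API, not a pytest case
test_all_pairs.__test__ = False  # type: ignore[attr-defined]


def interactions_frame(records: list[PairInteraction]) -> pd.DataFrame:
    cols = ["u", "v", "pair_type", "n", "m", "k", "N", "p", "q"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)
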