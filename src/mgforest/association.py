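"""Pairwise association measures for mixed-type variables.

Continuous-continuous pairs use Pearson correlation; categorical-categorical
pairs use normalized mutual information (NMI); mixed pairs discretize the
continuous variable into three bins at mean +/- one standard deviation and
then apply NMI.  All measures are returned on an absolute scale when they
enter the network, since the network is only used for grouping and weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import OmicsDataset

__all__ = [
    "pearson",
    "discretize_three_bins",
    "normalized_mi",
    "mixed_association",
    "pairwise_associations",
    "AssociationMatrix",
]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; constant input yields 0 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("constant input to pearson(); association undefined, using 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def discretize_three_bins(x: np.ndarray) -> np.ndarray:
    """Three-bin discretization at mu +/- delta (sample standard deviation).

    Returns integer codes 0 (low: x < mu-delta), 1 (mid, boundaries
    inclusive), 2 (high: x > mu+delta).  A constant vector is all mid.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    delta = x.std(ddof=1) if x.size > 1 else 0.0
    codes = np.ones(x.shape, dtype=int)
    if delta > 0:
        codes[x < mu - delta] = 0
        codes[x > mu + delta] = 2
    return codes


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def normalized_mi(x: np.ndarray, y: np.ndarray) -> float:
    """MI(x, y) / sqrt(H(x) * H(y)) with natural-log empirical entropies.

    Returns 0 when either marginal entropy is 0 (constant variable).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny).astype(float)
    hx = _entropy(joint.sum(axis=1))
    hy = _entropy(joint.sum(axis=0))
    if hx == 0 or hy == 0:
        return 0.0
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float((p[mask] * np.log(p[mask] / (px @ py)[mask])).sum())
    return min(1.0, mi / np.sqrt(hx * hy))


def mixed_association(x: np.ndarray, g: np.ndarray) -> float:
    """Association of a continuous vector with a categorical one: NMI after
    three-bin discretization of the continuous side."""
    return normalized_mi(discretize_three_bins(x), g)


@dataclass
class AssociationMatrix:
    """Symmetric grid of association scores over a dataset's variables.

    ``values[i, j]`` is Pearson r (signed) for continuous pairs and NMI in
    [0, 1] otherwise; the diagonal is 1 for non-constant variables.
    ``sources``/``kinds`` carry the per-variable tags needed for the
    per-block ranking in network construction.
    """

    ids: list[str]
    values: np.ndarray
    kinds: list[str]
    sources: list[str]

    def pair_type(self, i: int, j: int) -> str:
        a, b = sorted([self.kinds[i], self.kinds[j]])
        return {"categorical,categorical": "cat-cat",
                "continuous,continuous": "cont-cont",
                "categorical,continuous": "cat-cont"}[f"{a},{b}"]

    @property
    def n(self) -> int:
        return len(self.ids)


def _codes_matrix(values: np.ndarray, kinds: list[str], cols: np.ndarray) -> np.ndarray:
    """Integer codes for the given columns (discretizing continuous ones)."""
    out = np.empty((values.shape[0], len(cols)), dtype=int)
    for k, j in enumerate(cols):
        col = values[:, j]
        if kinds[j] == "categorical":
            _, out[:, k] = np.unique(col, return_inverse=True)
        else:
            out[:, k] = discretize_three_bins(col)
    return out


def _nmi_block(a_codes: np.ndarray, b_codes: np.ndarray) -> np.ndarray:
    """All-pairs NMI between two code matrices, via one-hot contraction."""
    n = a_codes.shape[0]
    la = int(a_codes.max()) + 1 if a_codes.size else 1
    lb = int(b_codes.max()) + 1 if b_codes.size else 1
    oa = np.zeros((n, a_codes.shape[1], la))
    ob = np.zeros((n, b_codes.shape[1], lb))
    rows = np.arange(n)[:, None]
    oa[rows, np.arange(a_codes.shape[1])[None, :], a_codes] = 1.0
    ob[rows, np.arange(b_codes.shape[1])[None, :], b_codes] = 1.0
    joint = np.einsum("npa,nqb->pqab", oa, ob) / n  # p x q x la x lb
    pa = joint.sum(axis=3)  # p x q x la
    pb = joint.sum(axis=2)  # p x q x lb
    mask = joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.log(joint) - np.log(pa[..., :, None]) - np.log(pb[..., None, :])
    contrib = np.zeros_like(joint)
    contrib[mask] = joint[mask] * log_term[mask]
    mi = contrib.sum(axis=(2, 3))
    ha = np.where(pa[:, 0, :] > 0, -pa[:, 0, :] * np.log(pa[:, 0, :]), 0.0).sum(axis=1)
    hb = np.where(pb[0, :, :] > 0, -pb[0, :, :] * np.log(pb[0, :, :]), 0.0).sum(axis=1)
    denom = np.sqrt(ha[:, None] * hb[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        nmi = np.where(denom > 0, mi / denom, 0.0)
    return np.clip(nmi, 0.0, 1.0)


def pairwise_associations(d: OmicsDataset) -> AssociationMatrix:
    """Association matrix over all variable pairs, dispatching per pair type.

    Constant variables get association 0 to everything (and diagonal 0), so
    they become isolated nodes downstream.
    """
    kinds = [v.kind for v in d.variables]
    sources = [v.source for v in d.variables]
    m = d.n_variables
    values = d.values
    out = np.zeros((m, m))
    cont = np.array([k == "continuous" for k in kinds])
    cat = ~cont
    constant = values.std(axis=0) == 0

    ci = np.flatnonzero(cont & ~constant)
    if ci.size >= 1:
        r = np.corrcoef(values[:, ci], rowvar=False)
        r = np.atleast_2d(r)
        out[np.ix_(ci, ci)] = r

    ki = np.flatnonzero(cat & ~constant)
    if ki.size >= 1:
        codes = _codes_matrix(values, kinds, ki)
        out[np.ix_(ki, ki)] = _nmi_block(codes, codes)

    if ci.size and ki.size:
        ccodes = _codes_matrix(values, kinds, ci)
        kcodes = _codes_matrix(values, kinds, ki)
        block = _nmi_block(ccodes, kcodes)
        out[np.ix_(ci, ki)] = block
        out[np.ix_(ki, ci)] = block.T

    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    nonconst = np.flatnonzero(~constant)
    out[nonconst, nonconst] = 1.0
    return AssociationMatrix(d.variable_ids, out, kinds, sources)
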