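"""Typed containers and TSV I/O for genotype, expression and phenotype tables.

The central object is :class:`OmicsDataset`, a samples x variables table with
per-variable metadata (categorical marker vs continuous transcript), plus a
:class:`PhenotypeVector` aligned to it by sample id.  Genotypes are small
integer category codes (an F2 intercross has three classes, coded 0/1/2);
expression values are continuous.  Missing cells are rejected at validation
time -- imputation is an explicit, separate step (:func:`impute`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableDescriptor",
    "OmicsDataset",
    "PhenotypeVector",
    "DataValidationError",
    "read_dataset",
    "write_dataset",
    "read_phenotype",
    "write_phenotype",
    "merge_datasets",
    "align_phenotype",
    "impute",
]

#: columns with at most this many distinct integer values are auto-detected
#: as categorical (F2 genotypes have 3 levels)
DEFAULT_MAX_LEVELS = 10


class DataValidationError(ValueError):
    """Raised when a table violates the dataset contract."""


@dataclass(frozen=True)
class VariableDescriptor:
    """Metadata for one variable (column) of an :class:`OmicsDataset`.

    Parameters
    ----------
    id : str
        Unique variable identifier.
    kind : {"categorical", "continuous"}
    source : {"marker", "transcript", "other"}
        Data type the variable came from; drives per-block ranking in the
        correlation network and pair typing in the interaction test.
    n_levels : int, optional
        Number of category codes (categorical variables only, >= 2).
    chromosome, position_mb : optional genomic location.
    """

    id: str
    kind: str
    source: str = "other"
    n_levels: int | None = None
    chromosome: str | None = None
    position_mb: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise DataValidationError(f"unknown kind {self.kind!r} for {self.id!r}")
        if self.source not in ("marker", "transcript", "other"):
            raise DataValidationError(f"unknown source {self.source!r} for {self.id!r}")
        if self.kind == "categorical":
            if self.n_levels is None or self.n_levels < 2:
                raise DataValidationError(
                    f"categorical variable {self.id!r} needs n_levels >= 2"
                )
        if self.position_mb is not None:
            if self.chromosome is None:
                raise DataValidationError(
                    f"{self.id!r}: position_mb given without chromosome"
                )
            if self.position_mb < 0:
                raise DataValidationError(f"{self.id!r}: negative position_mb")


@dataclass
class OmicsDataset:
    """Samples x variables numeric grid with per-variable metadata.

    ``values`` is a float ndarray; categorical columns hold integer codes in
    ``[0, n_levels)``.  No missing cells are permitted.
    """

    sample_ids: list[str]
    variables: list[VariableDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataValidationError("values must be 2-D (samples x variables)")
        if self.values.shape != (len(self.sample_ids), len(self.variables)):
            raise DataValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variables)} variables"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataValidationError("duplicate sample ids")
        ids = [v.id for v in self.variables]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate variable ids: {dupes}")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            r, c = bad[0]
            raise DataValidationError(
                f"missing/non-finite cell at sample {self.sample_ids[r]!r}, "
                f"variable {self.variables[c].id!r}"
            )
        for j, v in enumerate(self.variables):
            if v.kind == "categorical":
                col = self.values[:, j]
                if not np.array_equal(col, np.round(col)):
                    raise DataValidationError(
                        f"categorical variable {v.id!r} has non-integer codes"
                    )
                if col.min() < 0 or col.max() >= v.n_levels:
                    raise DataValidationError(
                        f"categorical variable {v.id!r} has codes outside "
                        f"[0, {v.n_levels})"
                    )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def variable_ids(self) -> list[str]:
        return [v.id for v in self.variables]

    def column(self, var_id: str) -> np.ndarray:
        return self.values[:, self.variable_ids.index(var_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.variable_ids,
        )

    def select_variables(self, ids: Sequence[str]) -> "OmicsDataset":
        pos = {v.id: j for j, v in enumerate(self.variables)}
        idx = [pos[i] for i in ids]
        return OmicsDataset(
            sample_ids=list(self.sample_ids),
            variables=[self.variables[j] for j in idx],
            values=self.values[:, idx].copy(),
        )

    def select_samples(self, rows: Sequence[int]) -> "OmicsDataset":
        rows = list(rows)
        return OmicsDataset(
            sample_ids=[self.sample_ids[i] for i in rows],
            variables=list(self.variables),
            values=self.values[rows, :].copy(),
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        kind_map: Mapping[str, str] | str = "auto",
        source: str | Mapping[str, str] = "other",
        max_levels: int = DEFAULT_MAX_LEVELS,
    ) -> "OmicsDataset":
        """Build a dataset from a DataFrame, inferring variable kinds.

        Integer-valued columns with at most ``max_levels`` distinct values are
        treated as categorical unless overridden through ``kind_map``.
        """
        values = frame.to_numpy(dtype=float)
        variables = []
        for j, col in enumerate(frame.columns):
            kind = None
            if isinstance(kind_map, Mapping):
                kind = kind_map.get(col)
            elif kind_map != "auto":
                kind = kind_map
            colv = values[:, j]
            if kind is None:
                finite = colv[np.isfinite(colv)]
                is_int = finite.size > 0 and np.array_equal(finite, np.round(finite))
                kind = (
                    "categorical"
                    if is_int and np.unique(finite).size <= max_levels
                    else "continuous"
                )
            src = source[col] if isinstance(source, Mapping) else source
            if kind == "categorical":
                n_levels = max(2, int(np.nanmax(colv)) + 1) if colv.size else 2
                variables.append(
                    VariableDescriptor(str(col), "categorical", src, n_levels=n_levels)
                )
            else:
                variables.append(VariableDescriptor(str(col), "continuous", src))
        return cls([str(s) for s in frame.index], variables, values)


@dataclass
class PhenotypeVector:
    """Continuous trait values (e.g. body weight in grams) keyed by sample id."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise DataValidationError("phenotype must be 1-D, one value per sample")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataValidationError("duplicate sample ids in phenotype")
        if not np.all(np.isfinite(self.values)):
            i = int(np.argwhere(~np.isfinite(self.values))[0])
            raise DataValidationError(
                f"missing phenotype value for sample {self.sample_ids[i]!r}"
            )

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            name="phenotype",
        )


# -- I/O ----------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    nan_cells = frame.isna()
    if nan_cells.to_numpy().any():
        r, c = np.argwhere(nan_cells.to_numpy())[0]
        raise DataValidationError(
            f"{path}: empty cell at sample {frame.index[r]!r}, "
            f"variable {frame.columns[c]!r}"
        )
    try:
        out = frame.astype(float)
    except ValueError as exc:
        raise DataValidationError(f"{path}: non-numeric cell ({exc})") from exc
    return out


def read_dataset(
    path,
    kind_map: Mapping[str, str] | str = "auto",
    metadata_path=None,
    source: str | Mapping[str, str] = "other",
    max_levels: int = DEFAULT_MAX_LEVELS,
) -> OmicsDataset:
    """Read a matrix TSV (header = variable ids, first column = sample id).

    ``metadata_path`` may point to a sidecar TSV with columns
    ``id, kind, source, chromosome, position_mb`` overriding inference.
    """
    frame = _read_table(path)
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        meta = meta.set_index("id")
        kind_map = dict(meta["kind"]) if "kind" in meta else kind_map
        if "source" in meta:
            source = dict(meta["source"])
        ds = OmicsDataset.from_frame(frame, kind_map, source, max_levels)
        variables = []
        for v in ds.variables:
            if v.id in meta.index:
                row = meta.loc[v.id]
                chrom = row.get("chromosome")
                chrom = None if pd.isna(chrom) else str(chrom)
                pos = row.get("position_mb")
                pos = None if pd.isna(pos) else float(pos)
                v = replace(v, chromosome=chrom, position_mb=pos)
            variables.append(v)
        ds.variables = variables
        return ds
    return OmicsDataset.from_frame(frame, kind_map, source, max_levels)


def write_dataset(ds: OmicsDataset, path, metadata_path=None) -> None:
    frame = ds.to_frame()
    # keep categorical codes as integers so the round trip is bit-stable
    for j, v in enumerate(ds.variables):
        if v.kind == "categorical":
            frame[v.id] = frame[v.id].astype(int)
    frame.to_csv(path, sep="\t", float_format="%.12g")
    if metadata_path is not None:
        meta = pd.DataFrame(
            {
                "id": [v.id for v in ds.variables],
                "kind": [v.kind for v in ds.variables],
                "source": [v.source for v in ds.variables],
                "chromosome": [v.chromosome or "" for v in ds.variables],
                "position_mb": [
                    "" if v.position_mb is None else v.position_mb
                    for v in ds.variables
                ],
            }
        )
        meta.to_csv(metadata_path, sep="\t", index=False)


def read_phenotype(path) -> PhenotypeVector:
    frame = _read_table(path)
    if frame.shape[1] != 1:
        raise DataValidationError(f"{path}: phenotype TSV must have one value column")
    return PhenotypeVector(list(frame.index), frame.iloc[:, 0].to_numpy())


def write_phenotype(y: PhenotypeVector, path) -> None:
    y.to_series().to_frame().to_csv(path, sep="\t", float_format="%.12g")


# -- combination / alignment ---------------------------------------------------


def merge_datasets(a: OmicsDataset, b: OmicsDataset) -> OmicsDataset:
    """Column-concatenate two datasets over the same samples.

    ``b`` is reordered to ``a``'s sample order; source tags are preserved.
    """
    if set(a.sample_ids) != set(b.sample_ids):
        only_a = sorted(set(a.sample_ids) - set(b.sample_ids))
        only_b = sorted(set(b.sample_ids) - set(a.sample_ids))
        raise DataValidationError(
            f"sample sets differ: only in first={only_a}, only in second={only_b}"
        )
    order = [b.sample_ids.index(s) for s in a.sample_ids]
    return OmicsDataset(
        sample_ids=list(a.sample_ids),
        variables=list(a.variables) + list(b.variables),
        values=np.hstack([a.values, b.values[order, :]]),
    )


def align_phenotype(d: OmicsDataset, y: PhenotypeVector) -> PhenotypeVector:
    """Reorder/subset ``y`` to ``d``'s sample order (alignment is by id)."""
    pos = {s: i for i, s in enumerate(y.sample_ids)}
    missing = [s for s in d.sample_ids if s not in pos]
    if missing:
        raise DataValidationError(f"phenotype missing samples: {missing}")
    idx = [pos[s] for s in d.sample_ids]
    return PhenotypeVector(list(d.sample_ids), y.values[idx])


def impute(frame: pd.DataFrame, strategy: str = "mean") -> pd.DataFrame:
    """Fill missing cells column-wise by mean (continuous) or mode.

    Never applied implicitly: callers opt in before building an
    :class:`OmicsDataset`, which rejects NaN.
    """
    out = frame.copy()
    for col in out.columns:
        if strategy == "mean":
            out[col] = out[col].fillna(out[col].mean())
        elif strategy == "mode":
            out[col] = out[col].fillna(out[col].mode().iloc[0])
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    return out
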