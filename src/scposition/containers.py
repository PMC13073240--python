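"""Core in-memory containers for the positional-inference pipeline.

The pipeline works on dense cell × gene matrices carrying an explicit layer
tag (``counts``, ``lognorm`` or ``zscore``) so that every downstream
operation can state, and check, which representation it expects.  Cells and
genes are addressed by unique string identifiers; all alignment between
matrices, annotation tables and trained models happens by gene symbol, never
by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LAYERS = ("counts", "lognorm", "zscore")


class FormatError(ValueError):
    """Raised when an on-disk file or in-memory object violates a format contract."""


def _check_unique(ids: Sequence[str], axis: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1 or arr.size == 0:
        raise FormatError(f"{axis} ids must be a non-empty 1-D sequence")
    if len(set(arr.tolist())) != arr.size:
        dupes = pd.Index(arr)[pd.Index(arr).duplicated()].unique().tolist()
        raise FormatError(f"duplicate {axis} ids: {dupes[:5]}")
    return arr


@dataclass
class ExpressionMatrix:
    """Dense cells × genes expression matrix with a layer tag.

    Parameters
    ----------
    cell_ids, gene_ids
        Unique string identifiers for rows (cells) and columns (genes).
    values
        ``(n_cells, n_genes)`` numeric array.  For ``layer="counts"`` all
        entries must be non-negative integers.
    layer
        One of ``counts``, ``lognorm``, ``zscore``.
    """

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    values: np.ndarray
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.cell_ids.size, self.gene_ids.size):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{self.cell_ids.size} cells × {self.gene_ids.size} genes"
            )
        if self.layer not in LAYERS:
            raise FormatError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if np.isnan(self.values).any():
            raise FormatError("matrix contains NaN")
        if self.layer == "counts":
            if (self.values < 0).any():
                i, j = np.argwhere(self.values < 0)[0]
                raise FormatError(
                    f"negative count at cell {self.cell_ids[i]!r}, gene {self.gene_ids[j]!r}"
                )
            if not np.array_equal(self.values, np.round(self.values)):
                i, j = np.argwhere(self.values != np.round(self.values))[0]
                raise FormatError(
                    f"non-integer count at cell {self.cell_ids[i]!r}, gene {self.gene_ids[j]!r}"
                )

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = pd.Index(self.cell_ids).get_indexer(list(mask_or_ids))
            if (pos < 0).any():
                missing = np.asarray(list(mask_or_ids))[pos < 0]
                raise KeyError(f"unknown cell ids: {missing[:5].tolist()}")
            idx = pos
        return ExpressionMatrix(self.cell_ids[idx], self.gene_ids, self.values[idx], self.layer)

    def reindex_genes(self, gene_order: Sequence[str], fill: float = 0.0) -> "ExpressionMatrix":
        """Reorder columns to ``gene_order``; genes absent from the matrix are fill-valued."""
        order = _check_unique(gene_order, "gene")
        pos = pd.Index(self.gene_ids).get_indexer(order.tolist())
        out = np.full((self.n_cells, order.size), float(fill))
        present = pos >= 0
        out[:, present] = self.values[:, pos[present]]
        return ExpressionMatrix(self.cell_ids, order, out, self.layer)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class CellAnnotation:
    """Per-cell compartment labels plus optional categorical covariates."""

    cell_ids: np.ndarray
    compartment: np.ndarray
    covariates: dict = field(default_factory=dict)
    label_set: tuple = ()

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.compartment = np.asarray(self.compartment, dtype=object)
        if self.compartment.size != self.cell_ids.size:
            raise FormatError("compartment length does not match cell ids")
        if not self.label_set:
            self.label_set = tuple(sorted(set(self.compartment.tolist())))
        else:
            self.label_set = tuple(self.label_set)
            extra = set(self.compartment.tolist()) - set(self.label_set)
            if extra:
                raise FormatError(f"compartment values outside declared label set: {sorted(extra)}")
        for name, vals in self.covariates.items():
            arr = np.asarray(vals, dtype=object)
            if arr.size != self.cell_ids.size:
                raise FormatError(f"covariate {name!r} length does not match cell ids")
            self.covariates[name] = arr

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    def aligned_to(self, cell_ids: Sequence[str]) -> "CellAnnotation":
        """Return a copy whose rows follow ``cell_ids`` (must all be present)."""
        pos = pd.Index(self.cell_ids).get_indexer(list(cell_ids))
        if (pos < 0).any():
            raise KeyError("annotation is missing some requested cell ids")
        return CellAnnotation(
            np.asarray(list(cell_ids), dtype=object),
            self.compartment[pos],
            {k: v[pos] for k, v in self.covariates.items()},
            self.label_set,
        )

    def with_covariate(self, name: str, values) -> "CellAnnotation":
        cov = dict(self.covariates)
        cov[name] = np.asarray(values, dtype=object)
        return CellAnnotation(self.cell_ids, self.compartment, cov, self.label_set)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"compartment": self.compartment}, index=self.cell_ids)
        for name, vals in self.covariates.items():
            df[name] = vals
        return df


PROVENANCES = ("hvg", "fam", "rfe", "mir", "random", "custom")


@dataclass
class GeneSet:
    """Named, de-duplicated, ordered list of gene symbols."""

    name: str
    genes: list
    provenance: str = "custom"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        genes = [str(g) for g in self.genes]
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen: dict = {}
        for g in genes:
            if not g:
                raise ValueError(f"gene set {self.name!r} contains an empty symbol")
            seen.setdefault(g, None)
        self.genes = list(seen)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in set(self.genes)


@dataclass
class HomologyTable:
    """Ordered source → target gene-symbol mapping (e.g. mouse → human)."""

    pairs: list

    def __post_init__(self) -> None:
        mapping: dict = {}
        for src, tgt in self.pairs:
            src, tgt = str(src), str(tgt)
            if not src or not tgt:
                raise FormatError("homology table contains an empty symbol")
            if src in mapping and mapping[src] != tgt:
                raise FormatError(f"source symbol {src!r} maps to multiple targets")
            mapping.setdefault(src, tgt)
        if not mapping:
            raise FormatError("homology table is empty")
        self.pairs = [(s, t) for s, t in mapping.items()]
        self.mapping = mapping

    def __len__(self) -> int:
        return len(self.pairs)

    def inverted(self) -> "HomologyTable":
        return HomologyTable([(t, s) for s, t in self.pairs])
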