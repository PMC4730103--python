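"""Cell-type specificity matrices from annotated single-cell expression data.

The reference for an enrichment analysis is a single-cell expression matrix
(genes x cells, non-negative counts) whose cells carry a two-level annotation:
each cell belongs to exactly one *sub-cell type* (a fine cluster such as
``Int1`` or ``Peric``) and each sub-cell type belongs to exactly one *cell
type* (``interneuron``, ``pericyte`` ...).

The pipeline is:

1. average the raw expression of every gene within each sub-cell type;
2. drop genes whose largest sub-cell-type mean does not exceed a low-expression
   threshold (0.2 by default) -- a handful of reads in one cell would otherwise
   make a gene look like a perfectly specific marker;
3. divide each gene's mean in a sub-cell type by the sum of its means over all
   sub-cell types, giving the *specificity* ``e[g, c]`` -- the fraction of the
   gene's total mean expression attributable to sub-cell type ``c``.  Rows sum
   to one, so specificity is independent of a gene's overall expression level;
4. optionally sum specificity columns over the sub-cell types of each cell
   type, giving the cell-type-level specificity ``p[g, e]`` (rows still sum to
   one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("ewce")

#: Genes whose largest sub-cell-type mean expression is <= this value are
#: dropped before specificity is computed (strict ">" keeps a gene).
DEFAULT_EXPRESSION_THRESHOLD = 0.2

ROW_SUM_TOL = 1e-9


class EwceError(ValueError):
    """Base class for invalid inputs or internal inconsistencies."""


@dataclass
class SingleCellDataset:
    """An annotated single-cell expression matrix.

    Parameters
    ----------
    expression
        Genes x cells matrix of non-negative expression values (e.g. UMI
        counts).  Index: unique gene symbols; columns: unique cell ids.
    subtype_of_cell
        Series mapping cell id -> sub-cell-type label, covering every column
        of ``expression``.
    celltype_of_subtype
        Mapping sub-cell type -> cell type, covering every sub-cell type.
    normalize
        Optional per-cell pre-normalization hook ``matrix -> matrix``.  Off by
        default: the method operates on raw counts.
    """

    expression: pd.DataFrame
    subtype_of_cell: pd.Series
    celltype_of_subtype: dict[str, str]
    normalize: object = None

    def __post_init__(self) -> None:
        expr = self.expression
        expr.index = expr.index.astype(str).str.strip()
        if expr.index.duplicated().any():
            dups = expr.index[expr.index.duplicated()].unique().tolist()
            raise EwceError(f"duplicate gene symbols in expression matrix: {dups[:10]}")
        if expr.columns.duplicated().any():
            raise EwceError("duplicate cell ids in expression matrix")
        vals = expr.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise EwceError("expression matrix contains non-numeric entries")
        if np.isnan(vals).any() or (vals < 0).any():
            raise EwceError("expression values must be finite and non-negative")
        missing = [c for c in expr.columns if c not in self.subtype_of_cell.index]
        if missing:
            raise EwceError(f"cells missing a sub-cell-type annotation: {missing[:10]}")
        self.subtype_of_cell = self.subtype_of_cell.loc[expr.columns].astype(str)
        unmapped = sorted(
            set(self.subtype_of_cell) - set(self.celltype_of_subtype)
        )
        if unmapped:
            raise EwceError(f"sub-cell types missing a cell-type parent: {unmapped}")
        if self.normalize is not None:
            self.expression = self.normalize(expr)

    @property
    def gene_symbols(self) -> pd.Index:
        return self.expression.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def subtypes(self) -> list[str]:
        # deterministic order: first appearance over the cell columns
        return list(dict.fromkeys(self.subtype_of_cell))


@dataclass
class SubtypeMeanMatrix:
    """Mean expression of each gene within each sub-cell type."""

    values: pd.DataFrame            # genes x subtypes
    n_cells_per_subtype: pd.Series  # subtype -> N_c


@dataclass
class SpecificityMatrix:
    """Row-stochastic genes x groups matrix of expression specificity.

    ``level`` is ``"subtype"`` or ``"celltype"``; ``genes_dropped`` records
    the symbols removed by the low-expression filter.
    """

    values: pd.DataFrame
    level: str
    genes_dropped: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def groups(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        vals = self.values.to_numpy()
        if ((vals < -ROW_SUM_TOL) | (vals > 1 + ROW_SUM_TOL)).any():
            raise EwceError("specificity entries outside [0, 1]")
        rowsum = vals.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=ROW_SUM_TOL, rtol=0):
            bad = self.values.index[np.abs(rowsum - 1.0) > ROW_SUM_TOL]
            raise EwceError(f"specificity rows do not sum to 1: {list(bad[:10])}")


def mean_expression_by_subtype(dataset: SingleCellDataset) -> SubtypeMeanMatrix:
    """Average each gene's expression over the cells of every sub-cell type."""
    labels = dataset.subtype_of_cell
    order = dataset.subtypes
    counts = labels.value_counts()
    empty = [s for s in order if counts.get(s, 0) < 1]
    if empty:  # unreachable via the constructor, but guards hand-built inputs
        raise EwceError(f"sub-cell types with zero cells: {empty}")
    means = dataset.expression.T.groupby(labels).mean().T
    means = means[order]
    return SubtypeMeanMatrix(values=means, n_cells_per_subtype=counts.loc[order])


def drop_low_expression_genes(
    means: SubtypeMeanMatrix,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> SubtypeMeanMatrix:
    """Remove genes whose best sub-cell-type mean does not exceed ``threshold``.

    A gene is kept iff ``max_c mean[g, c] > threshold`` (strict): a gene whose
    maximum equals the threshold exactly is dropped.
    """
    if threshold < 0:
        raise EwceError("expression threshold must be >= 0")
    keep = means.values.max(axis=1) > threshold
    if not keep.any():
        raise EwceError(
            "low-expression filter removed every gene; "
            f"no gene has a sub-cell-type mean above {threshold}"
        )
    dropped = means.values.index[~keep]
    if len(dropped):
        logger.info("low-expression filter dropped %d genes", len(dropped))
    filtered = SubtypeMeanMatrix(
        values=means.values.loc[keep],
        n_cells_per_subtype=means.n_cells_per_subtype,
    )
    filtered.values.attrs["genes_dropped"] = list(dropped)
    return filtered


def compute_subtype_specificity(means: SubtypeMeanMatrix) -> SpecificityMatrix:
    """Row-normalize sub-cell-type means into specificity fractions."""
    totals = means.values.sum(axis=1)
    if (totals <= 0).any():
        bad = list(means.values.index[totals <= 0][:10])
        raise EwceError(
            f"genes with all-zero means reached specificity computation: {bad}; "
            "apply the low-expression filter first"
        )
    spec = SpecificityMatrix(
        values=means.values.div(totals, axis=0),
        level="subtype",
        genes_dropped=list(means.values.attrs.get("genes_dropped", [])),
    )
    spec.validate()
    return spec


def aggregate_specificity_to_celltype(
    spec: SpecificityMatrix, celltype_of_subtype: Mapping[str, str]
) -> SpecificityMatrix:
    """Sum sub-cell-type specificity columns within each cell type."""
    if spec.level != "subtype":
        raise EwceError("aggregation requires a subtype-level specificity matrix")
    missing = [s for s in spec.groups if s not in celltype_of_subtype]
    if missing:
        raise EwceError(f"sub-cell types missing from the cell-type map: {missing}")
    parents = [celltype_of_subtype[s] for s in spec.groups]
    order = list(dict.fromkeys(parents))
    agg = spec.values.T.groupby(pd.Series(parents, index=spec.values.columns)).sum().T
    out = SpecificityMatrix(
        values=agg[order], level="celltype", genes_dropped=list(spec.genes_dropped)
    )
    out.validate()
    return out


def specificity_from_dataset(
    dataset: SingleCellDataset,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> tuple[SpecificityMatrix, SpecificityMatrix]:
    """Full pipeline: return (subtype-level, celltype-level) specificity."""
    means = drop_low_expression_genes(mean_expression_by_subtype(dataset), threshold)
    sub = compute_subtype_specificity(means)
    return sub, aggregate_specificity_to_celltype(sub, dataset.celltype_of_subtype)
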