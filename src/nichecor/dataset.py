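"""Core data container for spatial single-cell expression.

A :class:`SpatialDataset` bundles a cells x genes count matrix with
per-cell coordinates, cell-type labels, optional technical covariates
(total counts, negative-control-probe counts, ...) and an optional
sample id.  Rows of every per-cell attribute are aligned with the rows
of ``counts``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DataError

__all__ = ["SpatialDataset", "filter_min_counts", "normalize_total_counts"]


@dataclass
class SpatialDataset:
    """Cells x genes expression with spatial and phenotypic annotation.

    Parameters
    ----------
    counts
        Non-negative cells x genes matrix, sparse (CSR) or dense.  Raw
        integer counts on construction; real-valued after normalization.
    positions
        ``(n_cells, 2)`` array of x/y coordinates in consistent length
        units (the unit also applies to radius parameters downstream).
    cell_type
        Per-cell categorical label.
    covariates
        Optional per-cell numeric covariates (e.g. ``total_counts``,
        ``negprobes``), one row per cell.
    sample_id
        Optional per-cell sample/tissue identifier.
    gene_ids, cell_ids
        Unique, ordered identifiers for columns and rows.
    normalized
        True once each row has been divided by its raw total.
    """

    counts: sp.spmatrix | np.ndarray
    positions: np.ndarray
    cell_type: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    covariates: pd.DataFrame | None = None
    sample_id: np.ndarray | None = None
    normalized: bool = False
    raw_totals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            self.counts = sp.csr_matrix(self.counts, dtype=np.float64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.cell_type = np.asarray(self.cell_type)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        self._validate()

    def _validate(self) -> None:
        n, g = self.counts.shape
        if self.counts.min() < 0:
            raise DataError("counts matrix contains negative entries")
        if self.positions.shape != (n, 2):
            raise DataError(
                f"positions shape {self.positions.shape} does not match {n} cells"
            )
        if not np.isfinite(self.positions).all():
            raise DataError("positions contain non-finite values")
        if len(self.cell_type) != n:
            raise DataError("cell_type length does not match number of cells")
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise DataError("id lengths do not match counts dimensions")
        if self.cell_ids.has_duplicates:
            dups = self.cell_ids[self.cell_ids.duplicated()].unique().tolist()
            raise DataError(f"duplicate cell ids: {dups[:5]}")
        if self.gene_ids.has_duplicates:
            dups = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene ids: {dups[:5]}")
        if self.covariates is not None and len(self.covariates) != n:
            raise DataError("covariates row count does not match number of cells")
        if self.sample_id is not None and len(self.sample_id) != n:
            raise DataError("sample_id length does not match number of cells")

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Per-cell raw total counts (pre-normalization totals if normalized)."""
        if self.normalized:
            if self.raw_totals is None:
                raise DataError("normalized dataset lost its raw totals")
            return self.raw_totals
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def counts_dense(self) -> np.ndarray:
        m = self.counts
        return m.toarray() if sp.issparse(m) else np.asarray(m)

    def subset_cells(self, mask_or_idx) -> "SpatialDataset":
        """Row-subset every per-cell attribute, preserving order."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            counts=self.counts[idx],
            positions=self.positions[idx],
            cell_type=self.cell_type[idx],
            cell_ids=self.cell_ids[idx],
            covariates=None if self.covariates is None else self.covariates.iloc[idx].reset_index(drop=True),
            sample_id=None if self.sample_id is None else self.sample_id[idx],
            raw_totals=None if self.raw_totals is None else self.raw_totals[idx],
        )

    def subset_genes(self, genes) -> "SpatialDataset":
        genes = pd.Index(genes)
        missing = genes.difference(self.gene_ids)
        if len(missing):
            raise DataError(f"unknown genes: {missing.tolist()[:5]}")
        pos = self.gene_ids.get_indexer(genes)
        return replace(self, counts=self.counts[:, pos], gene_ids=genes)


def filter_min_counts(ds: SpatialDataset, min_counts: int) -> SpatialDataset:
    """Drop cells whose raw total counts fall below ``min_counts``.

    Cells with total exactly equal to ``min_counts`` are kept (a filter
    described as removing cells *below* a threshold keeps the boundary).
    Must be applied before normalization, while row totals are raw counts.
    """
    if ds.normalized:
        raise DataError("filter_min_counts must be applied before normalization")
    totals = ds.total_counts()
    return ds.subset_cells(totals >= min_counts)


def normalize_total_counts(ds: SpatialDataset) -> SpatialDataset:
    """Divide each cell's expression profile by its total counts.

    Produces per-cell proportions (rows sum to 1).  Any constant rescaling
    would cancel in the correlations computed downstream, so none is
    applied.  Zero-total cells must be filtered out first.
    """
    if ds.normalized:
        raise DataError("dataset is already normalized")
    totals = ds.total_counts()
    if (totals <= 0).any():
        n_zero = int((totals <= 0).sum())
        raise DataError(
            f"{n_zero} cells have zero total counts; run filter_min_counts first"
        )
    inv = 1.0 / totals
    if sp.issparse(ds.counts):
        norm = sp.diags(inv) @ ds.counts
        norm = sp.csr_matrix(norm)
    else:
        norm = ds.counts * inv[:, None]
    return replace(ds, counts=norm, normalized=True, raw_totals=totals)
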