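"""Module scoring and cell-type attribution.

A module m with per-gene weights w_j is scored per cell,
M_{i,m} = sum_j w_j Y_{ij}, and per environment,
M^(N)_{i,m} = sum_j w_j Y^(N)_{i,j}.  Default weights are inverse
square roots of mean environment expression, w_j = mean(Y^(N)_.,j)^-0.5,
which counteracts the Poisson-like mean-variance relation of count data
so highly expressed genes do not dominate the score.

Cell-type attribution asks which cell types drive a module:
A(j,c) = cor( M^(N)_.,m , Y^(N,c)_.,j ), the correlation between the
module's environment score and the neighborhood expression of gene j
contributed by cells of type c alone; the cell-type summary is
A(c) = max_j A(j,c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import SpatialDataset
from .errors import DataError
from .modules import ModuleSet
from .neighbors import EnvironmentMatrix, NeighborGraph

log = logging.getLogger(__name__)

__all__ = [
    "ScoreMatrix",
    "AttributionTable",
    "gene_weights",
    "module_scores",
    "celltype_env_expression",
    "attribution",
]


@dataclass
class ScoreMatrix:
    """Cells x modules scores at single-cell and environment level."""

    cell_scores: np.ndarray
    env_scores: np.ndarray
    module_names: list
    weights_used: dict  # module name -> {gene: weight}


@dataclass
class AttributionTable:
    """Gene-level A(j,c) and cell-type-level A(c) involvement scores."""

    gene_level: list = field(default_factory=list)      # (module, gene, cell_type, value)
    celltype_level: list = field(default_factory=list)  # (module, cell_type, value)

    def celltype_score(self, module: str, cell_type: str) -> float:
        for m, c, v in self.celltype_level:
            if m == module and c == cell_type:
                return v
        raise KeyError((module, cell_type))


def gene_weights(env_expr: EnvironmentMatrix, genes) -> dict:
    """Inverse-square-root weights w_j = mean(Y^(N)_.,j)^-0.5.

    Genes with zero mean environment expression are excluded with a
    warning (they carry no signal to weight).
    """
    env = env_expr.dense()
    index = {g: i for i, g in enumerate(env_expr.feature_ids)}
    weights: dict = {}
    for g in genes:
        if g not in index:
            raise DataError(f"gene '{g}' not present in environment matrix")
        m = env[:, index[g]].mean()
        if m <= 0:
            log.warning("gene '%s' has zero mean environment expression; excluded", g)
            continue
        weights[g] = float(m ** -0.5)
    return weights


def module_scores(
    ds: SpatialDataset,
    env_expr: EnvironmentMatrix,
    modules: ModuleSet,
    normalize_weights: bool = False,
) -> ScoreMatrix:
    """Weighted-sum module scores per cell and per environment.

    Weights are taken literally (no renormalization); ``normalize_weights``
    rescales each module's weights to sum to 1, changing only the scale.
    """
    Y = ds.counts_dense()
    env = env_expr.dense()
    yindex = {g: i for i, g in enumerate(ds.gene_ids)}
    eindex = {g: i for i, g in enumerate(env_expr.feature_ids)}

    n = ds.n_cells
    cell_scores = np.zeros((n, len(modules)))
    env_scores = np.zeros((n, len(modules)))
    weights_used: dict = {}
    for mi, mod in enumerate(modules):
        w = gene_weights(env_expr, mod.genes)
        missing = [g for g in mod.genes if g not in yindex or g not in eindex]
        if missing:
            raise DataError(f"module '{mod.name}' references unknown genes: {missing}")
        if normalize_weights and w:
            total = sum(w.values())
            w = {g: v / total for g, v in w.items()}
        weights_used[mod.name] = w
        for g, wj in w.items():
            cell_scores[:, mi] += wj * Y[:, yindex[g]]
            env_scores[:, mi] += wj * env[:, eindex[g]]
    return ScoreMatrix(cell_scores, env_scores, list(modules.names), weights_used)


def _masked_counts(ds: SpatialDataset, cell_type: str):
    """Counts with rows of other cell types zeroed."""
    mask = (np.asarray(ds.cell_type) == cell_type).astype(np.float64)
    if sp.issparse(ds.counts):
        return sp.diags(mask) @ ds.counts
    return ds.counts * mask[:, None]


def celltype_env_expression(
    ds: SpatialDataset, graph: NeighborGraph, gene: str, cell_type: str
) -> np.ndarray:
    """Y^(N,c)_.,j: per-cell neighborhood expression of ``gene``
    contributed only by neighbors of type ``cell_type``.

    Summed over all cell types this reproduces the plain environment
    column exactly (partition identity).
    """
    if gene not in ds.gene_ids:
        raise DataError(f"unknown gene '{gene}'")
    if cell_type not in set(np.asarray(ds.cell_type)):
        raise DataError(f"unknown cell type '{cell_type}'")
    j = ds.gene_ids.get_loc(gene)
    col = ds.counts[:, [j]]
    mask = (np.asarray(ds.cell_type) == cell_type).astype(np.float64)
    masked = sp.diags(mask) @ col if sp.issparse(col) else np.asarray(col) * mask[:, None]
    env = graph.adjacency() @ masked
    return np.asarray(env.todense()).ravel() if sp.issparse(env) else np.asarray(env).ravel()


def _pearson_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Correlation of vector x with each column of Y; 0 where a column
    (or x) has zero variance."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0, keepdims=True)
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((Yc ** 2).sum(axis=0))
    num = Yc.T @ xc
    denom = sx * sy
    out = np.zeros(Y.shape[1])
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def attribution(
    ds: SpatialDataset,
    graph: NeighborGraph,
    modules: ModuleSet,
    scores: ScoreMatrix,
    max_cells: int | None = None,
    seed: int = 0,
    subsample: np.ndarray | None = None,
) -> AttributionTable:
    """Cell-type involvement scores for every (module, gene, cell type).

    Computed on a cell subsample for speed (pass the conditional-
    correlation subsample to keep the analyses paired).  Zero-variance
    masked-expression vectors yield A(j,c) = 0.
    """
    from .condcor import subsample_cells

    if subsample is None:
        if max_cells is None or ds.n_cells <= max_cells:
            subsample = np.arange(ds.n_cells)
        else:
            subsample = subsample_cells(ds.n_cells, max_cells, seed)

    adj = graph.adjacency()[subsample]
    cell_types = sorted(set(np.asarray(ds.cell_type)))
    table = AttributionTable()

    all_genes = sorted(set(modules.genes()))
    gpos = ds.gene_ids.get_indexer(pd.Index(all_genes)) if all_genes else []
    local = {g: i for i, g in enumerate(all_genes)}

    for c in cell_types:
        masked = _masked_counts(ds, c)
        env_c = adj @ (masked[:, gpos] if len(all_genes) else masked[:, :0])
        env_c = np.asarray(env_c.todense()) if sp.issparse(env_c) else np.asarray(env_c)
        for mi, mod in enumerate(modules):
            score_vec = scores.env_scores[subsample, mi]
            cols = [local[g] for g in mod.genes]
            vals = _pearson_many(score_vec, env_c[:, cols])
            for g, v in zip(mod.genes, vals):
                table.gene_level.append((mod.name, g, c, float(v)))

    for mod in modules:
        for c in cell_types:
            vals = [
                v
                for (m, _g, ct, v) in table.gene_level
                if m == mod.name and ct == c
            ]
            table.celltype_level.append((mod.name, c, max(vals)))
    return table
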