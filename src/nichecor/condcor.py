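"""Conditional correlation of environment expression.

The central statistic: the Pearson correlation of the environment
expression matrix Y^(N) after removing everything a set of environment
confounders X^(N) — neighborhood cell-type composition, total counts,
negative-probe counts, sample/FOV indicators — can linearly explain.
The conditional covariance is the Schur complement

    cov(Y^(N) | X^(N)) = cov(Y^(N)) - cov(Y^(N), X^(N)) cov(X^(N))^+ cov(X^(N), Y^(N))

with a Moore-Penrose pseudo-inverse so rank-deficient confounder blocks
(cell-type proportions summing to 1, one-hot FOV indicators) are handled
without dropping columns.  This equals the covariance of the residuals
from regressing Y^(N) on X^(N) with an intercept.  Rescaling the result
to unit diagonal gives the conditional correlation.

Because neighborhood sums are averages of many cells, the matrix is
estimated on a random subsample of cells (default 5000) with no loss of
interpretability; no p-values are computed, since at these sample sizes
even negligible correlations are formally significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._defaults import DEFAULTS
from .dataset import SpatialDataset
from .errors import ConfigError, DataError
from .neighbors import NeighborGraph, environment_sum

log = logging.getLogger(__name__)

__all__ = [
    "ConfounderSpec",
    "CondCorResult",
    "build_confounder_matrix",
    "subsample_cells",
    "conditional_covariance",
    "conditional_correlation",
    "raw_correlation",
]


@dataclass
class ConfounderSpec:
    """Which per-cell variables to condition on.

    ``use_cell_type`` expands the cell-type label into one-hot columns;
    categorical covariates (e.g. FOV id) are one-hot encoded the same
    way; numeric covariates (total counts, negative-probe counts) are
    used as-is.  All are then neighbor-summed into X^(N).
    """

    use_cell_type: bool = True
    categorical_covariates: tuple = ()
    numeric_covariates: tuple = ()
    drop_reference_level: bool = False

    @property
    def empty(self) -> bool:
        return not (
            self.use_cell_type or self.categorical_covariates or self.numeric_covariates
        )


@dataclass
class CondCorResult:
    """Genes x genes conditional (and optionally raw) correlation."""

    genes: pd.Index
    cond_cor: np.ndarray
    raw_cor: np.ndarray | None
    subsample_ids: pd.Index
    max_cells: int
    seed: int
    confounder_spec: ConfounderSpec
    zero_variance_genes: list = field(default_factory=list)

    def pair_value(self, gene_a: str, gene_b: str, raw: bool = False) -> float:
        mat = self.raw_cor if raw else self.cond_cor
        ia = self.genes.get_loc(gene_a)
        ib = self.genes.get_loc(gene_b)
        return float(mat[ia, ib])


def _covariate_column(ds: SpatialDataset, name: str) -> np.ndarray:
    if ds.covariates is not None and name in ds.covariates.columns:
        return ds.covariates[name].to_numpy(dtype=np.float64)
    if name == "total_counts":
        return ds.total_counts().astype(np.float64)
    raise DataError(f"covariate '{name}' not found in dataset")


def build_confounder_matrix(
    ds: SpatialDataset, spec: ConfounderSpec
) -> tuple[np.ndarray, list]:
    """Per-cell confounder matrix X (cells x confounders) and column names.

    Cell type contributes one indicator column per level (for a cell of
    type "T-cell", the "T-cell" column is 1 and the others 0).  With
    ``drop_reference_level`` the first level of each categorical block is
    omitted — harmless for the correlation itself (residualization with
    an implicit intercept spans the same space) but it removes the exact
    collinearity.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []

    def one_hot(labels: np.ndarray, prefix: str) -> None:
        levels = sorted(pd.unique(labels).tolist())
        if spec.drop_reference_level:
            if len(levels) == 1:
                log.warning("categorical '%s' has a single level; empty block", prefix)
            levels = levels[1:]
        for lev in levels:
            blocks.append((labels == lev).astype(np.float64)[:, None])
            names.append(f"{prefix}:{lev}")

    if spec.use_cell_type:
        one_hot(np.asarray(ds.cell_type), "cell_type")
    for cat in spec.categorical_covariates:
        if cat == "sample":
            if ds.sample_id is None:
                raise DataError("dataset has no sample ids")
            one_hot(np.asarray(ds.sample_id), "sample")
        else:
            if ds.covariates is None or cat not in ds.covariates.columns:
                raise DataError(f"categorical covariate '{cat}' not found")
            one_hot(ds.covariates[cat].astype(str).to_numpy(), cat)
    for num in spec.numeric_covariates:
        blocks.append(_covariate_column(ds, num)[:, None])
        names.append(num)

    if not blocks:
        return np.empty((ds.n_cells, 0)), []
    return np.hstack(blocks), names


def subsample_cells(n_cells: int, max_cells: int, seed: int) -> np.ndarray:
    """Uniform sample without replacement, sorted ascending; identity when
    the dataset is smaller than ``max_cells``."""
    if max_cells < 2:
        raise ConfigError("max_cells must be >= 2")
    if n_cells <= max_cells:
        return np.arange(n_cells)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_cells, size=max_cells, replace=False))


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def conditional_covariance(Yn: np.ndarray, Xn: np.ndarray) -> np.ndarray:
    """Schur-complement conditional covariance of Yn given Xn.

    Columns are mean-centered (implicit intercept); cov(X)^-1 is the
    Moore-Penrose pseudo-inverse, so exactly collinear confounder columns
    change nothing.  With zero confounder columns this is just cov(Yn).
    """
    Yn = np.asarray(Yn, dtype=np.float64)
    Xn = np.asarray(Xn, dtype=np.float64)
    if Yn.shape[0] != Xn.shape[0]:
        raise DataError("Yn and Xn must have the same number of rows")
    n = Yn.shape[0]
    if n < 3:
        raise DataError(f"need at least 3 rows to estimate covariance, got {n}")
    Yc = _center(Yn)
    cov_y = (Yc.T @ Yc) / (n - 1)
    if Xn.shape[1] == 0:
        return cov_y
    Xc = _center(Xn)
    cov_x = (Xc.T @ Xc) / (n - 1)
    cov_yx = (Yc.T @ Xc) / (n - 1)
    # rcond well above float noise: one-hot confounder blocks make cov_x
    # exactly singular, and the numerically-zero singular values must be
    # truncated, not inverted
    cov_x_pinv = np.linalg.pinv(cov_x, rcond=1e-10, hermitian=True)
    return cov_y - cov_yx @ cov_x_pinv @ cov_yx.T


def _cov_to_cor(cov: np.ndarray, tol_rel: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit-diagonal rescale; returns (cor, zero_variance_mask)."""
    var = np.diag(cov).copy()
    mean_var = var[var > 0].mean() if (var > 0).any() else 1.0
    zero = var <= tol_rel * mean_var
    scale = np.zeros_like(var)
    scale[~zero] = 1.0 / np.sqrt(var[~zero])
    cor = cov * scale[:, None] * scale[None, :]
    cor[zero, :] = 0.0
    cor[:, zero] = 0.0
    np.fill_diagonal(cor, np.where(zero, 0.0, 1.0))
    cor = np.clip(cor, -1.0, 1.0)
    cor = (cor + cor.T) / 2.0
    return cor, zero


def _env_expression(
    ds: SpatialDataset, graph: NeighborGraph, genes: pd.Index | None
) -> tuple[np.ndarray, pd.Index]:
    counts = ds.counts
    gene_index = ds.gene_ids
    if genes is not None:
        genes = pd.Index(genes)
        keep = genes[genes.isin(gene_index)]
        if len(keep) == 0:
            raise DataError("requested gene subset is disjoint from the panel")
        if len(keep) < len(genes):
            log.warning(
                "%d requested genes absent from panel", len(genes) - len(keep)
            )
        pos = gene_index.get_indexer(keep)
        counts = counts[:, pos]
        gene_index = keep
    env = environment_sum(graph, counts, feature_ids=list(gene_index))
    return env.dense(), gene_index


def conditional_correlation(
    ds: SpatialDataset,
    graph: NeighborGraph,
    spec: ConfounderSpec | None = None,
    max_cells: int = DEFAULTS["max_cells"],
    seed: int = 0,
    genes=None,
    compute_raw: bool = True,
    subsample: np.ndarray | None = None,
    method: str = "pearson",
) -> CondCorResult:
    """Conditional correlation of environment expression given environment
    confounders.

    Pipeline: neighbor-sum expression and confounders, subsample cells,
    Schur-complement conditional covariance, rescale to unit diagonal.
    Genes with (conditional) variance below tolerance get zero rows and
    columns and are listed in ``zero_variance_genes``.  A gene subset
    restricts the Y columns only — the conditional correlation of a pair
    depends only on that pair and X, so subset runs reproduce the
    corresponding entries of a full run.  ``method="spearman"`` ranks the
    environment columns before conditioning (non-default).
    """
    if spec is None:
        spec = ConfounderSpec()
    if graph.n_cells != ds.n_cells:
        raise DataError("graph was built on a different number of cells")

    Yn, gene_index = _env_expression(ds, graph, genes)
    if method == "spearman":
        from scipy.stats import rankdata

        Yn = rankdata(Yn, axis=0)
    elif method != "pearson":
        raise ConfigError(f"unknown correlation method '{method}'")

    X, _ = build_confounder_matrix(ds, spec)
    Xn = environment_sum(graph, X).dense() if X.shape[1] else X

    if subsample is None:
        subsample = subsample_cells(ds.n_cells, max_cells, seed)
    Ys = Yn[subsample]
    Xs = Xn[subsample] if Xn.shape[1] else np.empty((len(subsample), 0))

    tol = DEFAULTS["zero_variance_tol"]
    cond_cov = conditional_covariance(Ys, Xs)
    cond_cor, zero = _cov_to_cor(cond_cov, tol)

    raw_cor = None
    if compute_raw:
        raw_cov = conditional_covariance(Ys, np.empty((len(subsample), 0)))
        raw_cor, _ = _cov_to_cor(raw_cov, tol)

    return CondCorResult(
        genes=gene_index,
        cond_cor=cond_cor,
        raw_cor=raw_cor,
        subsample_ids=ds.cell_ids[subsample],
        max_cells=max_cells,
        seed=seed,
        confounder_spec=spec,
        zero_variance_genes=list(gene_index[zero]),
    )


def raw_correlation(
    ds: SpatialDataset,
    graph: NeighborGraph,
    max_cells: int = DEFAULTS["max_cells"],
    seed: int = 0,
    genes=None,
) -> CondCorResult:
    """Plain Pearson correlation of the environment expression matrix,
    cor(Y^(N)) — what a correlation analysis without confounder
    adjustment would report."""
    res = conditional_correlation(
        ds,
        graph,
        spec=ConfounderSpec(use_cell_type=False),
        max_cells=max_cells,
        seed=seed,
        genes=genes,
        compute_raw=False,
    )
    res.raw_cor = res.cond_cor
    return res
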