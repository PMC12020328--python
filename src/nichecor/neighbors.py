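"""Cellular neighborhoods and environment (neighborhood-sum) matrices.

A cell's *environment expression* is the sum of expression over its
spatial neighbors N(i) (optionally including the cell itself):

    Y^(N)_{i,j} = sum_{i' in N(i)} Y_{i',j}

Neighborhoods come from K-nearest neighbors, a fixed radius, or a
user-supplied list.  The same aggregation applies to any per-cell
matrix, in particular the confounder matrix.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .dataset import SpatialDataset
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

__all__ = [
    "NeighborGraph",
    "EnvironmentMatrix",
    "knn_graph",
    "radius_graph",
    "custom_graph",
    "environment_sum",
]


@dataclass
class NeighborGraph:
    """Per-cell neighbor index lists N(i) with construction metadata.

    ``neighbors[i]`` never contains ``i`` itself; ``include_self`` adds
    the cell's own row at aggregation time instead.
    """

    neighbors: list
    method: str
    param: float
    include_self: bool
    n_cells: int
    _adjacency: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.neighbors = [np.asarray(nb, dtype=np.int64) for nb in self.neighbors]
        if len(self.neighbors) != self.n_cells:
            raise DataError("neighbor list length does not match n_cells")
        for i, nb in enumerate(self.neighbors):
            if len(nb) and (nb.min() < 0 or nb.max() >= self.n_cells):
                raise DataError(f"cell {i}: neighbor index out of range")
            if len(np.unique(nb)) != len(nb):
                raise DataError(f"cell {i}: duplicate neighbor indices")

    def adjacency(self) -> sp.csr_matrix:
        """Sparse 0/1 matrix A with A[i, i'] = 1 iff i' contributes to i's
        environment (including the diagonal when ``include_self``)."""
        if self._adjacency is None:
            indptr = np.zeros(self.n_cells + 1, dtype=np.int64)
            counts = np.array([len(nb) for nb in self.neighbors], dtype=np.int64)
            np.cumsum(counts, out=indptr[1:])
            indices = (
                np.concatenate(self.neighbors)
                if indptr[-1]
                else np.empty(0, dtype=np.int64)
            )
            data = np.ones(indptr[-1], dtype=np.float64)
            adj = sp.csr_matrix(
                (data, indices, indptr), shape=(self.n_cells, self.n_cells)
            )
            if self.include_self:
                adj = adj + sp.identity(self.n_cells, format="csr")
            self._adjacency = sp.csr_matrix(adj)
        return self._adjacency

    def degrees(self) -> np.ndarray:
        deg = np.array([len(nb) for nb in self.neighbors], dtype=np.int64)
        return deg + 1 if self.include_self else deg

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(f"{self.method}|{self.param}|{self.include_self}|{self.n_cells}".encode())
        for nb in self.neighbors:
            h.update(np.sort(nb).tobytes())
        return h.hexdigest()[:16]

    def __eq__(self, other) -> bool:
        if not isinstance(other, NeighborGraph):
            return NotImplemented
        return (
            self.n_cells == other.n_cells
            and self.include_self == other.include_self
            and all(
                np.array_equal(np.sort(a), np.sort(b))
                for a, b in zip(self.neighbors, other.neighbors)
            )
        )


@dataclass
class EnvironmentMatrix:
    """Cells x features neighbor-summed matrix."""

    values: np.ndarray | sp.csr_matrix
    feature_ids: list
    graph_fingerprint: str

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)


def knn_graph(positions: np.ndarray, k: int = 50, include_self: bool = True) -> NeighborGraph:
    """K-nearest-neighbor graph by Euclidean distance.

    Exact distance ties are broken toward the lower cell index, so the
    graph is deterministic for any input.
    """
    positions = np.asarray(positions, dtype=np.float64)
    n = positions.shape[0]
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k >= n:
        raise ConfigError(f"k={k} must be smaller than the number of cells ({n})")

    tree = cKDTree(positions)
    # query a few extra candidates so boundary ties can be re-ranked exactly
    k_query = min(n, k + 8)
    _, idx = tree.query(positions, k=k_query)
    idx = np.atleast_2d(idx)

    neighbors = []
    for i in range(n):
        cand = idx[i][idx[i] != i]
        d2 = ((positions[cand] - positions[i]) ** 2).sum(axis=1)
        order = np.lexsort((cand, d2))  # distance first, then lower index
        neighbors.append(np.sort(cand[order[:k]]))
    return NeighborGraph(neighbors, "knn", float(k), include_self, n)


def radius_graph(
    positions: np.ndarray, r: float = 0.05, include_self: bool = True
) -> NeighborGraph:
    """Fixed-radius graph: N(i) = all cells within distance ``r`` of i.

    Symmetric by construction; cells in sparse regions may have empty
    neighborhoods (a warning is emitted if all of them are empty).
    """
    positions = np.asarray(positions, dtype=np.float64)
    if r <= 0:
        raise ConfigError("radius must be positive")
    n = positions.shape[0]
    tree = cKDTree(positions)
    lists = tree.query_ball_point(positions, r)
    neighbors = [np.sort([j for j in lst if j != i]) for i, lst in enumerate(lists)]
    if n and all(len(nb) == 0 for nb in neighbors):
        warnings.warn(
            f"radius {r} is below the minimum pairwise distance; all neighborhoods are empty",
            stacklevel=2,
        )
    return NeighborGraph(neighbors, "radius", float(r), include_self, n)


def custom_graph(
    neighbor_lists: dict, ds: SpatialDataset, include_self: bool = True
) -> NeighborGraph:
    """User-defined neighborhoods, keyed by cell id.

    Lists are stored verbatim (no symmetrization); duplicate entries are
    dropped with a warning; unknown ids are fatal.  Cells absent from the
    mapping get empty neighborhoods.
    """
    index = {cid: i for i, cid in enumerate(ds.cell_ids)}
    neighbors = [np.empty(0, dtype=np.int64) for _ in range(ds.n_cells)]
    for cid, nb_ids in neighbor_lists.items():
        if cid not in index:
            raise DataError(f"custom neighborhood references unknown cell id '{cid}'")
        nb_idx = []
        for nid in nb_ids:
            if nid not in index:
                raise DataError(f"custom neighborhood references unknown cell id '{nid}'")
            nb_idx.append(index[nid])
        uniq, first = np.unique(nb_idx, return_index=True)
        if len(uniq) != len(nb_idx):
            warnings.warn(f"cell '{cid}': duplicate neighbors dropped", stacklevel=2)
        i = index[cid]
        kept = np.array(sorted(np.asarray(nb_idx)[np.sort(first)]), dtype=np.int64)
        neighbors[i] = kept[kept != i]
    return NeighborGraph(neighbors, "custom", float("nan"), include_self, ds.n_cells)


def read_custom_graph(path, ds: SpatialDataset, include_self: bool = True) -> NeighborGraph:
    """Load a custom graph from a two-column (cell_id, neighbor_id) TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError("custom neighborhood file needs two columns: cell_id, neighbor_id")
    lists: dict = {}
    for cid, nid in zip(df.iloc[:, 0], df.iloc[:, 1]):
        lists.setdefault(cid, []).append(nid)
    return custom_graph(lists, ds, include_self=include_self)


def environment_sum(
    graph: NeighborGraph,
    mat: np.ndarray | sp.spmatrix,
    feature_ids=None,
    mean: bool = False,
) -> EnvironmentMatrix:
    """Aggregate a cells x features matrix over neighborhoods.

    ``mean=True`` divides each row by the neighborhood size (cells with
    empty neighborhoods keep a zero row); the default is the plain sum.
    """
    if mat.shape[0] != graph.n_cells:
        raise DataError(
            f"matrix has {mat.shape[0]} rows but graph covers {graph.n_cells} cells"
        )
    adj = graph.adjacency()
    env = adj @ mat
    if mean:
        deg = graph.degrees().astype(np.float64)
        scale = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        env = sp.diags(scale) @ env if sp.issparse(env) else env * scale[:, None]
    if sp.issparse(env):
        env = sp.csr_matrix(env)
    if feature_ids is None:
        feature_ids = list(range(mat.shape[1]))
    return EnvironmentMatrix(env, list(feature_ids), graph.fingerprint())
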