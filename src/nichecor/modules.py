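"""Gene-module extraction from the conditional correlation matrix.

The conditional correlation matrix is sparsified by zeroing entries
below a threshold (default 0.2; anti-correlated pairs are thereby
removed as well), the surviving entries become edge weights of a gene
graph, and Leiden community detection partitions that graph.  Oversized
communities are re-clustered once at double the resolution; undersized
communities and communities with low mean pairwise conditional
correlation are discarded.  Modules are named after their two most
influential genes, influence being the gene's weighted degree within
the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd

from ._defaults import DEFAULTS
from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

__all__ = ["Module", "ModuleSet", "threshold_adjacency", "detect_modules", "name_module"]


@dataclass
class Module:
    name: str
    genes: list
    weights: np.ndarray          # per-gene; influence at detection, scoring weights once attached
    avg_cor: float


@dataclass
class ModuleSet:
    """Disjoint gene modules plus the parameters that produced them."""

    modules: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    @property
    def names(self) -> list:
        return [m.name for m in self.modules]

    def genes(self) -> list:
        return [g for m in self.modules for g in m.genes]

    def __getitem__(self, name: str) -> Module:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)


def threshold_adjacency(cond_cor: np.ndarray, threshold: float = DEFAULTS["edge_threshold"]) -> np.ndarray:
    """Weighted adjacency: entries below ``threshold`` (and the diagonal)
    set to 0; surviving entries keep their correlation value."""
    cond_cor = np.asarray(cond_cor, dtype=np.float64)
    if cond_cor.ndim != 2 or cond_cor.shape[0] != cond_cor.shape[1]:
        raise DataError("adjacency input must be a square matrix")
    if not np.allclose(cond_cor, cond_cor.T, atol=1e-8):
        raise DataError("adjacency input must be symmetric")
    adj = np.where(cond_cor >= threshold, cond_cor, 0.0)
    np.fill_diagonal(adj, 0.0)
    return adj


def _within_module_degree(adj: np.ndarray, members: np.ndarray) -> np.ndarray:
    sub = adj[np.ix_(members, members)]
    return sub.sum(axis=1)


def name_module(genes, cond_cor: np.ndarray, adj: np.ndarray | None = None) -> str:
    """Name = the module's two most influential genes joined by "_".

    Influence is the weighted degree within the module on the thresholded
    graph (or on ``cond_cor`` if no adjacency is given); ties are broken
    alphabetically.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ConfigError("a module needs at least 2 genes to be named")
    mat = adj if adj is not None else np.asarray(cond_cor)
    deg = mat.sum(axis=1)
    order = sorted(range(len(genes)), key=lambda i: (-deg[i], genes[i]))
    return f"{genes[order[0]]}_{genes[order[1]]}"


def _leiden_partition(
    adj: np.ndarray, vertices: np.ndarray, resolution: float, seed: int
) -> list[np.ndarray]:
    """Leiden communities (as arrays of global vertex indices) of the
    subgraph induced by ``vertices``."""
    sub = adj[np.ix_(vertices, vertices)]
    ii, jj = np.nonzero(np.triu(sub, k=1))
    if len(ii) == 0:
        return [np.array([v]) for v in vertices]
    g = ig.Graph(n=len(vertices), edges=list(zip(ii.tolist(), jj.tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=sub[ii, jj].tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return [vertices[np.asarray(c)] for c in part]


def _avg_cor(cond_cor: np.ndarray, members: np.ndarray) -> float:
    """Mean conditional correlation over unordered off-diagonal pairs."""
    sub = cond_cor[np.ix_(members, members)]
    k = len(members)
    return float((sub.sum() - np.trace(sub)) / (k * (k - 1)))


def detect_modules(
    adj: np.ndarray,
    gene_ids,
    cond_cor: np.ndarray | None = None,
    resolution: float = DEFAULTS["leiden_resolution"],
    max_size: int = DEFAULTS["max_module_size"],
    min_size: int = DEFAULTS["min_module_size"],
    min_avg_cor: float = DEFAULTS["min_avg_cor"],
    seed: int = 0,
    threshold: float | None = None,
) -> ModuleSet:
    """Partition the thresholded correlation graph into gene modules.

    Steps: Leiden at ``resolution``; communities larger than ``max_size``
    re-partitioned once at 2x resolution; communities smaller than
    ``min_size`` dropped; communities whose mean pairwise conditional
    correlation is below ``min_avg_cor`` dropped.  Degree-0 genes never
    form modules.  Deterministic given ``seed``.
    """
    adj = np.asarray(adj, dtype=np.float64)
    gene_ids = list(gene_ids)
    if cond_cor is None:
        cond_cor = adj
    if min_size < 2:
        raise ConfigError("min_size must be >= 2")

    connected = np.flatnonzero(adj.sum(axis=1) > 0)
    communities: list[np.ndarray] = []
    if len(connected):
        for comm in _leiden_partition(adj, connected, resolution, seed):
            if len(comm) > max_size:
                communities.extend(_leiden_partition(adj, comm, 2 * resolution, seed))
            else:
                communities.append(comm)

    modules: list[Module] = []
    used_names: dict[str, int] = {}
    # deterministic order: by size desc, then first gene
    communities.sort(key=lambda c: (-len(c), gene_ids[c[0]]))
    for comm in communities:
        if len(comm) < min_size:
            continue
        avg = _avg_cor(cond_cor, comm)
        if avg < min_avg_cor:
            continue
        genes = [gene_ids[i] for i in comm]
        influence = _within_module_degree(adj, comm)
        order = sorted(range(len(genes)), key=lambda i: (-influence[i], genes[i]))
        genes = [genes[i] for i in order]
        influence = influence[order]
        base = f"{genes[0]}_{genes[1]}"
        if base in used_names:
            used_names[base] += 1
            name = f"{base}_{used_names[base]}"
        else:
            used_names[base] = 1
            name = base
        modules.append(Module(name=name, genes=genes, weights=influence, avg_cor=avg))

    params = {
        "threshold": threshold,
        "resolution": resolution,
        "max_size": max_size,
        "min_size": min_size,
        "min_avg_cor": min_avg_cor,
        "seed": seed,
    }
    return ModuleSet(modules=modules, params=params)
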