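"""Multi-sample conditional-correlation comparison.

For a study of several tissues (e.g. TMA cores) the pipeline is run
independently per sample — each sample gets its own neighborhood graph
and its own cell subsample, with per-sample seeds derived from the
master seed — and the per-sample conditional correlation matrices are
summarized into *consensus* pairs (consistently correlated across
samples) and *variable* pairs (strongly correlated in some samples and
uncorrelated in others).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._defaults import DEFAULTS
from .condcor import CondCorResult, ConfounderSpec, conditional_correlation
from .dataset import SpatialDataset
from .errors import ConfigError, DataError
from .neighbors import knn_graph, radius_graph

log = logging.getLogger(__name__)

__all__ = ["MultiSampleResult", "run_per_sample", "consensus_pairs", "variable_pairs"]


@dataclass
class MultiSampleResult:
    samples: list
    per_sample_cor: list            # CondCorResult per retained sample, aligned genes
    genes: pd.Index
    skipped_samples: list = field(default_factory=list)

    def pair_values(self, gene_a: str, gene_b: str) -> np.ndarray:
        """Per-sample conditional correlations for one unordered pair."""
        ia = self.genes.get_loc(gene_a)
        ib = self.genes.get_loc(gene_b)
        return np.array([r.cond_cor[ia, ib] for r in self.per_sample_cor])

    def stacked(self) -> np.ndarray:
        """(n_samples, n_genes, n_genes) array of conditional correlations."""
        return np.stack([r.cond_cor for r in self.per_sample_cor])


def run_per_sample(
    ds: SpatialDataset,
    spec: ConfounderSpec | None = None,
    neighborhood: str = "radius",
    k: int = DEFAULTS["knn_k"],
    r: float = DEFAULTS["radius_mm"],
    include_self: bool = DEFAULTS["include_self"],
    max_cells: int = DEFAULTS["max_cells"],
    seed: int = 0,
    min_cells_per_sample: int = DEFAULTS["min_cells_per_sample"],
    genes=None,
) -> MultiSampleResult:
    """Run conditional correlation independently for every sample.

    Samples with fewer cells than ``min_cells_per_sample`` are skipped
    with a warning (too few cells to power the estimate).  The gene set
    is the panel intersection across retained samples; per-sample seeds
    are ``seed + sample_index``.
    """
    if ds.sample_id is None:
        raise DataError("dataset has no sample ids; multisample mode needs them")
    sample_ids = pd.unique(np.asarray(ds.sample_id)).tolist()

    retained, skipped, subsets = [], [], []
    for s in sample_ids:
        mask = np.asarray(ds.sample_id) == s
        n = int(mask.sum())
        if n < min_cells_per_sample:
            log.warning(
                "sample '%s' has %d cells (< %d); skipped", s, n, min_cells_per_sample
            )
            skipped.append(s)
            continue
        retained.append(s)
        subsets.append(ds.subset_cells(mask))
    if not retained:
        raise DataError("no samples with enough cells remain")

    genes_common = subsets[0].gene_ids
    for sub in subsets[1:]:
        genes_common = genes_common.intersection(sub.gene_ids)
    if genes is not None:
        genes_common = genes_common.intersection(pd.Index(genes))

    results: list[CondCorResult] = []
    for si, sub in enumerate(subsets):
        if neighborhood == "knn":
            graph = knn_graph(sub.positions, k=min(k, sub.n_cells - 1), include_self=include_self)
        elif neighborhood == "radius":
            graph = radius_graph(sub.positions, r=r, include_self=include_self)
        else:
            raise ConfigError(f"unknown neighborhood method '{neighborhood}'")
        res = conditional_correlation(
            sub,
            graph,
            spec=spec,
            max_cells=max_cells,
            seed=seed + si,
            genes=genes_common,
            compute_raw=False,
        )
        results.append(res)
    return MultiSampleResult(
        samples=retained, per_sample_cor=results, genes=genes_common, skipped_samples=skipped
    )


def _iter_pairs(result: MultiSampleResult):
    genes = list(result.genes)
    stack = result.stacked()
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            ga, gb = sorted((genes[a], genes[b]))
            yield ga, gb, stack[:, a, b]


def default_min_samples(n_samples: int) -> int:
    """Default consensus support: ceil(17/19 * n_samples)."""
    return math.ceil(DEFAULTS["consensus_min_frac"] * n_samples)


def consensus_pairs(
    result: MultiSampleResult,
    cor_threshold: float = DEFAULTS["consensus_cor_threshold"],
    min_samples: int | None = None,
) -> pd.DataFrame:
    """Gene pairs with conditional correlation > ``cor_threshold`` in at
    least ``min_samples`` samples."""
    n = len(result.samples)
    if min_samples is None:
        min_samples = default_min_samples(n)
    if min_samples > n:
        raise ConfigError(f"min_samples={min_samples} exceeds the {n} retained samples")
    rows = []
    for ga, gb, vals in _iter_pairs(result):
        passing = int((vals > cor_threshold).sum())
        if passing >= min_samples:
            rows.append((ga, gb, passing))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_samples_passing"])


def variable_pairs(
    result: MultiSampleResult,
    hi: float = DEFAULTS["variable_hi"],
    lo: float = DEFAULTS["variable_lo"],
    min_hi: int = DEFAULTS["variable_min_hi"],
    min_lo: int = DEFAULTS["variable_min_lo"],
) -> pd.DataFrame:
    """Gene pairs with conditional correlation > ``hi`` in >= ``min_hi``
    samples AND < ``lo`` in >= ``min_lo`` samples, with per-sample values
    for heatmap output."""
    if hi <= lo:
        raise ConfigError("hi must exceed lo")
    n = len(result.samples)
    if min_hi > n or min_lo > n:
        raise ConfigError("min_hi/min_lo exceed the number of retained samples")
    rows = []
    for ga, gb, vals in _iter_pairs(result):
        n_high = int((vals > hi).sum())
        n_low = int((vals < lo).sum())
        if n_high >= min_hi and n_low >= min_lo:
            rows.append((ga, gb, n_high, n_low, *vals))
    cols = ["gene_a", "gene_b", "n_high", "n_low"] + [str(s) for s in result.samples]
    return pd.DataFrame(rows, columns=cols)
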