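"""Shared fixtures.

The expensive simulated studies (10k-20k cells) are session-scoped so
several tests can reuse one draw; all seeds are fixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import nichecor as nc

#: confounder set mirroring the standard recipe: neighborhood cell-type
#: composition plus technical covariates
FULL_SPEC = nc.ConfounderSpec(numeric_covariates=("total_counts", "negprobes"))


def make_tiny_dataset(n_cells: int = 6, n_genes: int = 4, seed: int = 0, **kwargs):
    """Small hand-checkable dataset with raw integer counts."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(5.0, size=(n_cells, n_genes)).astype(float)
    return nc.SpatialDataset(
        counts=counts,
        positions=rng.random((n_cells, 2)),
        cell_type=np.array(["A", "B"] * (n_cells // 2) + ["A"] * (n_cells % 2)),
        gene_ids=pd.Index([f"g{j}" for j in range(n_genes)]),
        cell_ids=pd.Index([f"c{i}" for i in range(n_cells)]),
        **kwargs,
    )


@pytest.fixture(scope="session")
def sim_null_10k():
    """10,000 cells, 3 spatially clustered types, 10 markers each, no
    planted programs — the cell-type-landscape-only world."""
    cfg = nc.SimulationConfig(n_cells=10_000, seed=5)
    ds, truth = nc.simulate_dataset(cfg)
    ds = nc.filter_min_counts(ds, 1)
    ds = nc.normalize_total_counts(ds)
    return ds, truth


@pytest.fixture(scope="session")
def sim_planted_10k():
    """10,000 cells with 3 planted 6-gene programs (calibrated defaults,
    fixed seed)."""
    cfg = nc.SimulationConfig(
        n_cells=10_000,
        seed=11,
        planted_modules=[nc.PlantedModule(f"prog{m}") for m in range(3)],
    )
    ds, truth = nc.simulate_dataset(cfg)
    ds = nc.filter_min_counts(ds, 1)
    return ds, truth


@pytest.fixture(scope="session")
def planted_run(sim_planted_10k):
    """Full pipeline result on the planted study."""
    ds, truth = sim_planted_10k
    cfg = nc.RunConfig(seed=11, numeric_covariates=["total_counts", "negprobes"])
    return nc.run_analysis(ds, cfg), truth


@pytest.fixture(scope="session")
def sim_small_planted():
    """3,000 cells with one planted program — cheap end-to-end fixture."""
    cfg = nc.SimulationConfig(
        n_cells=3000, seed=2, planted_modules=[nc.PlantedModule("prog0")]
    )
    ds, truth = nc.simulate_dataset(cfg)
    ds = nc.filter_min_counts(ds, 1)
    return ds, truth
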