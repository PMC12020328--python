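"""One-call end-to-end run: load -> filter/normalize -> neighborhoods ->
conditional + raw correlation -> modules -> scores -> attribution ->
result tables on disk, with a run manifest for provenance.

All defaults come from :mod:`nichecor._defaults` and are echoed into the
manifest, so a run is fully reproducible from its output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from ._defaults import DEFAULTS
from .condcor import CondCorResult, ConfounderSpec, conditional_correlation
from .dataset import SpatialDataset, filter_min_counts, normalize_total_counts
from .errors import ConfigError, DataError, NichecorError
from .modules import ModuleSet, detect_modules, threshold_adjacency
from .neighbors import knn_graph, radius_graph, environment_sum
from .scoring import AttributionTable, ScoreMatrix, attribution, module_scores

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "run_analysis", "pair_report"]


@dataclass
class RunConfig:
    """Everything one run needs; round-trips losslessly through YAML."""

    counts: str = ""
    metadata: str = ""
    out_dir: str = "nichecor_out"
    column_map: dict = field(default_factory=dict)
    # neighborhoods
    neighborhood: str = "knn"                 # knn | radius | custom
    k: int = DEFAULTS["knn_k"]
    r: float = DEFAULTS["radius_mm"]
    include_self: bool = DEFAULTS["include_self"]
    custom_graph_path: str | None = None
    # filtering / normalization
    min_counts: int | None = None             # None = filter off
    normalize: bool = True
    # confounders
    use_cell_type: bool = True
    categorical_covariates: list = field(default_factory=list)
    numeric_covariates: list = field(default_factory=list)
    # correlation
    max_cells: int = DEFAULTS["max_cells"]
    # modules
    edge_threshold: float = DEFAULTS["edge_threshold"]
    resolution: float = DEFAULTS["leiden_resolution"]
    max_module_size: int = DEFAULTS["max_module_size"]
    min_module_size: int = DEFAULTS["min_module_size"]
    min_avg_cor: float = DEFAULTS["min_avg_cor"]
    # subsets
    gene_subset: str | None = None            # path: one symbol per line
    cell_subset: str | None = None            # "column==value" metadata expression
    # multisample
    sample_manifest: str | None = None
    min_cells_per_sample: int = DEFAULTS["min_cells_per_sample"]
    seed: int = 0
    overwrite: bool = True

    def confounder_spec(self) -> ConfounderSpec:
        return ConfounderSpec(
            use_cell_type=self.use_cell_type,
            categorical_covariates=tuple(self.categorical_covariates),
            numeric_covariates=tuple(self.numeric_covariates),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunResult:
    dataset: SpatialDataset
    corr: CondCorResult
    modules: ModuleSet
    scores: ScoreMatrix | None
    attrib: AttributionTable | None
    out_dir: Path | None


def _apply_cell_subset(ds: SpatialDataset, expression: str) -> SpatialDataset:
    """Filter cells with a "column==value" expression on cell_type,
    sample or a covariate column — applied BEFORE graph construction so
    neighborhoods stay internal to the region."""
    if "==" not in expression:
        raise ConfigError("cell_subset must look like 'column==value'")
    col, val = (s.strip() for s in expression.split("==", 1))
    if col == "cell_type":
        mask = np.asarray(ds.cell_type).astype(str) == val
    elif col == "sample":
        if ds.sample_id is None:
            raise DataError("dataset has no sample ids")
        mask = np.asarray(ds.sample_id).astype(str) == val
    elif ds.covariates is not None and col in ds.covariates.columns:
        mask = ds.covariates[col].astype(str).to_numpy() == val
    else:
        raise ConfigError(f"cell_subset column '{col}' not found")
    if not mask.any():
        raise DataError(f"cell subset '{expression}' matches no cells")
    return ds.subset_cells(mask)


def _build_graph(cfg: RunConfig, ds: SpatialDataset):
    if cfg.neighborhood == "knn":
        return knn_graph(ds.positions, k=cfg.k, include_self=cfg.include_self)
    if cfg.neighborhood == "radius":
        return radius_graph(ds.positions, r=cfg.r, include_self=cfg.include_self)
    if cfg.neighborhood == "custom":
        from .neighbors import read_custom_graph

        if not cfg.custom_graph_path:
            raise ConfigError("neighborhood=custom requires custom_graph_path")
        return read_custom_graph(cfg.custom_graph_path, ds, include_self=cfg.include_self)
    raise ConfigError(f"unknown neighborhood method '{cfg.neighborhood}'")


def run_analysis(
    ds: SpatialDataset,
    cfg: RunConfig | None = None,
    genes=None,
) -> RunResult:
    """In-memory pipeline on an already-loaded dataset (no file output)."""
    cfg = cfg or RunConfig()
    stage = "prepare"
    try:
        if cfg.cell_subset:
            ds = _apply_cell_subset(ds, cfg.cell_subset)
        if cfg.min_counts is not None and not ds.normalized:
            ds = filter_min_counts(ds, cfg.min_counts)
        if cfg.normalize and not ds.normalized:
            ds = normalize_total_counts(ds)

        stage = "neighborhoods"
        graph = _build_graph(cfg, ds)

        stage = "conditional_correlation"
        corr = conditional_correlation(
            ds,
            graph,
            spec=cfg.confounder_spec(),
            max_cells=cfg.max_cells,
            seed=cfg.seed,
            genes=genes,
            compute_raw=True,
        )

        stage = "module_detection"
        adj = threshold_adjacency(corr.cond_cor, cfg.edge_threshold)
        modules = detect_modules(
            adj,
            corr.genes,
            cond_cor=corr.cond_cor,
            resolution=cfg.resolution,
            max_size=cfg.max_module_size,
            min_size=cfg.min_module_size,
            min_avg_cor=cfg.min_avg_cor,
            seed=cfg.seed,
            threshold=cfg.edge_threshold,
        )

        scores = attrib = None
        if len(modules):
            stage = "scoring"
            env = environment_sum(graph, ds.counts, feature_ids=list(ds.gene_ids))
            scores = module_scores(ds, env, modules)
            # record the scoring weights on the module objects
            for mod in modules:
                w = scores.weights_used[mod.name]
                mod.genes = [g for g in mod.genes if g in w]
                mod.weights = np.array([w[g] for g in mod.genes])

            stage = "attribution"
            sub_idx = ds.cell_ids.get_indexer(corr.subsample_ids)
            attrib = attribution(ds, graph, modules, scores, subsample=sub_idx)
    except NichecorError as err:
        raise type(err)(f"[stage: {stage}] {err}") from err
    return RunResult(ds, corr, modules, scores, attrib, None)


def run_pipeline(cfg: RunConfig, ds: SpatialDataset | None = None) -> RunResult:
    """Full run with file output and manifest.

    If ``ds`` is omitted, counts and metadata are loaded from the paths
    in ``cfg``.  Writes: conditional and raw correlation matrices (wide
    and long form), module table, edge list, score matrix, attribution
    table, and ``manifest.json``.
    """
    t0 = time.time()
    timings: dict = {}
    if ds is None:
        ds = nio.load_dataset(cfg.counts, cfg.metadata, cfg.column_map)
    timings["load_s"] = round(time.time() - t0, 3)

    genes = None
    if cfg.gene_subset:
        genes = [g for g in Path(cfg.gene_subset).read_text().split() if g]

    result = run_analysis(ds, cfg, genes=genes)
    timings["analysis_s"] = round(time.time() - t0 - timings["load_s"], 3)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ow = cfg.overwrite
    corr = result.corr
    nio.write_matrix(corr.cond_cor, corr.genes, out / "conditional_correlation.tsv", ow)
    nio.write_matrix_long(corr.cond_cor, corr.genes, out / "conditional_correlation_long.csv", ow)
    if corr.raw_cor is not None:
        nio.write_matrix(corr.raw_cor, corr.genes, out / "raw_correlation.tsv", ow)
    nio.write_modules(result.modules, out / "modules.tsv", ow)
    adj = threshold_adjacency(corr.cond_cor, cfg.edge_threshold)
    nio.write_edge_list(adj, corr.genes, result.modules, out / "network_edges.tsv", ow)
    if result.scores is not None:
        nio.write_scores(
            result.scores.cell_scores, result.dataset.cell_ids,
            result.scores.module_names, out / "cell_scores.csv", ow,
        )
        nio.write_scores(
            result.scores.env_scores, result.dataset.cell_ids,
            result.scores.module_names, out / "environment_scores.csv", ow,
        )
    if result.attrib is not None:
        nio.write_attribution(result.attrib, out / "attribution.csv", ow)

    # per-FOV score summaries support the secondary-QC reading of modules
    if (
        result.scores is not None
        and result.dataset.covariates is not None
        and "fov" in result.dataset.covariates.columns
    ):
        fov = result.dataset.covariates["fov"].to_numpy()
        df = pd.DataFrame(result.scores.cell_scores, columns=result.scores.module_names)
        df["fov"] = fov
        df.groupby("fov").mean().to_csv(out / "fov_score_summary.csv", float_format=nio.FLOAT_FMT)

    manifest = {
        "config": asdict(cfg),
        "defaults": DEFAULTS,
        "seed": cfg.seed,
        "n_cells": int(result.dataset.n_cells),
        "n_genes": int(len(corr.genes)),
        "n_modules": len(result.modules),
        "subsample_ids": list(map(str, corr.subsample_ids)),
        "zero_variance_genes": list(map(str, corr.zero_variance_genes)),
        "timings": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result.out_dir = out
    return result


def pair_report(
    result: CondCorResult, pairs, threshold: float = 0.1
) -> pd.DataFrame:
    """Per-pair conditional and raw correlation with a pass flag.

    Unordered duplicates are reported once; pairs naming unknown genes
    are kept in the table flagged ``missing`` rather than failing, so a
    literature-derived pair list (e.g. ligand-receptor) can be screened
    as-is.  The number of passing pairs is in ``df.attrs["n_passing"]``.
    """
    seen = set()
    rows = []
    for a, b in pairs:
        key = tuple(sorted((str(a), str(b))))
        if key in seen:
            continue
        seen.add(key)
        ga, gb = key
        if ga not in result.genes or gb not in result.genes:
            rows.append((ga, gb, np.nan, np.nan, False, True))
            continue
        cond = result.pair_value(ga, gb)
        raw = result.pair_value(ga, gb, raw=True) if result.raw_cor is not None else np.nan
        rows.append((ga, gb, cond, raw, bool(cond > threshold), False))
    df = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "conditional_cor", "raw_cor", "passing", "missing"],
    )
    df.attrs["n_passing"] = int(df["passing"].sum())
    return df
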