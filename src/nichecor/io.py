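"""Reading counts + metadata and writing result tables.

Counts are accepted as MatrixMarket triplets (with one-column gene and
cell-id sidecar files, 10x-style) or as a dense delimited table with a
header row of gene symbols and cell ids in the first column.  Metadata is
a delimited table with one row per cell.  All writers are deterministic:
fixed column order and a fixed ``%.10g`` float format.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .dataset import SpatialDataset
from .errors import DataError

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

#: default metadata column names; override entries via ``column_map``
DEFAULT_COLUMNS = {
    "cell_id": "cell_id",
    "x": "x",
    "y": "y",
    "cell_type": "cell_type",
    "sample": "sample",
    "total_counts": "total_counts",
    "negprobes": "negprobes",
}


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def _read_counts(counts_path: Path) -> tuple[sp.csr_matrix | np.ndarray, pd.Index, pd.Index]:
    """Return (matrix, cell_ids, gene_ids) from MTX-with-sidecars or dense CSV/TSV."""
    if counts_path.suffix.lower() == ".mtx":
        mat = sp.csr_matrix(mmread(counts_path))
        stem = counts_path.with_suffix("")
        genes_file = Path(str(stem) + ".genes.txt")
        cells_file = Path(str(stem) + ".cells.txt")
        if not genes_file.exists() or not cells_file.exists():
            raise DataError(
                f"MTX sidecars not found: expected {genes_file.name} and {cells_file.name}"
            )
        gene_ids = pd.Index(genes_file.read_text().split())
        cell_ids = pd.Index(cells_file.read_text().split())
        if mat.shape != (len(cell_ids), len(gene_ids)):
            raise DataError(
                f"MTX shape {mat.shape} does not match sidecars "
                f"({len(cell_ids)} cells x {len(gene_ids)} genes)"
            )
        return mat, cell_ids, gene_ids
    df = _read_table(counts_path)
    cell_ids = pd.Index(df.iloc[:, 0].astype(str))
    mat = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return mat, cell_ids, pd.Index(df.columns[1:])


def load_dataset(
    counts_path: str | Path,
    metadata_path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> SpatialDataset:
    """Load counts and per-cell metadata into a :class:`SpatialDataset`.

    Cells are aligned by id; the result keeps the metadata's cell order
    restricted to cells present in both files.  Cells missing from either
    file, or missing coordinates or cell type, are dropped with a log
    message.  No overlap at all, duplicate ids and negative counts are
    fatal.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    counts_path, metadata_path = Path(counts_path), Path(metadata_path)

    mat, cell_ids, gene_ids = _read_counts(counts_path)
    if cell_ids.has_duplicates:
        raise DataError("duplicate cell ids in counts file")
    if mat.min() < 0:
        raise DataError("counts file contains negative values")

    meta = _read_table(metadata_path)
    id_col = cols["cell_id"] if cols["cell_id"] in meta.columns else meta.columns[0]
    meta[id_col] = meta[id_col].astype(str)
    if meta[id_col].duplicated().any():
        raise DataError("duplicate cell ids in metadata file")

    for req in ("x", "y", "cell_type"):
        if cols[req] not in meta.columns:
            raise DataError(f"metadata is missing required column '{cols[req]}'")

    complete = meta[[cols["x"], cols["y"], cols["cell_type"]]].notna().all(axis=1)
    n_incomplete = int((~complete).sum())
    if n_incomplete:
        log.warning("dropping %d cells with missing coordinates or cell type", n_incomplete)
        meta = meta[complete]

    meta_ids = pd.Index(meta[id_col])
    keep = meta_ids[meta_ids.isin(cell_ids)]
    if len(keep) == 0:
        raise DataError("no overlap between counts and metadata cell ids")
    dropped = len(meta_ids) - len(keep) + (len(cell_ids) - len(keep))
    if dropped:
        log.warning("dropped %d cells absent from one of the two files", dropped)

    meta = meta.set_index(id_col).loc[keep]
    row_pos = cell_ids.get_indexer(keep)
    mat = mat[row_pos]

    covars = {}
    for key in ("total_counts", "negprobes"):
        if cols[key] in meta.columns:
            covars[key] = pd.to_numeric(meta[cols[key]]).to_numpy()
    covariates = pd.DataFrame(covars, index=range(len(keep))) if covars else None
    sample = (
        meta[cols["sample"]].astype(str).to_numpy()
        if cols["sample"] in meta.columns
        else None
    )

    return SpatialDataset(
        counts=mat,
        positions=meta[[cols["x"], cols["y"]]].to_numpy(dtype=np.float64),
        cell_type=meta[cols["cell_type"]].astype(str).to_numpy(),
        gene_ids=gene_ids,
        cell_ids=keep,
        covariates=covariates,
        sample_id=sample,
    )


def write_counts_mtx(ds: SpatialDataset, counts_path: str | Path) -> None:
    """Write counts as MTX plus ``.genes.txt`` / ``.cells.txt`` sidecars."""
    counts_path = Path(counts_path)
    mat = ds.counts if sp.issparse(ds.counts) else sp.csr_matrix(ds.counts)
    mmwrite(str(counts_path), sp.coo_matrix(mat))
    stem = counts_path.with_suffix("")
    Path(str(stem) + ".genes.txt").write_text("\n".join(ds.gene_ids) + "\n")
    Path(str(stem) + ".cells.txt").write_text("\n".join(ds.cell_ids.astype(str)) + "\n")


# ----------------------------------------------------------------------
# result writers


def _check_target(path: Path, overwrite: bool) -> Path:
    if path.exists() and not overwrite:
        raise DataError(f"refusing to overwrite existing file {path} (pass overwrite=True)")
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def write_matrix(mat: np.ndarray, labels, path: str | Path, overwrite: bool = False) -> None:
    """Gene x gene matrix as a TSV with row and column labels."""
    path = _check_target(Path(path), overwrite)
    df = pd.DataFrame(np.asarray(mat), index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_long(
    mat: np.ndarray, labels, path: str | Path, overwrite: bool = False
) -> None:
    """Upper-triangle long form: gene_a, gene_b, value (gene_a < gene_b)."""
    path = _check_target(Path(path), overwrite)
    mat = np.asarray(mat)
    labels = list(labels)
    ia, ib = np.triu_indices(len(labels), k=1)
    df = pd.DataFrame(
        {
            "gene_a": [labels[i] for i in ia],
            "gene_b": [labels[i] for i in ib],
            "value": mat[ia, ib],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_modules(modules, path: str | Path, overwrite: bool = False) -> None:
    """ModuleSet as a TSV with columns module, gene, weight."""
    path = _check_target(Path(path), overwrite)
    rows = []
    for mod in modules:
        for gene, w in zip(mod.genes, mod.weights):
            rows.append((mod.name, gene, w))
    df = pd.DataFrame(rows, columns=["module", "gene", "weight"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_edge_list(
    adjacency: np.ndarray, labels, modules, path: str | Path, overwrite: bool = False
) -> None:
    """Network edge list (gene_a, gene_b, weight, module) for graph viewers."""
    path = _check_target(Path(path), overwrite)
    adjacency = np.asarray(adjacency)
    labels = list(labels)
    gene_to_module = {}
    for mod in modules:
        for g in mod.genes:
            gene_to_module[g] = mod.name
    ia, ib = np.triu_indices(len(labels), k=1)
    nz = adjacency[ia, ib] > 0
    rows = []
    for i, j in zip(ia[nz], ib[nz]):
        ga, gb = labels[i], labels[j]
        mod = gene_to_module.get(ga, "")
        if gene_to_module.get(gb, "") != mod:
            mod = ""
        rows.append((ga, gb, adjacency[i, j], mod))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "module"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_scores(
    scores: np.ndarray, cell_ids, module_names, path: str | Path, overwrite: bool = False
) -> None:
    """Cells x modules score matrix as CSV."""
    path = _check_target(Path(path), overwrite)
    df = pd.DataFrame(np.asarray(scores), index=cell_ids, columns=module_names)
    df.to_csv(path, float_format=FLOAT_FMT, index_label="cell_id")


def write_attribution(table, path: str | Path, overwrite: bool = False) -> None:
    """AttributionTable long-form CSV: module, gene, cell_type, score.

    Cell-type level rows carry an empty gene field.
    """
    path = _check_target(Path(path), overwrite)
    rows = [
        (m, g, c, v) for (m, g, c, v) in table.gene_level
    ] + [(m, "", c, v) for (m, c, v) in table.celltype_level]
    df = pd.DataFrame(rows, columns=["module", "gene", "cell_type", "score"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
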