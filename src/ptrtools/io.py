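"""Containers, readers/writers, QC filtering, configuration and logging.

The pipeline consumes log-normalized single-cell expression matrices (genes x
cells) with per-cell metadata (patient, tissue, optional cluster / cell type /
QC fields) and gene-set files.  Expression values are assumed already
normalized — by convention log1p of counts-per-10k, as published single-cell
objects typically are — so this module validates non-negativity but never
re-normalizes.

Supported formats:

* expression — Matrix Market (``.mtx``) with gene/cell id sidecar files, or a
  dense CSV with genes as rows and cells as columns;
* per-cell metadata — TSV keyed by cell id;
* gene sets — GMT (name, description, tab-separated members) or a plain
  one-gene-per-line list.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

logger = logging.getLogger("ptrtools")

#: metadata columns every cell must carry
REQUIRED_META = ("patient_id", "tissue")

#: per-cell QC fields required by :func:`qc_filter`
QC_FIELDS = ("n_features", "n_counts", "pct_mito", "log10_genes_per_umi")


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with a compact format (idempotent)."""
    root = logging.getLogger("ptrtools")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        root.addHandler(handler)
    root.setLevel(level)


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    """A named gene signature.

    Members are unique gene symbols; matching against a matrix is exact and
    case-sensitive (no symbol mapping is attempted).
    """

    name: str
    members: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ExpressionMatrix:
    """Genes x cells normalized expression with per-cell metadata.

    ``values`` may be dense (ndarray) or CSR sparse; rows follow ``gene_ids``
    and columns follow ``cell_ids``.  ``cell_meta`` is indexed by cell id and
    must carry ``patient_id`` and ``tissue`` for every cell.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")
        self.cell_ids = pd.Index(self.cell_ids, name="cell_id")
        if self.gene_ids.has_duplicates:
            dupes = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.cell_ids.has_duplicates:
            dupes = self.cell_ids[self.cell_ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell ids: {dupes[:5]}")
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
            data = self.values.data
        else:
            self.values = np.asarray(self.values)
            data = self.values
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if data.size and np.min(data) < 0:
            raise ValueError("expression values must be non-negative")
        if not self.cell_meta.index.equals(self.cell_ids):
            raise ValueError("cell_meta index must equal cell_ids (same order)")
        for col in REQUIRED_META:
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta missing required column {col!r}")
            if self.cell_meta[col].isna().any():
                raise ValueError(f"cell_meta column {col!r} has missing values")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_values(self, gene: str) -> np.ndarray:
        """Dense 1-D expression vector of one gene across all cells."""
        return self.genes_values([gene])[0]

    def genes_values(self, genes: Sequence[str]) -> np.ndarray:
        """Dense (len(genes) x n_cells) block, preserving requested order."""
        idx = self.gene_ids.get_indexer(genes)
        missing = [g for g, i in zip(genes, idx) if i < 0]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        block = self.values[idx, :]
        if sp.issparse(block):
            block = block.toarray()
        return np.asarray(block, dtype=float)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            if mask.shape != (self.n_cells,):
                raise ValueError("boolean mask length must equal n_cells")
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return ExpressionMatrix(
            values=self.values[:, cols],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[cols],
            cell_meta=self.cell_meta.iloc[cols],
        )


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------


def _read_id_file(path: Path) -> pd.Index:
    # one id per line; tolerate extra tab-separated annotation columns
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str)
    return pd.Index(ids.values)


def read_expression(
    matrix_path: str | Path,
    meta_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix plus per-cell metadata.

    ``matrix_path`` may be Matrix Market (``.mtx``, genes x cells, with
    sidecar id files — ``genes.tsv`` / ``cells.tsv`` next to the matrix unless
    given explicitly) or a dense CSV whose first column holds gene ids and
    whose header holds cell ids.  ``meta_path`` is a TSV whose first column is
    the cell id; cells absent from the metadata are an error.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None:
            genes_path = matrix_path.parent / "genes.tsv"
        if cells_path is None:
            cells_path = matrix_path.parent / "cells.tsv"
        values = sp.csr_matrix(mmread(matrix_path))
        gene_ids = _read_id_file(Path(genes_path))
        cell_ids = _read_id_file(Path(cells_path))
    else:
        frame = pd.read_csv(matrix_path, index_col=0)
        values = frame.to_numpy(dtype=float)
        gene_ids = pd.Index(frame.index.astype(str))
        cell_ids = pd.Index(frame.columns.astype(str))

    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    missing = cell_ids.difference(meta.index)
    if len(missing):
        raise ValueError(f"cells absent from metadata: {list(missing[:5])}")
    extra = meta.index.difference(cell_ids)
    if len(extra):
        logger.warning("dropping %d metadata rows with no matrix column", len(extra))
    meta = meta.loc[cell_ids]
    return ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids, cell_meta=meta)


def write_expression(expr: ExpressionMatrix, out_dir: str | Path, sparse: bool = True) -> None:
    """Write matrix (MTX or dense CSV) + id sidecars + metadata TSV to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sparse:
        mmwrite(out / "matrix.mtx", sp.coo_matrix(expr.values))
        pd.Series(expr.gene_ids).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
        pd.Series(expr.cell_ids).to_csv(out / "cells.tsv", sep="\t", index=False, header=False)
    else:
        dense = expr.values.toarray() if sp.issparse(expr.values) else expr.values
        pd.DataFrame(dense, index=expr.gene_ids, columns=expr.cell_ids).to_csv(
            out / "matrix.csv"
        )
    expr.cell_meta.to_csv(out / "cell_meta.tsv", sep="\t")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def _dedup(name: str, members: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    n_in = 0
    for m in members:
        n_in += 1
        seen.setdefault(m, None)
    if len(seen) < n_in:
        logger.warning(
            "gene set %s: collapsed %d duplicate members", name, n_in - len(seen)
        )
    return list(seen)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file, or a one-gene-per-line list.

    GMT rows are ``name<TAB>description<TAB>gene1<TAB>gene2...``; duplicate
    members within a set are collapsed with a warning.  A plain list file
    yields a single set named after the file stem.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path} is empty")
    sets: list[GeneSet] = []
    if path.suffix.lower() == ".gmt":
        for ln in lines:
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT row (needs >= 3 fields): {ln[:60]!r}")
            name, desc, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(name=name, members=_dedup(name, members), provenance=desc))
    else:
        members = [ln.strip() for ln in lines]
        sets.append(GeneSet(name=path.stem, members=_dedup(path.stem, members),
                            provenance=str(path)))
    return sets


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def qc_filter(
    expr: ExpressionMatrix,
    max_features: int = 3000,
    min_features: int = 200,
    max_counts: int = 10_000,
    min_log10_genes_per_umi: float = 0.82,
    max_pct_mito: float = 10.0,
    counts_rule: str = "max",
) -> ExpressionMatrix:
    """Drop low-quality cells using per-cell QC metadata.

    Retains exactly the cells with ``min_features <= n_features <=
    max_features``, a UMI-count bound, ``log10_genes_per_umi >
    min_log10_genes_per_umi`` and ``pct_mito < max_pct_mito``.  Published
    methods state the count bound inconsistently across datasets, so
    ``counts_rule`` selects the reading: ``"max"`` retains
    ``n_counts <= max_counts`` (default), ``"min"`` retains
    ``n_counts >= max_counts``.  Counts removed per rule are logged.
    """
    missing = [c for c in QC_FIELDS if c not in expr.cell_meta.columns]
    if missing:
        raise ValueError(f"cell_meta missing QC fields: {missing}")
    if counts_rule not in ("max", "min"):
        raise ValueError("counts_rule must be 'max' or 'min'")
    meta = expr.cell_meta
    feats = meta["n_features"].to_numpy(float)
    counts = meta["n_counts"].to_numpy(float)
    complexity = meta["log10_genes_per_umi"].to_numpy(float)
    mito = meta["pct_mito"].to_numpy(float)

    rules = {
        "n_features": (feats >= min_features) & (feats <= max_features),
        "n_counts": counts <= max_counts if counts_rule == "max" else counts >= max_counts,
        "log10_genes_per_umi": complexity > min_log10_genes_per_umi,
        "pct_mito": mito < max_pct_mito,
    }
    keep = np.ones(expr.n_cells, dtype=bool)
    for rule, ok in rules.items():
        logger.info("qc_filter: %s removes %d cells", rule, int((~ok).sum()))
        keep &= ok
    if not keep.any():
        raise ValueError("qc_filter removed every cell")
    logger.info("qc_filter: retained %d / %d cells", int(keep.sum()), expr.n_cells)
    return expr.subset_cells(keep)
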