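"""Expression-matrix containers, Matrix Market / TSV IO, QC filters and normalization.

The container is a thin wrapper over a ``scipy.sparse`` count matrix and a
pandas cell-metadata table, the same triplet layout (matrix.mtx + cells.tsv +
genes.tsv) that CellRanger-style exports use.  QC thresholds follow the common
droplet conventions: a cell is kept when it has *more than* ``min_genes``
detected genes, a total UMI count between ``umi_min`` and ``umi_max``
(inclusive), a mitochondrial fraction strictly *under* ``mito_max`` and a
haemoglobin fraction strictly *below* ``hb_max``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

CELL_META_COLUMNS = ["sample_id", "compartment", "total_umi", "n_genes_detected", "mito_fraction", "hb_fraction"]


class FormatError(ValueError):
    """Raised when an on-disk matrix or metadata table is malformed."""


@dataclass
class GeneAnnotation:
    """Per-gene genomic coordinates plus mitochondrial / haemoglobin flags.

    ``table`` is indexed by gene identifier with columns ``chromosome``,
    ``arm``, ``start``, ``end`` (half-open, 0-based), ``genomic_order``
    (permutation of 0..G-1 sorted by chromosome then start), ``is_mito`` and
    ``is_hb``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chromosome", "arm", "start", "end", "genomic_order"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"gene annotation missing columns: {sorted(missing)}")
        for flag in ("is_mito", "is_hb"):
            if flag not in self.table.columns:
                self.table[flag] = False
        order = np.sort(self.table["genomic_order"].to_numpy())
        if not np.array_equal(order, np.arange(len(self.table))):
            raise FormatError("genomic_order must be a permutation of 0..G-1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def genome_order_index(self) -> np.ndarray:
        """Column permutation that puts genes in genomic order."""
        return np.argsort(self.table["genomic_order"].to_numpy(), kind="stable")


@dataclass
class ExpressionMatrix:
    """Sparse cell x gene counts with per-cell metadata.

    ``cell_meta`` is indexed by cell id and carries ``sample_id``, optional
    ``compartment``, and the QC covariates ``total_umi``,
    ``n_genes_detected``, ``mito_fraction`` and ``hb_fraction``.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.cell_meta):
            raise FormatError(
                f"counts has {self.counts.shape[0]} rows but cell_meta has {len(self.cell_meta)}"
            )
        if self.counts.shape[1] != len(self.gene_ids):
            raise FormatError(
                f"counts has {self.counts.shape[1]} columns but {len(self.gene_ids)} gene ids given"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if self.cell_meta.index.has_duplicates:
            raise FormatError("duplicate cell identifiers")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> list[str]:
        return list(self.cell_meta.index)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        """Pure row subsetting; retained values are untouched."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionMatrix(
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_ids=list(self.gene_ids),
        )


def compute_qc_covariates(
    counts: sp.spmatrix, annot: GeneAnnotation | None = None,
    mito_prefixes: tuple[str, ...] = ("MT-",), hb_prefixes: tuple[str, ...] = ("HBA", "HBB"),
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Recompute total_umi / n_genes_detected / mito_fraction / hb_fraction from counts.

    Mito/Hb genes come from annotation flags when an annotation is supplied,
    otherwise from gene-id prefixes (the convention for human data).
    """
    counts = sp.csr_matrix(counts)
    total = np.asarray(counts.sum(axis=1)).ravel()
    ngene = counts.getnnz(axis=1)
    if annot is not None:
        is_mito = annot.table["is_mito"].to_numpy()
        is_hb = annot.table["is_hb"].to_numpy()
    elif gene_ids is not None:
        is_mito = np.array([g.upper().startswith(mito_prefixes) for g in gene_ids])
        is_hb = np.array([g.upper().startswith(hb_prefixes) for g in gene_ids])
    else:
        raise ValueError("need either a GeneAnnotation or gene_ids")
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(total > 0, total, 1)
        mito = np.asarray(counts[:, is_mito].sum(axis=1)).ravel() / denom
        hb = np.asarray(counts[:, is_hb].sum(axis=1)).ravel() / denom
    return pd.DataFrame(
        {"total_umi": total.astype(int), "n_genes_detected": ngene.astype(int),
         "mito_fraction": mito, "hb_fraction": hb}
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_counts(mtx_path: str | Path, cells_tsv: str | Path, genes_tsv: str | Path) -> tuple[ExpressionMatrix, GeneAnnotation]:
    """Read a Matrix Market counts file with its cell and gene TSV sidecars.

    The matrix is stored cell x gene.  ``write_counts`` followed by
    ``read_counts`` is the identity on values and orderings.
    """
    mat = scipy.io.mmread(str(mtx_path))
    data = mat.tocsr()
    if data.nnz and not np.allclose(data.data, np.round(data.data)):
        raise FormatError(f"{mtx_path}: count matrix has non-integer entries")
    data = data.astype(np.int64)
    cells = pd.read_csv(cells_tsv, sep="\t", index_col=0)
    genes = pd.read_csv(genes_tsv, sep="\t", index_col=0)
    if data.shape[0] != len(cells):
        raise FormatError(f"matrix rows ({data.shape[0]}) != cells table ({len(cells)})")
    if data.shape[1] != len(genes):
        raise FormatError(f"matrix cols ({data.shape[1]}) != genes table ({len(genes)})")
    annot = GeneAnnotation(genes)
    em = ExpressionMatrix(counts=data, cell_meta=cells, gene_ids=list(genes.index))
    return em, annot


def write_counts(out_dir: str | Path, em: ExpressionMatrix, annot: GeneAnnotation) -> dict[str, Path]:
    """Write matrix.mtx + cells.tsv + genes.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "matrix.mtx",
        "cells": out / "cells.tsv",
        "genes": out / "genes.tsv",
    }
    scipy.io.mmwrite(str(paths["mtx"]), em.counts.tocoo(), field="integer")
    em.cell_meta.to_csv(paths["cells"], sep="\t")
    annot.table.to_csv(paths["genes"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# QC filtering and normalization
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_by: dict[str, int]


def qc_filter(
    em: ExpressionMatrix,
    min_genes: int = 500,
    umi_min: int = 500,
    umi_max: int = 10000,
    mito_max: float = 0.20,
    hb_max: float = 0.01,
) -> tuple[ExpressionMatrix, QCReport]:
    """Cell-level QC.

    Retains cells with n_genes_detected > ``min_genes``, total UMI in
    [``umi_min``, ``umi_max``] inclusive, mito_fraction < ``mito_max`` and
    hb_fraction < ``hb_max``.  Boundary semantics are literal ("over",
    "between ... and", "under", "below") and configurable.  Gene set is
    unchanged; removal counts per criterion are reported (a cell can count
    against several criteria).
    """
    if not (0 <= mito_max <= 1 and 0 <= hb_max <= 1):
        raise ValueError("fraction thresholds must lie in [0, 1]")
    meta = em.cell_meta
    ok_genes = meta["n_genes_detected"].to_numpy() > min_genes
    umi = meta["total_umi"].to_numpy()
    ok_umi = (umi >= umi_min) & (umi <= umi_max)
    ok_mito = meta["mito_fraction"].to_numpy() < mito_max
    ok_hb = meta["hb_fraction"].to_numpy() < hb_max
    keep = ok_genes & ok_umi & ok_mito & ok_hb
    report = QCReport(
        n_input=em.n_cells,
        n_retained=int(keep.sum()),
        removed_by={
            "min_genes": int((~ok_genes).sum()),
            "umi_range": int((~ok_umi).sum()),
            "mito_max": int((~ok_mito).sum()),
            "hb_max": int((~ok_hb).sum()),
        },
    )
    if report.n_retained == 0:
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    logger.info("qc_filter: %d/%d cells retained (%s)", report.n_retained, report.n_input, report.removed_by)
    return em.subset_cells(keep), report


def normalize_log_cpm(em: ExpressionMatrix, scale: float = 1e4) -> np.ndarray:
    """Depth-normalized log expression: log2(1 + scale * count / total_umi).

    Dense output; monotone in counts within each cell.  Cells with zero total
    counts are rejected — run QC first.
    """
    totals = np.asarray(em.counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("matrix contains zero-total cells; apply qc_filter before normalizing")
    X = em.counts.toarray().astype(np.float64)
    X *= (scale / totals)[:, None]
    return np.log2(1.0 + X)


def normalize_log_median(em: ExpressionMatrix) -> np.ndarray:
    """log2(1 + count * median_libsize / total_umi): depth-normalized without
    inflating low-count noise.

    Counts are scaled to the median library size rather than a fixed large
    factor, which keeps typical entries near the linear part of log1p; this
    is the normalization the CNV caller expects (the inferCNV convention).
    """
    totals = np.asarray(em.counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("matrix contains zero-total cells; apply qc_filter before normalizing")
    X = em.counts.toarray().astype(np.float64)
    X *= (np.median(totals) / totals)[:, None]
    return np.log2(1.0 + X)


def filter_samples_min_cells(em: ExpressionMatrix, min_cells: int = 100) -> ExpressionMatrix:
    """Drop whole samples with fewer than ``min_cells`` cells (strict <)."""
    sizes = em.cell_meta["sample_id"].value_counts()
    keep_samples = set(sizes.index[sizes >= min_cells])
    dropped = sorted(set(sizes.index) - keep_samples)
    if dropped:
        logger.info("filter_samples_min_cells: dropping samples %s", dropped)
    keep = em.cell_meta["sample_id"].isin(keep_samples).to_numpy()
    if not keep.any():
        warnings.warn("all samples fall below the minimum cell count", stacklevel=2)
    return em.subset_cells(keep)
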