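"""Readers and writers for the plain-text formats the pipeline consumes.

Dense matrices are CSV/TSV with a header row of column ids and the first
column holding row ids. Sparse single-cell input follows the CellRanger
triplet layout: Matrix Market coordinate file plus features/barcodes TSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .gficf import CellCounts


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_dense_matrix(path: str | Path) -> pd.DataFrame:
    """Dense matrix: header = column ids, first column = row ids."""
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)


def write_dense_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    frame.to_csv(path, sep=_sep_for(path))


def read_viability(path: str | Path) -> pd.DataFrame:
    """Drugs x lines potency table; empty cells are missing values."""
    return read_dense_matrix(path)


def _read_id_column(path: Path) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return frame.iloc[:, 0].to_numpy(dtype=object)


def read_mtx_counts(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CellCounts:
    """CellRanger-style triplet: MTX (genes x cells) + features + barcodes."""
    matrix = sparse.csr_matrix(spio.mmread(str(mtx_path)))
    genes = _read_id_column(Path(features_path))
    cells = _read_id_column(Path(barcodes_path))
    return CellCounts(matrix, genes, cells)


def write_mtx_counts(m: CellCounts, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(m.counts))
    pd.Series(m.gene_ids).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(m.cell_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    return outdir


def read_cell_counts(
    path: str | Path,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> CellCounts:
    """Counts from either a dense CSV/TSV or an MTX triplet."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        if features_path is None or barcodes_path is None:
            raise ValueError("MTX input needs features and barcodes files")
        return read_mtx_counts(path, features_path, barcodes_path)
    dense = read_dense_matrix(path)
    return CellCounts(
        sparse.csr_matrix(dense.to_numpy()),
        dense.index.to_numpy(dtype=object),
        dense.columns.to_numpy(dtype=object),
    )


def read_labels(path: str | Path) -> pd.Series:
    """Two-column TSV (cell, group) -> Series indexed by cell id."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("labels file needs two columns: cell, group")
    return frame.set_index(frame.columns[0])[frame.columns[1]]


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str, "drug_id": str})
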