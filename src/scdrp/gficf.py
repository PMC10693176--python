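"""Gene frequency / inverse cell frequency scoring of single-cell counts.

A TF-IDF-style scheme: a gene is relevant for a cell when it takes a large
share of that cell's UMIs (gene frequency) but is not expressed in every
cell (inverse cell frequency). Only the normalization and the per-cell
top-N ranking are implemented here; downstream consumers use the ranked
gene sets, not the scores themselves.

Variant implemented: GF(g, c) = count(g, c) / total(c) and
ICF(g) = ln(n_cells / n_cells_expressing(g)), no smoothing, so genes
expressed in every cell score exactly zero. The log base and the absence of
smoothing are recorded in the output provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

MITO_PREFIX = "MT-"


def mito_mask_from_prefix(gene_ids, prefix: str = MITO_PREFIX) -> np.ndarray:
    """Boolean per-gene mask of mitochondrial genes by id prefix."""
    return np.array(
        [str(g).upper().startswith(prefix.upper()) for g in gene_ids], dtype=bool
    )


@dataclass
class CellCounts:
    """Sparse genes x cells UMI count matrix with ids and a mito flag."""

    counts: sparse.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    mito: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicated gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicated cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.mito is not None:
            self.mito = np.asarray(self.mito, dtype=bool)
            if self.mito.shape != self.gene_ids.shape:
                raise ValueError("mito flag length does not match gene ids")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def to_dense_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.gene_ids, columns=self.cell_ids
        )


def qc_filter_cells(
    m: CellCounts,
    min_umi: int = 5000,
    max_mito_frac: float = 0.10,
    mito_prefix: str = MITO_PREFIX,
) -> CellCounts:
    """Keep cells with total UMI >= ``min_umi`` and mito share < ``max_mito_frac``.

    The UMI bound is inclusive, the mitochondrial bound strict. When no mito
    flag is attached to the matrix, mitochondrial genes are identified by id
    prefix (default ``MT-``).
    """
    totals = m.cell_totals()
    keep = totals >= min_umi
    if max_mito_frac < 1:
        mito = m.mito if m.mito is not None else mito_mask_from_prefix(
            m.gene_ids, mito_prefix
        )
        mito_counts = np.asarray(m.counts[mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
        keep &= frac < max_mito_frac
    if not keep.any():
        raise ValueError(
            f"QC removed all {m.n_cells} cells "
            f"(min_umi={min_umi}, max_mito_frac={max_mito_frac}; "
            f"median total UMI={np.median(totals):.0f})"
        )
    return CellCounts(
        m.counts[:, keep].tocsr(),
        m.gene_ids,
        m.cell_ids[keep],
        mito=m.mito,
    )


@dataclass
class GficfMatrix:
    """Sparse genes x cells relevance scores plus normalization provenance."""

    scores: sparse.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    provenance: dict = field(default_factory=dict)


def gficf_normalize(m: CellCounts) -> GficfMatrix:
    """Score every (gene, cell) as GF x ICF.

    Cells with zero total UMI are rejected. Genes expressed nowhere get
    ICF = 0 by convention; genes expressed everywhere get ICF = ln(1) = 0
    and therefore never rank among a cell's relevant genes.
    """
    totals = m.cell_totals()
    if (totals <= 0).any():
        bad = m.cell_ids[totals <= 0].tolist()
        raise ValueError(f"cells with zero total UMI: {bad[:5]}")
    csc = m.counts.tocsc()
    gf = csc.astype(float) @ sparse.diags(1.0 / totals)
    n_expressing = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        icf = np.where(n_expressing > 0, np.log(m.n_cells / np.maximum(n_expressing, 1)), 0.0)
    scores = sparse.diags(icf) @ gf
    scores = sparse.csr_matrix(scores)
    scores.eliminate_zeros()
    return GficfMatrix(
        scores,
        m.gene_ids,
        m.cell_ids,
        provenance={"gf": "count/cell_total", "icf": "ln(n_cells/n_expressing)",
                    "log_base": "e", "smoothing": None},
    )


@dataclass(frozen=True)
class RelevantGenes:
    """One cell's top-N genes by relevance score, best first."""

    cell_id: str
    genes: tuple[str, ...]
    scores: tuple[float, ...]
    n_requested: int


def top_relevant_genes(g: GficfMatrix, n: int = 500) -> list[RelevantGenes]:
    """Extract each cell's ``n`` highest-scoring genes.

    Only strictly positive scores qualify; cells with fewer than ``n``
    positive-score genes return all of them without padding. Ties at the
    cutoff are broken by lexicographic gene id, which makes the selection
    deterministic and nested across increasing ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    csc = g.scores.tocsc()
    out: list[RelevantGenes] = []
    for j, cell_id in enumerate(g.cell_ids):
        start, end = csc.indptr[j], csc.indptr[j + 1]
        rows = csc.indices[start:end]
        vals = csc.data[start:end]
        pos = vals > 0
        rows, vals = rows[pos], vals[pos]
        order = np.lexsort((g.gene_ids[rows], -vals))[:n]
        out.append(
            RelevantGenes(
                cell_id=str(cell_id),
                genes=tuple(str(x) for x in g.gene_ids[rows[order]]),
                scores=tuple(float(v) for v in vals[order]),
                n_requested=n,
            )
        )
    empty = [r.cell_id for r in out if not r.genes]
    if empty:
        warnings.warn(f"{len(empty)} cells have no positive-score genes")
    return out
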