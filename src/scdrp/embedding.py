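"""Cell-cell distances and 2-D embedding from predicted drug responses.

The distance between two cells compares the *signs* of their response
rows: for each of the m drugs, two matching nonzero signs contribute
agreement, opposite or missing calls do not. Formally

    D(x, y) = 1 - sum_j |sign(E[x, j]) + sign(E[y, j])| / (2 m)

which is 0 for two fully-called identical rows and 1 for rows with
opposite nonzero signs everywhere. Note the deliberate consequence of the
formula: a row with z zero (no-evidence) entries has self-distance
1 - (m - z)/m > 0, so identity of indiscernibles holds only on zero-free
matrices; no normalized variant is silently substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import DrugResponse


@dataclass
class DistanceMatrix:
    """Symmetric cells x cells distance matrix in [0, 1]."""

    D: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return self.D.shape[0]


def fuzzy_jaccard(E: pd.DataFrame | DrugResponse) -> DistanceMatrix:
    """Sign-agreement distance matrix of a cells x drugs response matrix."""
    frame = E.E if isinstance(E, DrugResponse) else E
    if frame.shape[1] < 1:
        raise ValueError("need at least one drug column")
    signs = np.sign(frame.to_numpy(dtype=float))
    pos = (signs > 0).astype(float)
    neg = (signs < 0).astype(float)
    # sum_j |s_x + s_y| = nnz_x + nnz_y - 2 * #{opposite nonzero signs}
    opposite = pos @ neg.T + neg @ pos.T
    nnz = pos.sum(axis=1) + neg.sum(axis=1)
    agreement = nnz[:, None] + nnz[None, :] - 2.0 * opposite
    m = frame.shape[1]
    d = 1.0 - agreement / (2.0 * m)
    np.clip(d, 0.0, 1.0, out=d)
    return DistanceMatrix(pd.DataFrame(d, index=frame.index, columns=frame.index))


@dataclass
class Embedding2D:
    coords: pd.DataFrame  # columns x, y; index = cell ids
    seed: int
    params: dict


def reduce_drug_space(
    distances: DistanceMatrix,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> Embedding2D:
    """UMAP embedding of cells from the precomputed response distance matrix.

    Deterministic under a fixed seed (single-threaded). Needs >= 3 cells.
    """
    n = distances.n_cells
    if n < 3:
        raise ValueError("need at least 3 cells to embed")
    import umap  # deferred: numba-backed import is slow

    effective_neighbors = int(min(n_neighbors, n - 1))
    reducer = umap.UMAP(
        n_components=2,
        metric="precomputed",
        random_state=seed,
        n_neighbors=effective_neighbors,
        min_dist=min_dist,
    )
    coords = reducer.fit_transform(distances.D.to_numpy())
    return Embedding2D(
        coords=pd.DataFrame(coords, index=distances.D.index, columns=["x", "y"]),
        seed=seed,
        params={"n_neighbors": effective_neighbors, "min_dist": min_dist},
    )
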