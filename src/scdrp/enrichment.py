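"""Per-cell drug scoring by weighted Kolmogorov-Smirnov enrichment.

Each cell's relevant-gene set is tested against every drug ranking with
the classic GSEA running sum: walking the ranked list, hits increment the
sum by |score|^exponent (normalized by the total hit weight) and misses
decrement it by 1/(L - k). The enrichment score (ES) is the signed maximum
deviation, in [-1, +1]. A positive ES means the query concentrates among
resistance biomarkers (top of the list): the cell is predicted tolerant; a
negative ES predicts sensitivity.

p-values come from random same-size gene sets drawn uniformly from the
ranking universe (exact enumeration when the universe is small enough,
seeded Monte Carlo otherwise), are doubled into a two-sided value, and are
BH-adjusted per drug across cells. ES values whose FDR clears the
threshold populate the cells x drugs response matrix E; everything else,
including zero-overlap (undefined) pairs, becomes 0 — the "no supporting
evidence" state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .gficf import RelevantGenes
from .rankings import DrugRanking, RankingCollection

RECORD_COLUMNS = ["cell_id", "drug_id", "es", "p_value", "n_overlap"]


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, length: int
) -> float:
    """ES from sorted 0-based hit positions and their gene-level weights.

    If every hit weight is zero the walk falls back to equal weights
    (unweighted KS), which keeps the score defined.
    """
    k = positions.size
    if k == 0:
        raise ValueError("no hit positions")
    total = weights.sum()
    if total <= 0:
        weights = np.ones(k)
        total = float(k)
    hit_cum = np.cumsum(weights) / total
    miss_step = 1.0 / (length - k) if length > k else 0.0
    misses_before = positions - np.arange(k)
    after_hit = hit_cum - misses_before * miss_step
    before_hit = np.concatenate(([0.0], hit_cum[:-1])) - misses_before * miss_step
    max_pos = max(0.0, float(after_hit.max()))
    min_neg = min(0.0, float(before_hit.min()))
    # positive branch wins exact ties; the epsilon keeps the choice stable
    # against float accumulation order
    es = max_pos if max_pos >= -min_neg - 1e-9 else min_neg
    return float(np.clip(es, -1.0, 1.0))


@dataclass
class _RankedLookup:
    """Precomputed per-ranking state for repeated ES evaluation."""

    length: int
    weights: np.ndarray
    position: dict

    @classmethod
    def from_ranking(cls, ranking: DrugRanking, weight_exponent: float) -> "_RankedLookup":
        return cls(
            length=len(ranking),
            weights=np.abs(ranking.scores) ** weight_exponent,
            position={g: i for i, g in enumerate(ranking.genes)},
        )

    def hit_positions(self, query) -> np.ndarray:
        pos = [self.position[g] for g in query if g in self.position]
        return np.array(sorted(pos), dtype=int)

    def es(self, positions: np.ndarray) -> float:
        return _es_from_positions(positions, self.weights[positions], self.length)


def enrichment_score(
    ranking: DrugRanking, query, weight_exponent: float = 1.0
) -> tuple[float, int]:
    """ES of a query gene set against one ranking.

    Query genes outside the ranking universe are dropped; the returned
    tuple carries the overlap size actually used. Zero overlap is an error
    (callers wanting a soft path use :func:`score_cells`).
    """
    genes = query.genes if isinstance(query, RelevantGenes) else query
    lookup = _RankedLookup.from_ranking(ranking, weight_exponent)
    positions = lookup.hit_positions(genes)
    if positions.size == 0:
        raise ValueError("query has no overlap with the ranking universe")
    return lookup.es(positions), int(positions.size)


def _tail_count(null_es: np.ndarray, observed: float, eps: float = 1e-12) -> int:
    if observed >= 0:
        return int(np.count_nonzero(null_es >= observed - eps))
    return int(np.count_nonzero(null_es <= observed + eps))


def es_pvalue(
    ranking: DrugRanking,
    query_size: int,
    observed_es: float,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    two_sided: bool = True,
    method: str = "auto",
    exact_limit: int = 100_000,
    early_stop_count: int | None = None,
) -> float:
    """Null probability of an ES at least as extreme (in its sign) as observed.

    ``method="exact"`` enumerates every same-size gene set of the universe
    (p = tail / total); ``method="mc"`` draws ``n_perm`` random sets and
    uses the add-one estimator (x + 1)/(n + 1), optionally stopping early
    once ``early_stop_count`` tail hits accumulate. ``"auto"`` picks exact
    when the number of subsets is at most ``exact_limit``. The one-sided
    tail is doubled (capped at 1) when ``two_sided``.
    """
    if query_size < 1:
        raise ValueError("query_size must be >= 1")
    lookup = _RankedLookup.from_ranking(ranking, weight_exponent)
    length = lookup.length
    if query_size > length:
        raise ValueError("query_size exceeds universe size")
    n_subsets = comb(length, query_size)
    use_exact = method == "exact" or (method == "auto" and n_subsets <= exact_limit)
    if use_exact:
        null = np.fromiter(
            (
                lookup.es(np.array(idx, dtype=int))
                for idx in combinations(range(length), query_size)
            ),
            dtype=float,
            count=n_subsets,
        )
        p_one = _tail_count(null, observed_es) / n_subsets
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1 for Monte Carlo estimation")
        rng = np.random.default_rng(seed)
        tail = 0
        done = 0
        for _ in range(n_perm):
            idx = np.sort(rng.choice(length, size=query_size, replace=False))
            tail += _tail_count(np.array([lookup.es(idx)]), observed_es)
            done += 1
            if early_stop_count is not None and tail >= early_stop_count:
                break
        p_one = (tail + 1) / (done + 1)
    return float(min(1.0, 2.0 * p_one)) if two_sided else float(p_one)


def score_cells(
    cells: list[RelevantGenes],
    collection: RankingCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Score every (cell, drug) pair; returns a long-format record table.

    Columns: ``cell_id, drug_id, es, p_value, n_overlap``. Pairs with zero
    overlap stay in the table with NaN es/p (undefined); a cell overlapping
    no ranking at all is reported via a warning. Monte-Carlo nulls are
    shared across cells with the same overlap size within a drug, which is
    statistically identical to drawing per-cell sets. ``n_perm = 0`` skips
    p-value estimation (p = NaN) for workflows that only need ES.
    """
    if not cells or len(collection) == 0:
        raise ValueError("cells and collection must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    no_overlap = {c.cell_id: True for c in cells}
    for ranking in collection:
        lookup = _RankedLookup.from_ranking(ranking, weight_exponent)
        per_cell: list[tuple[str, float, int]] = []
        for cell in cells:
            positions = lookup.hit_positions(cell.genes)
            if positions.size == 0:
                per_cell.append((cell.cell_id, np.nan, 0))
            else:
                no_overlap[cell.cell_id] = False
                per_cell.append((cell.cell_id, lookup.es(positions), positions.size))
        nulls: dict[int, np.ndarray] = {}
        if n_perm > 0:
            for size in sorted({k for _, _, k in per_cell if k > 0}):
                draws = np.empty(n_perm)
                for i in range(n_perm):
                    idx = np.sort(rng.choice(lookup.length, size=size, replace=False))
                    draws[i] = lookup.es(idx)
                nulls[size] = draws
        for cell_id, es, k in per_cell:
            if k == 0 or n_perm == 0:
                p = np.nan
            else:
                p_one = (_tail_count(nulls[k], es) + 1) / (n_perm + 1)
                p = min(1.0, 2.0 * p_one) if two_sided else p_one
            rows.append((cell_id, ranking.drug_id, es, p, k))
    undefined_cells = [c for c, flag in no_overlap.items() if flag]
    if undefined_cells:
        warnings.warn(
            f"{len(undefined_cells)} cells overlap no ranking universe: "
            f"{undefined_cells[:5]}"
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through as NaN."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    values = p[ok]
    n = values.size
    if n == 0:
        return out
    order = np.argsort(values, kind="stable")
    ranked = values[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(adjusted, 0.0, 1.0, out=adjusted)
    result = np.empty(n)
    result[order] = adjusted
    out[ok] = result
    return out


def fdr_correct(records: pd.DataFrame) -> pd.DataFrame:
    """Attach a per-drug BH FDR column to a record table.

    Correction is applied within each drug across its cells, so the FDR of
    a record is not comparable across drugs and need not dominate its own
    p-value ordering across the whole table.
    """
    out = records.copy()
    out["fdr"] = np.nan
    for _, idx in out.groupby("drug_id", sort=False).groups.items():
        out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p_value"].to_numpy())
    return out


@dataclass
class DrugResponse:
    """Cells x drugs matrix of significant ES values (0 elsewhere)."""

    E: pd.DataFrame
    fdr_threshold: float

    @property
    def n_cells(self) -> int:
        return self.E.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.E.shape[1]


def build_response_matrix(
    records: pd.DataFrame, fdr_threshold: float = 0.1
) -> DrugResponse:
    """Pivot records into E: ES where FDR < threshold, 0 otherwise.

    Undefined records (NaN es or FDR) also map to 0. Row order follows
    first appearance of each cell, column order first appearance of each
    drug.
    """
    if "fdr" not in records.columns:
        raise ValueError("records lack an 'fdr' column; run fdr_correct first")
    cells = records["cell_id"].drop_duplicates().tolist()
    drugs = records["drug_id"].drop_duplicates().tolist()
    es = records.pivot(index="cell_id", columns="drug_id", values="es")
    fdr = records.pivot(index="cell_id", columns="drug_id", values="fdr")
    es = es.reindex(index=cells, columns=drugs)
    fdr = fdr.reindex(index=cells, columns=drugs)
    e = es.where(fdr < fdr_threshold, 0.0).fillna(0.0)
    return DrugResponse(E=e, fdr_threshold=fdr_threshold)
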