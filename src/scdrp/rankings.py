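"""Drug-sensitivity gene rankings from bulk pharmacogenomic screens.

A *drug gene ranking* orders every gene of a bulk expression universe by the
Pearson correlation between the gene's expression (log10(CPM + 1)) and the
drug's potency across cell lines. Potency is the area under the viability
dose-response curve (AUC) by default: low AUC means the line is sensitive,
so genes that correlate *positively* with AUC are resistance biomarkers and
sit at the top of the list, while negatively correlated genes (sensitivity
biomarkers) sit at the bottom.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class InsufficientLinesError(ValueError):
    """Raised when a drug has too few measured cell lines to be ranked."""


def _check_unique(ids, what: str) -> None:
    if pd.Index(ids).has_duplicates:
        dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicated {what}: {dup[:5]}")


def normalize_bulk(raw_counts: pd.DataFrame) -> pd.DataFrame:
    """Library-size normalize raw bulk counts to log10(CPM + 1).

    Parameters
    ----------
    raw_counts
        Genes x cell-lines matrix of non-negative integer counts.

    Returns
    -------
    Genes x cell-lines matrix of log10(CPM + 1) values, same ordering.

    Notes
    -----
    Plain per-line library-size scaling is used (no compositional
    re-weighting such as TMM); callers holding a pre-normalized matrix can
    skip this step entirely.
    """
    _check_unique(raw_counts.index, "gene ids")
    _check_unique(raw_counts.columns, "line ids")
    values = raw_counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("raw counts must be non-negative")
    totals = values.sum(axis=0)
    empty = raw_counts.columns[totals <= 0].tolist()
    if empty:
        raise ValueError(f"lines with zero total counts: {empty}")
    cpm = values * (1e6 / totals)
    return pd.DataFrame(
        np.log10(1.0 + cpm), index=raw_counts.index, columns=raw_counts.columns
    )


def _histogram_entropy(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Per-row Shannon entropy (nats) of an equal-width histogram.

    Bins span each row's own [min, max] range. Constant rows get entropy 0.
    """
    n_rows, n_cols = values.shape
    lo = values.min(axis=1)
    hi = values.max(axis=1)
    span = hi - lo
    constant = span <= 0
    safe_span = np.where(constant, 1.0, span)
    idx = ((values - lo[:, None]) / safe_span[:, None] * n_bins).astype(int)
    np.clip(idx, 0, n_bins - 1, out=idx)
    flat = idx + n_bins * np.arange(n_rows)[:, None]
    counts = np.bincount(flat.ravel(), minlength=n_rows * n_bins)
    counts = counts.reshape(n_rows, n_bins)
    p = counts / n_cols
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    ent = -terms.sum(axis=1)
    ent[constant] = 0.0
    return ent


def filter_genes(
    expr: pd.DataFrame,
    entropy_percentile: float = 0.05,
    min_positive_lines: int = 1,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Drop poorly expressed and low-entropy genes from a bulk matrix.

    Genes expressed (value > 0) in fewer than ``min_positive_lines`` lines
    are removed first. The Shannon entropy of each remaining gene is then
    computed from a 10-bin equal-width histogram of its values across lines,
    and genes whose entropy is at or below the ``entropy_percentile``
    quantile of the entropy distribution are removed. With
    ``entropy_percentile = 0`` only the poor-expression filter applies.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 lines to filter genes")
    if not 0 <= entropy_percentile < 1:
        raise ValueError("entropy_percentile must be in [0, 1)")
    expressed = (expr.to_numpy() > 0).sum(axis=1) >= min_positive_lines
    kept = expr.loc[expressed]
    if kept.empty:
        raise ValueError("all genes removed by the expression filter")
    if entropy_percentile > 0:
        ent = _histogram_entropy(kept.to_numpy(dtype=float), n_bins=n_bins)
        threshold = np.quantile(ent, entropy_percentile)
        kept = kept.loc[ent > threshold]
    if kept.empty:
        raise ValueError("all genes removed by the entropy filter")
    return kept


@dataclass(frozen=True)
class DrugRanking:
    """One drug's genes ordered by signed correlation with potency.

    ``genes`` is sorted by ``scores`` in non-increasing order; resistance
    biomarkers (positive correlation with AUC) come first.
    """

    drug_id: str
    genes: np.ndarray
    scores: np.ndarray
    n_lines_used: int
    source_tag: str = ""
    metric_tag: str = "AUC"

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")
        if np.nanmax(np.abs(self.scores), initial=0.0) > 1 + 1e-9:
            raise ValueError("scores must lie in [-1, 1]")
        _check_unique(self.genes, "genes")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "score": self.scores})


@dataclass
class RankingCollection:
    """A set of drug rankings sharing one gene universe."""

    rankings: list[DrugRanking]
    gene_universe: np.ndarray

    def __post_init__(self) -> None:
        universe = set(self.gene_universe)
        for r in self.rankings:
            if len(r) != len(universe) or set(r.genes) != universe:
                raise ValueError(
                    f"ranking for {r.drug_id!r} does not cover the gene universe"
                )

    def __len__(self) -> int:
        return len(self.rankings)

    def __iter__(self):
        return iter(self.rankings)

    def __getitem__(self, drug_id: str) -> DrugRanking:
        for r in self.rankings:
            if r.drug_id == drug_id:
                return r
        raise KeyError(drug_id)

    @property
    def drug_ids(self) -> list[str]:
        return [r.drug_id for r in self.rankings]


def build_ranking(
    expr: pd.DataFrame,
    potency: pd.Series,
    drug_id: str,
    min_lines: int = 100,
    source_tag: str = "",
    metric_tag: str = "AUC",
) -> DrugRanking:
    """Rank every gene by Pearson correlation with one drug's potency.

    ``potency`` is indexed by line id and may contain missing values; lines
    are matched against ``expr`` columns and missing entries dropped
    pairwise. Genes (or a potency vector) with zero variance get r = 0.
    Ties are broken by lexicographic gene id so the output is deterministic.
    """
    lines = expr.columns.intersection(potency.dropna().index)
    if len(lines) < min_lines:
        raise InsufficientLinesError(
            f"drug {drug_id!r}: {len(lines)} measured lines < min_lines={min_lines}"
        )
    x = expr[lines].to_numpy(dtype=float)
    y = potency[lines].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    x_ss = np.einsum("ij,ij->i", xc, xc)
    y_ss = float(yc @ yc)
    r = np.zeros(expr.shape[0])
    if y_ss > 0:
        ok = x_ss > 0
        with np.errstate(invalid="ignore"):
            r[ok] = (xc[ok] @ yc) / np.sqrt(x_ss[ok] * y_ss)
        np.clip(r, -1.0, 1.0, out=r)
    else:
        warnings.warn(f"drug {drug_id!r}: potency has zero variance; all r = 0")
    gene_ids = expr.index.to_numpy(dtype=object)
    order = np.lexsort((gene_ids, -r))
    return DrugRanking(
        drug_id=drug_id,
        genes=gene_ids[order],
        scores=r[order],
        n_lines_used=int(len(lines)),
        source_tag=source_tag,
        metric_tag=metric_tag,
    )


def build_ranking_collection(
    expr: pd.DataFrame,
    viability: pd.DataFrame,
    min_lines: int = 100,
    source_tag: str = "",
    metric_tag: str = "AUC",
) -> RankingCollection:
    """Build a ranking per drug row of ``viability``, skipping sparse drugs.

    Drugs measured on fewer than ``min_lines`` of the expression lines are
    skipped with a warning rather than failing the whole build.
    """
    rankings = []
    for drug_id in viability.index:
        try:
            rankings.append(
                build_ranking(
                    expr,
                    viability.loc[drug_id],
                    str(drug_id),
                    min_lines=min_lines,
                    source_tag=source_tag,
                    metric_tag=metric_tag,
                )
            )
        except InsufficientLinesError as exc:
            warnings.warn(str(exc))
    if not rankings:
        raise ValueError("no drug passed the min_lines filter")
    return RankingCollection(rankings, expr.index.to_numpy(dtype=object))


def compare_rankings(a: DrugRanking, b: DrugRanking) -> float:
    """Spearman correlation between two rankings' score vectors.

    Computed over the shared genes (intersection) when the universes
    differ; fewer than 3 shared genes is an error.
    """
    shared = np.intersect1d(a.genes, b.genes)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    sa = pd.Series(a.scores, index=a.genes).loc[shared]
    sb = pd.Series(b.scores, index=b.genes).loc[shared]
    rho = stats.spearmanr(sa.to_numpy(), sb.to_numpy()).statistic
    return float(rho)


_SAFE = re.compile(r"[^A-Za-z0-9._-]+")


def save_collection(collection: RankingCollection, outdir: str | Path) -> Path:
    """Serialize a collection: per-drug TSVs, a bundled TSV and a manifest.

    Scores are written with the shortest round-trip repr (and re-read with
    pandas' round-trip parser) so a load is bit-exact.
    """
    outdir = Path(outdir)
    per_drug = outdir / "rankings"
    per_drug.mkdir(parents=True, exist_ok=True)
    entries = []
    bundle_frames = []
    for i, r in enumerate(collection):
        fname = f"{i:04d}_{_SAFE.sub('_', r.drug_id)}.tsv"
        frame = r.to_frame()
        # shortest round-trip repr so a reload is bit-exact
        frame.assign(score=[repr(float(s)) for s in r.scores]).to_csv(
            per_drug / fname, sep="\t", index=False
        )
        entries.append(
            {
                "drug_id": r.drug_id,
                "source_tag": r.source_tag,
                "metric_tag": r.metric_tag,
                "n_lines_used": r.n_lines_used,
                "file": f"rankings/{fname}",
            }
        )
        bundle_frames.append(frame.assign(drug_id=r.drug_id))
    pd.concat(bundle_frames)[["drug_id", "gene", "score"]].to_csv(
        outdir / "rankings.tsv", sep="\t", index=False, float_format="%.17g"
    )
    (outdir / "gene_universe.txt").write_text(
        "\n".join(map(str, collection.gene_universe)) + "\n"
    )
    (outdir / "manifest.json").write_text(json.dumps({"drugs": entries}, indent=2))
    return outdir


def load_collection(indir: str | Path) -> RankingCollection:
    """Load a collection written by :func:`save_collection`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    universe = np.array(
        (indir / "gene_universe.txt").read_text().splitlines(), dtype=object
    )
    rankings = []
    for entry in manifest["drugs"]:
        frame = pd.read_csv(
            indir / entry["file"],
            sep="\t",
            dtype={"gene": str},
            float_precision="round_trip",
        )
        rankings.append(
            DrugRanking(
                drug_id=entry["drug_id"],
                genes=frame["gene"].to_numpy(dtype=object),
                scores=frame["score"].to_numpy(dtype=float),
                n_lines_used=int(entry["n_lines_used"]),
                source_tag=entry["source_tag"],
                metric_tag=entry["metric_tag"],
            )
        )
    return RankingCollection(rankings, universe)
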