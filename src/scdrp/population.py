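"""Population-level aggregation, evaluation and differential analysis.

Per-cell enrichment records are aggregated to groups (cell lines,
subpopulations, patients) by median ES and by the fraction of cells called
sensitive. Predictions are benchmarked against a potency-derived gold
standard with PR/ROC curves, summarized into a binarized
fraction-sensitive landscape clustered by Jaccard distance, and compared
between subpopulations with per-drug Mann-Whitney tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn import metrics as skm

from .enrichment import bh_adjust


def _as_group_series(grouping, cell_ids) -> pd.Series:
    groups = pd.Series(grouping) if not isinstance(grouping, pd.Series) else grouping
    missing = [c for c in cell_ids if c not in groups.index]
    if missing:
        raise ValueError(f"cells without a group label: {missing[:5]}")
    return groups


def median_es(records: pd.DataFrame, grouping) -> pd.DataFrame:
    """Group x drug median ES; undefined (NaN) records are excluded.

    A (group, drug) cell with no defined record stays NaN rather than 0.
    """
    groups = _as_group_series(grouping, records["cell_id"].unique())
    labelled = records.assign(group=records["cell_id"].map(groups))
    sizes = labelled.groupby("group")["cell_id"].nunique()
    if (sizes == 0).any():
        raise ValueError("empty group")
    return labelled.pivot_table(
        index="group", columns="drug_id", values="es", aggfunc="median"
    )


def percent_sensitive(
    records: pd.DataFrame,
    grouping,
    rule: str = "fdr",
    threshold: float | None = None,
) -> pd.DataFrame:
    """Fraction of each group's cells with a significant negative ES.

    ``rule`` selects the significance statistic: ``"fdr"`` (default
    threshold 0.1) or ``"p"`` (default threshold 0.05). The denominator is
    the full group size, undefined records included.
    """
    if rule not in {"fdr", "p"}:
        raise ValueError("rule must be 'fdr' or 'p'")
    column = "fdr" if rule == "fdr" else "p_value"
    if column not in records.columns:
        raise ValueError(f"records lack column {column!r}")
    if threshold is None:
        threshold = 0.1 if rule == "fdr" else 0.05
    groups = _as_group_series(grouping, records["cell_id"].unique())
    labelled = records.assign(group=records["cell_id"].map(groups))
    group_sizes = labelled.groupby("group")["cell_id"].nunique()
    if (group_sizes == 0).any():
        raise ValueError("empty group")
    hit = (labelled["es"] < 0) & (labelled[column] < threshold)
    counts = labelled.assign(hit=hit).pivot_table(
        index="group", columns="drug_id", values="hit", aggfunc="sum", fill_value=0
    )
    return counts.div(group_sizes, axis=0)


@dataclass
class GoldStandard:
    """Per-drug sets of cell lines called sensitive from potency z-scores."""

    sensitive_pairs: set
    line_ids: list
    drug_ids: list
    percentile: float
    provenance: dict = field(default_factory=dict)

    def label(self, line_id, drug_id) -> int:
        return int((line_id, drug_id) in self.sensitive_pairs)


def build_gold_standard(
    viability: pd.DataFrame, percentile: float = 0.05, min_lines: int = 2
) -> GoldStandard:
    """Flag, per drug, the lines whose potency z-score sits in the bottom tail.

    Potency (AUC) is z-scored across the drug's non-missing lines, and
    lines at or below the ``percentile`` quantile (linear-interpolation
    convention) of those z-scores are labelled sensitive — z-scoring is
    order preserving, so this equals the same quantile cut on raw AUC.
    Zero-variance drugs flag nothing (with a warning).
    """
    if not 0 < percentile < 1:
        raise ValueError("percentile must be in (0, 1)")
    pairs = set()
    for drug_id, row in viability.iterrows():
        values = row.dropna()
        if len(values) < min_lines:
            continue
        sd = values.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            warnings.warn(f"drug {drug_id!r}: zero potency variance, nothing flagged")
            continue
        z = (values - values.mean()) / sd
        cut = np.quantile(z.to_numpy(), percentile)
        for line_id in values.index[z <= cut]:
            pairs.add((line_id, drug_id))
    return GoldStandard(
        sensitive_pairs=pairs,
        line_ids=list(viability.columns),
        drug_ids=list(viability.index),
        percentile=percentile,
        provenance={"min_lines": min_lines, "quantile": "linear"},
    )


@dataclass
class EvaluationResult:
    roc_auc: float
    pr_auc: float
    roc_curve: pd.DataFrame
    pr_curve: pd.DataFrame
    per_drug_roc_auc: pd.Series
    per_line_roc_auc: pd.Series
    n_positive: int
    n_negative: int


def _safe_roc_auc(y: np.ndarray, score: np.ndarray) -> float:
    if len(set(y)) < 2:
        return float("nan")
    return float(skm.roc_auc_score(y, score))


def evaluate_predictions(pred: pd.DataFrame, gold: GoldStandard) -> EvaluationResult:
    """PR/ROC evaluation of group x drug median-ES predictions.

    Pairs are ranked by ES multiplied by -1 so predicted-sensitive pairs
    come first; the ROC AUC is the rank (Mann-Whitney) statistic and the PR
    summary is step-interpolated average precision. Per-drug and per-line
    ROC AUCs restrict the same gold standard to one column or row.
    """
    rows = []
    for line_id in pred.index:
        for drug_id in pred.columns:
            value = pred.at[line_id, drug_id]
            if pd.isna(value):
                continue
            if line_id not in gold.line_ids or drug_id not in gold.drug_ids:
                continue
            rows.append((line_id, drug_id, -float(value), gold.label(line_id, drug_id)))
    if not rows:
        raise ValueError("no evaluable (group, drug) pairs")
    table = pd.DataFrame(rows, columns=["line_id", "drug_id", "score", "label"])
    n_pos = int(table["label"].sum())
    n_neg = int(len(table) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("gold standard is degenerate over the evaluable pairs")
    y = table["label"].to_numpy()
    score = table["score"].to_numpy()
    fpr, tpr, roc_thr = skm.roc_curve(y, score)
    precision, recall, pr_thr = skm.precision_recall_curve(y, score)
    per_drug = table.groupby("drug_id").apply(
        lambda t: _safe_roc_auc(t["label"].to_numpy(), t["score"].to_numpy()),
        include_groups=False,
    )
    per_line = table.groupby("line_id").apply(
        lambda t: _safe_roc_auc(t["label"].to_numpy(), t["score"].to_numpy()),
        include_groups=False,
    )
    return EvaluationResult(
        roc_auc=float(skm.roc_auc_score(y, score)),
        pr_auc=float(skm.average_precision_score(y, score)),
        roc_curve=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr}),
        pr_curve=pd.DataFrame(
            {
                "precision": precision,
                "recall": recall,
                "threshold": np.append(pr_thr, np.nan),
            }
        ),
        per_drug_roc_auc=per_drug,
        per_line_roc_auc=per_line,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def correlate_predictions(
    pred: pd.DataFrame, observed: pd.DataFrame
) -> tuple[float, float]:
    """Spearman correlation between predicted median ES and observed potency.

    Matched over shared (group, drug) pairs with both values present. Lower
    potency (more growth inhibition) should pair with more negative ES, so
    a working predictor yields a *positive* coefficient here.
    """
    shared_rows = pred.index.intersection(observed.index)
    shared_cols = pred.columns.intersection(observed.columns)
    a = pred.loc[shared_rows, shared_cols].to_numpy(dtype=float).ravel()
    b = observed.loc[shared_rows, shared_cols].to_numpy(dtype=float).ravel()
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError(f"only {int(ok.sum())} matched pairs; need >= 3")
    result = stats.spearmanr(a[ok], b[ok])
    return float(result.statistic), float(result.pvalue)


@dataclass
class Landscape:
    fraction_sensitive: pd.DataFrame
    binary: pd.DataFrame
    row_clusters: pd.Series
    col_clusters: pd.Series
    linkage_method: str


def cluster_binary_matrix(
    binary: pd.DataFrame, k_rows: int, k_cols: int, method: str = "complete"
) -> tuple[pd.Series, pd.Series]:
    """Jaccard-distance agglomerative clustering of a 0/1 matrix, cut at k."""

    def _cut(matrix: np.ndarray, k: int, index) -> pd.Series:
        if matrix.shape[0] < 2:
            return pd.Series(np.ones(matrix.shape[0], dtype=int), index=index)
        d = pdist(matrix.astype(bool), metric="jaccard")
        tree = linkage(d, method=method)
        labels = fcluster(tree, t=min(k, matrix.shape[0]), criterion="maxclust")
        return pd.Series(labels, index=index)

    return (
        _cut(binary.to_numpy(), k_rows, binary.index),
        _cut(binary.to_numpy().T, k_cols, binary.columns),
    )


def build_landscape(
    records: pd.DataFrame,
    grouping,
    sens_threshold: float = 0.9,
    rule: str = "p",
    rule_threshold: float | None = None,
    k_rows: int = 4,
    k_cols: int = 4,
    linkage_method: str = "complete",
) -> Landscape:
    """Fraction-sensitive landscape: binarize at >= ``sens_threshold``, cluster.

    The significance rule defaults to p < 0.05 here (other aggregations
    default to FDR < 0.1). An all-zero binarized matrix cannot be
    clustered and is rejected.
    """
    fraction = percent_sensitive(records, grouping, rule=rule, threshold=rule_threshold)
    binary = (fraction >= sens_threshold).astype(int)
    if binary.to_numpy().sum() == 0:
        raise ValueError(
            f"no (group, drug) entry reaches fraction >= {sens_threshold}; "
            "nothing to cluster"
        )
    row_clusters, col_clusters = cluster_binary_matrix(
        binary, k_rows, k_cols, method=linkage_method
    )
    return Landscape(fraction, binary, row_clusters, col_clusters, linkage_method)


def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([x, y]))
    n1 = len(x)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)


def mann_whitney(
    x: np.ndarray, y: np.ndarray, exact_limit: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney test returning (U, p).

    Small tie-safe exact path: when the pooled size is at most
    ``exact_limit`` the label permutation distribution of U is enumerated
    (symmetric about n1*n2/2, so the two-sided p sums both tails at the
    observed distance). Larger samples use the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return n1 * n2 / 2.0, 1.0
    u_obs = _mw_u(x, y)
    if n1 + n2 <= exact_limit:
        ranks = stats.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2
        u_low = min(u_obs, n1 * n2 - u_obs)
        hits = total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            if min(u, n1 * n2 - u) <= u_low + 1e-9:
                hits += 1
            total += 1
        return u_obs, hits / total
    result = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(result.statistic), float(result.pvalue)


def diff_drug_analysis(
    records: pd.DataFrame,
    labels,
    fdr_threshold: float = 0.1,
    exact_limit: int = 8,
) -> pd.DataFrame:
    """Per-drug differential sensitivity between each subpopulation and the rest.

    For every (focal group, drug): two-sided Mann-Whitney on the defined ES
    values of focal vs all other cells, BH-corrected across drugs within
    the focal group. A drug is flagged specific for the focal group when
    its FDR is below ``fdr_threshold`` and the median ES of *every* other
    group is greater than zero. Drugs whose ES is zero for all tested cells
    are excluded.
    """
    groups = _as_group_series(labels, records["cell_id"].unique())
    labelled = records.assign(group=records["cell_id"].map(groups)).dropna(
        subset=["es"]
    )
    group_names = sorted(labelled["group"].unique())
    if len(group_names) < 2:
        raise ValueError("need at least 2 subpopulations")
    sizes = labelled.groupby("group")["cell_id"].nunique()
    if (sizes < 2).any():
        raise ValueError("every subpopulation needs at least 2 cells")
    rows = []
    for focal in group_names:
        others = [g for g in group_names if g != focal]
        for drug_id, chunk in labelled.groupby("drug_id", sort=False):
            es = chunk["es"].to_numpy(dtype=float)
            if np.all(es == 0):
                continue
            x = chunk.loc[chunk["group"] == focal, "es"].to_numpy(dtype=float)
            y = chunk.loc[chunk["group"] != focal, "es"].to_numpy(dtype=float)
            if len(x) == 0 or len(y) == 0:
                continue
            u, p = mann_whitney(x, y, exact_limit=exact_limit)
            other_medians = [
                float(np.median(chunk.loc[chunk["group"] == g, "es"]))
                for g in others
                if (chunk["group"] == g).any()
            ]
            rows.append(
                {
                    "group": focal,
                    "drug_id": drug_id,
                    "u_statistic": u,
                    "p_value": p,
                    "median_focal": float(np.median(x)) if len(x) else np.nan,
                    "min_other_median": min(other_medians) if other_medians else np.nan,
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return result.reindex(
            columns=[
                "group",
                "drug_id",
                "u_statistic",
                "p_value",
                "fdr",
                "median_focal",
                "min_other_median",
                "specific",
            ]
        )
    result["fdr"] = np.nan
    for _, idx in result.groupby("group", sort=False).groups.items():
        result.loc[idx, "fdr"] = bh_adjust(result.loc[idx, "p_value"].to_numpy())
    result["specific"] = (result["fdr"] < fdr_threshold) & (
        result["min_other_median"] > 0
    )
    return result
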