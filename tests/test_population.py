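from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scdrp.population import (
    GoldStandard,
    build_gold_standard,
    build_landscape,
    cluster_binary_matrix,
    correlate_predictions,
    diff_drug_analysis,
    evaluate_predictions,
    mann_whitney,
    median_es,
    percent_sensitive,
)


def records_from(es_by_cell_drug: dict, p=0.01, fdr=0.01) -> pd.DataFrame:
    rows = []
    for (cell, drug), es in es_by_cell_drug.items():
        rows.append((cell, drug, es, p, 10, fdr))
    return pd.DataFrame(
        rows, columns=["cell_id", "drug_id", "es", "p_value", "n_overlap", "fdr"]
    )


class TestMedianEs:
    def test_single_cell_group(self):
        records = records_from({("c1", "d"): -0.3})
        out = median_es(records, {"c1": "A"})
        assert out.at["A", "d"] == pytest.approx(-0.3)

    def test_median_oracle(self):
        records = records_from(
            {("c1", "d"): -0.2, ("c2", "d"): -0.4, ("c3", "d"): 0.1}
        )
        out = median_es(records, {"c1": "A", "c2": "A", "c3": "A"})
        assert out.at["A", "d"] == pytest.approx(-0.2)

    def test_undefined_records_excluded_not_zeroed(self):
        records = records_from({("c1", "d"): np.nan, ("c2", "d"): -0.6})
        out = median_es(records, {"c1": "A", "c2": "A"})
        assert out.at["A", "d"] == pytest.approx(-0.6)

    def test_unlabelled_cell_rejected(self):
        records = records_from({("c1", "d"): 0.1})
        with pytest.raises(ValueError, match="without a group"):
            median_es(records, {"other": "A"})


class TestPercentSensitive:
    def test_all_significant_negative(self):
        records = records_from({(f"c{i}", "d"): -0.5 for i in range(4)}, fdr=0.01)
        out = percent_sensitive(records, {f"c{i}": "A" for i in range(4)})
        assert out.at["A", "d"] == 1.0

    def test_counting_oracle(self):
        # 10 cells: 3 significant ES<0, 2 non-significant ES<0, rest positive
        es = [-0.5, -0.4, -0.3, -0.2, -0.1, 0.1, 0.2, 0.3, 0.4, 0.5]
        fdr = [0.01, 0.01, 0.01, 0.5, 0.5, 0.01, 0.01, 0.5, 0.5, 0.01]
        rows = {(f"c{i}", "d"): es[i] for i in range(10)}
        records = records_from(rows)
        records["fdr"] = fdr
        out = percent_sensitive(records, {f"c{i}": "A" for i in range(10)}, rule="fdr")
        assert out.at["A", "d"] == pytest.approx(0.3)

    def test_no_significant_cells(self):
        records = records_from({("c1", "d"): -0.5, ("c2", "d"): -0.1}, fdr=0.9)
        out = percent_sensitive(records, {"c1": "A", "c2": "A"})
        assert out.at["A", "d"] == 0.0

    def test_p_rule_variant(self):
        records = records_from({("c1", "d"): -0.5, ("c2", "d"): -0.4})
        records["p_value"] = [0.04, 0.06]
        records["fdr"] = [0.9, 0.9]
        out = percent_sensitive(records, {"c1": "A", "c2": "A"}, rule="p")
        assert out.at["A", "d"] == pytest.approx(0.5)

    def test_unknown_rule(self):
        records = records_from({("c1", "d"): 0.0})
        with pytest.raises(ValueError, match="rule"):
            percent_sensitive(records, {"c1": "A"}, rule="bonferroni")


class TestGoldStandard:
    def test_twenty_distinct_lines_one_flagged(self, rng):
        auc = rng.permutation(np.linspace(0.1, 0.9, 20))
        lines = [f"l{j}" for j in range(20)]
        viability = pd.DataFrame([auc], index=["d"], columns=lines)
        gold = build_gold_standard(viability, percentile=0.05)
        assert gold.sensitive_pairs == {(lines[int(np.argmin(auc))], "d")}

    def test_hundred_lines_five_flagged(self, rng):
        auc = rng.permutation(np.linspace(0.0, 1.0, 100))
        lines = [f"l{j}" for j in range(100)]
        viability = pd.DataFrame([auc], index=["d"], columns=lines)
        gold = build_gold_standard(viability, percentile=0.05)
        assert len(gold.sensitive_pairs) == 5
        flagged_auc = sorted(auc[[lines.index(l) for l, _ in gold.sensitive_pairs]])
        assert flagged_auc == sorted(auc)[:5]  # the five lowest-AUC lines

    def test_constant_drug_flags_nothing(self):
        viability = pd.DataFrame([[0.5] * 10], index=["d"], columns=range(10))
        with pytest.warns(UserWarning, match="zero potency variance"):
            gold = build_gold_standard(viability)
        assert gold.sensitive_pairs == set()

    def test_missing_entries_ignored(self, rng):
        auc = np.append(rng.uniform(0.3, 0.9, 19), np.nan)
        viability = pd.DataFrame([auc], index=["d"], columns=[f"l{j}" for j in range(20)])
        gold = build_gold_standard(viability, percentile=0.05)
        assert all(l != "l19" for l, _ in gold.sensitive_pairs)

    def test_flag_count_monotone_in_percentile(self, rng):
        auc = rng.uniform(0, 1, size=(3, 50))
        viability = pd.DataFrame(auc, index=["a", "b", "c"], columns=range(50))
        counts = [
            len(build_gold_standard(viability, percentile=q).sensitive_pairs)
            for q in [0.02, 0.05, 0.1, 0.25, 0.5]
        ]
        assert counts == sorted(counts)


def simple_gold(pairs, lines, drugs, percentile=0.05) -> GoldStandard:
    return GoldStandard(set(pairs), list(lines), list(drugs), percentile)


class TestEvaluate:
    def test_perfect_ordering(self):
        pred = pd.DataFrame({"d": [-0.9, -0.8, 0.5, 0.6]}, index=list("abcd"))
        gold = simple_gold({("a", "d"), ("b", "d")}, "abcd", ["d"])
        assert evaluate_predictions(pred, gold).roc_auc == 1.0

    def test_inverted_ordering(self):
        pred = pd.DataFrame({"d": [0.9, 0.8, -0.5, -0.6]}, index=list("abcd"))
        gold = simple_gold({("a", "d"), ("b", "d")}, "abcd", ["d"])
        assert evaluate_predictions(pred, gold).roc_auc == 0.0

    def test_concordant_pair_counting(self):
        # ranking a, c, b, d with gold {a, b}: 3 of 4 pos-neg pairs concordant
        pred = pd.DataFrame({"d": [-0.9, -0.5, -0.7, 0.2]}, index=list("abcd"))
        gold = simple_gold({("a", "d"), ("b", "d")}, "abcd", ["d"])
        assert evaluate_predictions(pred, gold).roc_auc == pytest.approx(0.75)

    def test_roc_auc_equals_u_statistic(self, rng):
        for _ in range(100):
            n_lines, n_drugs = int(rng.integers(3, 8)), int(rng.integers(2, 5))
            lines = [f"l{j}" for j in range(n_lines)]
            drugs = [f"d{j}" for j in range(n_drugs)]
            pred = pd.DataFrame(
                rng.normal(size=(n_lines, n_drugs)), index=lines, columns=drugs
            )
            all_pairs = [(l, d) for l in lines for d in drugs]
            k = int(rng.integers(1, len(all_pairs)))
            positives = [all_pairs[i] for i in rng.choice(len(all_pairs), k, replace=False)]
            gold = simple_gold(positives, lines, drugs)
            result = evaluate_predictions(pred, gold)
            pos_scores = [-pred.at[l, d] for l, d in positives]
            neg_scores = [
                -pred.at[l, d] for l, d in all_pairs if (l, d) not in set(positives)
            ]
            u = stats.mannwhitneyu(pos_scores, neg_scores, alternative="two-sided").statistic
            expected = u / (len(pos_scores) * len(neg_scores))
            assert result.roc_auc == pytest.approx(expected)

    def test_degenerate_gold_rejected(self):
        pred = pd.DataFrame({"d": [-0.9, 0.5]}, index=list("ab"))
        gold = simple_gold({("a", "d"), ("b", "d")}, "ab", ["d"])
        with pytest.raises(ValueError, match="degenerate"):
            evaluate_predictions(pred, gold)

    def test_per_drug_and_per_line_aucs(self, rng):
        lines = [f"l{j}" for j in range(6)]
        drugs = ["d1", "d2"]
        pred = pd.DataFrame(rng.normal(size=(6, 2)), index=lines, columns=drugs)
        positives = {(l, "d1") for l in lines[:3]} | {(l, "d2") for l in lines[3:]}
        result = evaluate_predictions(pred, simple_gold(positives, lines, drugs))
        assert set(result.per_drug_roc_auc.index) == set(drugs)
        assert set(result.per_line_roc_auc.index) == set(lines)
        # each line has exactly one positive and one negative pair, so its
        # restricted ROC AUC is either 0 or 1
        assert result.per_line_roc_auc.isin([0.0, 1.0]).all()
        # per-drug AUC equals the evaluation restricted to that drug column
        for drug in drugs:
            restricted = evaluate_predictions(
                pred[[drug]], simple_gold(positives, lines, [drug])
            )
            assert result.per_drug_roc_auc[drug] == pytest.approx(restricted.roc_auc)

    def test_per_line_auc_nan_for_single_class(self):
        lines = ["l0", "l1"]
        pred = pd.DataFrame({"d": [-0.5, 0.5]}, index=lines)
        result = evaluate_predictions(pred, simple_gold({("l0", "d")}, lines, ["d"]))
        assert np.isnan(result.per_line_roc_auc).all()  # one pair per line


class TestCorrelate:
    def test_rank_identity(self):
        pred = pd.DataFrame({"d1": [-0.5, -0.2, 0.3], "d2": [-0.1, 0.2, 0.4]},
                            index=list("abc"))
        observed = 2.0 * pred + 5.0  # monotone transform: same ranks
        scc, p = correlate_predictions(pred, observed)
        assert scc == pytest.approx(1.0)

    def test_anti_ranked(self):
        pred = pd.DataFrame({"d1": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=list("abcde"))
        observed = pd.DataFrame({"d1": [5.0, 4.0, 3.0, 2.0, 1.0]}, index=list("abcde"))
        scc, _ = correlate_predictions(pred, observed)
        assert scc == pytest.approx(-1.0)

    def test_toy_table_matches_rank_oracle(self, rng):
        pred = pd.DataFrame({"d1": rng.normal(size=5)}, index=list("abcde"))
        observed = pd.DataFrame({"d1": rng.normal(size=5)}, index=list("abcde"))
        scc, p = correlate_predictions(pred, observed)
        expected = stats.spearmanr(pred["d1"], observed["d1"])
        assert scc == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)

    def test_too_few_pairs(self):
        pred = pd.DataFrame({"d1": [1.0, 2.0]}, index=list("ab"))
        with pytest.raises(ValueError, match=">= 3"):
            correlate_predictions(pred, pred)


class TestLandscape:
    def make_records(self, fractions: dict) -> tuple[pd.DataFrame, dict]:
        """10 cells per group; `fractions[group][drug]` cells get significant ES<0."""
        rows = []
        grouping = {}
        for group, per_drug in fractions.items():
            for i in range(10):
                cell = f"{group}_{i}"
                grouping[cell] = group
                for drug, n_hit in per_drug.items():
                    hit = i < n_hit
                    rows.append(
                        (cell, drug, -0.5 if hit else 0.4,
                         0.01 if hit else 0.8, 10, 0.01 if hit else 0.8)
                    )
        frame = pd.DataFrame(
            rows, columns=["cell_id", "drug_id", "es", "p_value", "n_overlap", "fdr"]
        )
        return frame, grouping

    def test_binarization_boundary_inclusive(self):
        records, grouping = self.make_records(
            {"A": {"d1": 9, "d2": 8}, "B": {"d1": 10, "d2": 2}}
        )
        landscape = build_landscape(records, grouping, k_rows=2, k_cols=2)
        assert landscape.fraction_sensitive.at["A", "d1"] == pytest.approx(0.9)
        assert landscape.binary.at["A", "d1"] == 1  # exactly 0.9 -> 1
        assert landscape.binary.at["A", "d2"] == 0  # 0.8 -> 0
        assert landscape.binary.at["B", "d1"] == 1  # 1.0 -> 1

    def test_all_zero_rejected(self):
        records, grouping = self.make_records({"A": {"d1": 1}, "B": {"d1": 2}})
        with pytest.raises(ValueError, match="nothing to cluster"):
            build_landscape(records, grouping)

    def test_block_diagonal_recovery(self):
        binary = pd.DataFrame(
            [
                [1, 1, 1, 0, 0],
                [1, 1, 1, 0, 0],
                [1, 1, 1, 0, 0],
                [0, 0, 0, 1, 1],
                [0, 0, 0, 1, 1],
            ],
            index=list("abcde"),
            columns=[f"d{j}" for j in range(5)],
        )
        row_clusters, col_clusters = cluster_binary_matrix(binary, 2, 2)
        assert row_clusters["a"] == row_clusters["b"] == row_clusters["c"]
        assert row_clusters["d"] == row_clusters["e"]
        assert row_clusters["a"] != row_clusters["d"]
        assert col_clusters["d0"] == col_clusters["d1"] == col_clusters["d2"]
        assert col_clusters["d3"] == col_clusters["d4"]
        assert col_clusters["d0"] != col_clusters["d3"]

    def test_input_order_invariance(self, rng):
        binary = pd.DataFrame(
            rng.integers(0, 2, size=(8, 6)),
            index=[f"r{i}" for i in range(8)],
            columns=[f"c{j}" for j in range(6)],
        )
        binary.iloc[0, :] = 1  # ensure nonzero
        rows_a, _ = cluster_binary_matrix(binary, 3, 2)
        perm = rng.permutation(8)
        rows_b, _ = cluster_binary_matrix(binary.iloc[perm], 3, 2)
        # same partition up to label permutation
        for i in range(8):
            for j in range(8):
                same_a = rows_a.iloc[i] == rows_a.iloc[j]
                same_b = rows_b[rows_a.index[i]] == rows_b[rows_a.index[j]]
                assert same_a == same_b


class TestMannWhitney:
    def test_spec_worked_example(self):
        u, p = mann_whitney([-0.5, -0.4, -0.6], [0.1, 0.2, 0.3])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_exact_matches_scipy_enumeration(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 9 - n1))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            u, p = mann_whitney(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_all_tied_p_one(self):
        u, p = mann_whitney([0.2, 0.2], [0.2, 0.2, 0.2])
        assert p == 1.0

    def test_large_groups_use_asymptotic(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(0.5, size=25)
        _, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue)

    def test_exact_enumeration_oracle_with_ties(self, rng):
        # independent enumeration over labelings, midranks for ties
        x = np.array([1.0, 2.0, 2.0])
        y = np.array([2.0, 3.0])
        u_obs, p = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        n1, n2 = 3, 2
        u_low = min(u_obs, n1 * n2 - u_obs)
        hits = 0
        subsets = list(combinations(range(5), 3))
        for idx in subsets:
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            if min(u, n1 * n2 - u) <= u_low + 1e-9:
                hits += 1
        assert p == pytest.approx(hits / len(subsets))


class TestDiffDrugAnalysis:
    def base_records(self):
        rows = []
        for i, es in enumerate([-0.5, -0.4, -0.6]):
            rows.append((f"a{i}", "d1", es, 0.01, 10))
        for i, es in enumerate([0.1, 0.2, 0.3]):
            rows.append((f"b{i}", "d1", es, 0.01, 10))
        return pd.DataFrame(
            rows, columns=["cell_id", "drug_id", "es", "p_value", "n_overlap"]
        )

    def labels(self):
        return {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)}

    def test_spec_worked_example(self):
        out = diff_drug_analysis(self.base_records(), self.labels())
        row = out[(out["group"] == "A") & (out["drug_id"] == "d1")].iloc[0]
        assert row["u_statistic"] == 0.0
        assert row["p_value"] == pytest.approx(0.1)
        assert row["min_other_median"] == pytest.approx(0.2)
        # single drug: FDR = p = 0.1, which does NOT clear FDR < 0.1
        assert row["fdr"] == pytest.approx(0.1)
        assert not row["specific"]

    def test_specific_when_fdr_clears(self):
        # two drugs: the second is identical noise, BH keeps d1's FDR at ~0.1;
        # lower the d1 p by enlarging groups so FDR < 0.1 and B median > 0
        rows = []
        for i in range(6):
            rows.append((f"a{i}", "d1", -0.5 - 0.01 * i, 0.01, 10))
            rows.append((f"b{i}", "d1", 0.2 + 0.01 * i, 0.01, 10))
        records = pd.DataFrame(
            rows, columns=["cell_id", "drug_id", "es", "p_value", "n_overlap"]
        )
        labels = {f"a{i}": "A" for i in range(6)} | {f"b{i}": "B" for i in range(6)}
        out = diff_drug_analysis(records, labels)
        row = out[(out["group"] == "A") & (out["drug_id"] == "d1")].iloc[0]
        assert row["fdr"] < 0.1
        assert row["specific"]
        row_b = out[(out["group"] == "B") & (out["drug_id"] == "d1")].iloc[0]
        assert not row_b["specific"]  # other-group median is negative

    def test_identical_distributions_not_specific(self):
        rows = []
        for g, prefix in [("A", "a"), ("B", "b")]:
            for i, es in enumerate([0.1, 0.2, 0.3]):
                rows.append((f"{prefix}{i}", "d1", es, 0.01, 10))
        records = pd.DataFrame(
            rows, columns=["cell_id", "drug_id", "es", "p_value", "n_overlap"]
        )
        labels = {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)}
        out = diff_drug_analysis(records, labels)
        assert not out["specific"].any()

    def test_all_zero_drug_excluded(self):
        records = self.base_records()
        zero = records.copy()
        zero["drug_id"] = "dzero"
        zero["es"] = 0.0
        out = diff_drug_analysis(pd.concat([records, zero]), self.labels())
        assert "dzero" not in set(out["drug_id"])

    def test_all_tied_nonzero_drug_p_one(self):
        records = self.base_records()
        tied = records.copy()
        tied["drug_id"] = "dtied"
        tied["es"] = 0.7
        out = diff_drug_analysis(pd.concat([records, tied]), self.labels())
        row = out[(out["group"] == "A") & (out["drug_id"] == "dtied")].iloc[0]
        assert row["p_value"] == 1.0
        assert not row["specific"]

    def test_needs_two_groups(self):
        records = self.base_records()
        with pytest.raises(ValueError, match="2 subpopulations"):
            diff_drug_analysis(records, {c: "A" for c in records["cell_id"]})

    def test_small_groups_rejected(self):
        records = self.base_records()
        labels = self.labels() | {"b1": "C"}
        del labels["b2"]
        records = records[records["cell_id"] != "b2"]
        with pytest.raises(ValueError, match="at least 2 cells"):
            diff_drug_analysis(records, labels)
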