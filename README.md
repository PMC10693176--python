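# scdrp

Per-cell drug sensitivity prediction from single-cell transcriptomes.

Given (1) a bulk expression matrix of cancer cell lines and (2) a drug
viability table (AUC of the dose-response curve, or IC50) over those lines,
`scdrp` builds one **drug gene ranking** per drug: every gene ordered by the
Pearson correlation between its expression (log10(CPM+1)) and the drug's
potency. Genes that correlate positively with AUC are resistance biomarkers
and sit at the top; sensitivity biomarkers sit at the bottom.

Single cells are then scored drug by drug: UMI counts are QC-filtered
(≥ 5000 UMI, < 10% mitochondrial), normalized with a gene-frequency /
inverse-cell-frequency scheme, and each cell's top-N relevant genes are
tested against every drug ranking with the classic weighted
Kolmogorov–Smirnov running-sum enrichment score (ES ∈ [−1, +1]; negative =
predicted sensitive, positive = predicted tolerant). Permutation p-values
are BH-corrected per drug across cells, and significant ES values populate
the cells × drugs response matrix **E** (0 = no supporting evidence).

Downstream, the package aggregates predictions to populations (median ES,
fraction sensitive), benchmarks them against a potency-derived gold
standard (PR/ROC), reconstructs a binarized fraction-sensitive landscape
with Jaccard-distance hierarchical clustering, runs per-drug Mann–Whitney
differential-sensitivity tests between subpopulations, and embeds cells in
2-D from the sign-agreement ("fuzzy Jaccard") distance of their response
rows. A synthetic-data module generates seeded bulk and single-cell
fixtures with planted biomarkers and planted sensitive/tolerant
subpopulations so the whole pipeline is testable offline.

## Library sketch

```python
import pandas as pd
import scdrp as s

counts, viability, truth = s.simulate_pharmacogenomic(seed=0)
expr = s.filter_genes(s.normalize_bulk(counts))          # log10(CPM+1) + entropy filter
rankings = s.build_ranking_collection(expr, viability, min_lines=100)

sc, sc_truth = s.simulate_single_cell(
    rankings, [s.PopulationSpec.single("popA", "D000", "sensitive")]
)
sc = s.qc_filter_cells(sc)                               # >=5000 UMI, <10% mito
relevant = s.top_relevant_genes(s.gficf_normalize(sc), n=500)
records = s.fdr_correct(s.score_cells(relevant, rankings, n_perm=1000, seed=1))
response = s.build_response_matrix(records, fdr_threshold=0.1)

medians = s.median_es(records, pd.Series(sc_truth.cell_population))
coords = s.reduce_drug_space(s.fuzzy_jaccard(response), seed=42)
diff = s.diff_drug_analysis(records, pd.Series(sc_truth.cell_population))
```

## CLI

One console script, `scdrp`, with subcommands mirroring the pipeline:

```bash
scdrp simulate bulk --n-lines 200 --n-genes 2000 --n-drugs 5 --seed 0 --out bulk/
scdrp build-rankings --expr bulk/bulk_counts.csv --viability bulk/viability.csv \
      --min-lines 100 --entropy-pct 0.05 --out rankings/
scdrp simulate sc --rankings rankings/ \
      --populations "popA:D000:sensitive,popB:D001:tolerant" --out sc/
scdrp score --sc sc/matrix.mtx --features sc/features.tsv --barcodes sc/barcodes.tsv \
      --rankings rankings/ --topn 500 --n-perm 1000 --seed 1 --out scored/
scdrp evaluate --records scored/records.tsv --labels sc/labels.tsv \
      --viability bulk/viability.csv --out eval/
scdrp landscape --records scored/records.tsv --labels sc/labels.tsv --out landscape/
scdrp diff --records scored/records.tsv --labels sc/labels.tsv --out diff.tsv
scdrp embed --e-matrix scored/E.csv --seed 42 --out coords.tsv
```

All inputs/outputs are plain text: dense CSV/TSV matrices (header = column
ids, first column = row ids), CellRanger-style MTX triplets, long-format
record TSVs, and JSON manifests.

## Notes and caveats

- Bulk normalization is plain per-line CPM; no compositional (TMM-style)
  re-weighting. Pre-normalized matrices can be passed straight through.
- The gf-icf variant is GF = count/total, ICF = ln(n_cells/n_expressing),
  unsmoothed: genes expressed in every cell score 0 and never rank as
  relevant.
- The sign-agreement cell distance implements its defining formula
  exactly. A consequence worth knowing: rows containing zero
  (no-evidence) entries have *positive self-distance*, so the matrix is a
  true metric only on zero-free response matrices; no normalized variant
  is substituted silently.
- Mann–Whitney p-values are exact (tie-safe label enumeration) for pooled
  sizes ≤ 8, tie-corrected normal approximation above.
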