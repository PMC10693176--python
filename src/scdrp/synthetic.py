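"""Seeded synthetic fixtures with planted ground truth.

Two generators: a bulk pharmacogenomic cohort in which chosen biomarker
genes are linearly coupled (in log space) to each drug's potency, and a
single-cell cohort in which subpopulations up-weight the extreme genes of
a given drug ranking so that their predicted phenotype is known. Both are
bit-exactly reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import sparse

from .gficf import CellCounts
from .rankings import RankingCollection

SENSITIVE = "sensitive"
TOLERANT = "tolerant"


@dataclass
class BulkTruth:
    """Planted biomarkers of a pharmacogenomic fixture."""

    resistance_genes: dict[str, list[str]]
    sensitivity_genes: dict[str, list[str]]
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_pharmacogenomic(
    n_lines: int = 200,
    n_genes: int = 1000,
    n_drugs: int = 5,
    n_biomarkers_per_drug: int = 20,
    effect: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    base_log_expr: float = 2.0,
    background_sd: float = 0.5,
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, BulkTruth]:
    """Bulk counts + potency table with planted gene-drug correlations.

    Per drug, potency (AUC) is uniform on [0, 1] across lines. Each drug
    gets ``n_biomarkers_per_drug`` resistance genes whose log10 expression
    is ``base + effect * (AUC - 1/2) + N(0, noise_sd)`` and the same number
    of sensitivity genes with the opposite slope; background genes are
    independent noise around the base level. Counts are recovered by
    exponentiation (``round(10^x - 1)``), so at ``noise_sd = 0`` the
    planted genes correlate near-perfectly with potency after CPM
    re-normalization (up to rounding).
    """
    if n_lines < 3:
        raise ValueError("n_lines must be >= 3")
    if 2 * n_biomarkers_per_drug * n_drugs > n_genes:
        raise ValueError("not enough genes to plant all biomarkers")
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    lines = np.array([f"L{i:04d}" for i in range(n_lines)], dtype=object)
    drugs = np.array([f"D{i:03d}" for i in range(n_drugs)], dtype=object)

    auc = rng.uniform(0.0, 1.0, size=(n_drugs, n_lines))
    log_expr = base_log_expr + rng.normal(0.0, background_sd, size=(n_genes, n_lines))

    resistance: dict[str, list[str]] = {}
    sensitivity: dict[str, list[str]] = {}
    cursor = 0
    for d in range(n_drugs):
        res_idx = np.arange(cursor, cursor + n_biomarkers_per_drug)
        cursor += n_biomarkers_per_drug
        sen_idx = np.arange(cursor, cursor + n_biomarkers_per_drug)
        cursor += n_biomarkers_per_drug
        centred = auc[d] - 0.5
        log_expr[res_idx] = (
            base_log_expr
            + effect * centred
            + rng.normal(0.0, noise_sd, size=(len(res_idx), n_lines))
        )
        log_expr[sen_idx] = (
            base_log_expr
            - effect * centred
            + rng.normal(0.0, noise_sd, size=(len(sen_idx), n_lines))
        )
        resistance[str(drugs[d])] = genes[res_idx].astype(str).tolist()
        sensitivity[str(drugs[d])] = genes[sen_idx].astype(str).tolist()

    np.clip(log_expr, 0.0, None, out=log_expr)
    counts = np.rint(10.0**log_expr - 1.0).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=genes, columns=lines)

    viability = pd.DataFrame(auc, index=drugs, columns=lines)
    if missing_rate > 0:
        mask = rng.random(viability.shape) < missing_rate
        viability = viability.mask(mask)

    truth = BulkTruth(
        resistance_genes=resistance,
        sensitivity_genes=sensitivity,
        seed=seed,
        params={
            "n_lines": n_lines,
            "n_genes": n_genes,
            "n_drugs": n_drugs,
            "n_biomarkers_per_drug": n_biomarkers_per_drug,
            "effect": effect,
            "noise_sd": noise_sd,
            "base_log_expr": base_log_expr,
            "background_sd": background_sd,
            "missing_rate": missing_rate,
        },
    )
    return counts_df, viability, truth


def ic50_from_auc(viability: pd.DataFrame, scale: float = 4.0) -> pd.DataFrame:
    """Monotone transform of an AUC table into a synthetic IC50 table.

    Strictly increasing, so sensitivity ordering is preserved; used to
    exercise the alternative potency-metric configuration.
    """
    return 10.0 ** (scale * (viability - 0.5))


@dataclass(frozen=True)
class PopulationSpec:
    """A cell subpopulation and its planted per-drug phenotypes."""

    name: str
    programs: tuple[tuple[str, str], ...]  # (drug_id, "sensitive"|"tolerant")

    @classmethod
    def single(cls, name: str, drug_id: str, phenotype: str) -> "PopulationSpec":
        return cls(name=name, programs=((drug_id, phenotype),))


@dataclass
class SingleCellTruth:
    """Planted phenotype of every generated cell."""

    cell_population: dict[str, str]
    population_programs: dict[str, dict[str, str]]
    program_genes: dict[str, list[str]]
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_single_cell(
    collection: RankingCollection,
    populations: list[PopulationSpec],
    n_cells_per_pop: int = 50,
    n_program_genes: int = 50,
    signal_strength: float = 5.0,
    library_size_range: tuple[int, int] = (5000, 20000),
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> tuple[CellCounts, SingleCellTruth]:
    """UMI counts for subpopulations programmed against a ranking collection.

    Each population's expected expression up-weights, by a factor
    ``1 + signal_strength``, the ``n_program_genes`` genes at the relevant
    extreme of its drug's ranking: the top (resistance biomarkers) for a
    ``tolerant`` program, the bottom (sensitivity biomarkers) for a
    ``sensitive`` one, on a shared lognormal background. Dropout zeroes a
    Bernoulli fraction of each cell's gene probabilities *before* the
    multinomial draw, so every cell's observed total equals its drawn
    library size and QC behaviour is predictable by construction.
    """
    if not populations:
        raise ValueError("populations must be nonempty")
    lo, hi = library_size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid library_size_range")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    genes = np.asarray(collection.gene_universe, dtype=object)
    n_genes = len(genes)
    if n_program_genes > n_genes:
        raise ValueError("n_program_genes exceeds the gene universe")
    rng = np.random.default_rng(seed)
    background = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    pop_weights = {}
    program_genes: dict[str, list[str]] = {}
    for spec in populations:
        weights = background.copy()
        planted: list[str] = []
        for drug_id, phenotype in spec.programs:
            ranking = collection[drug_id]  # KeyError for unknown drug
            if phenotype == TOLERANT:
                chosen = ranking.genes[:n_program_genes]
            elif phenotype == SENSITIVE:
                chosen = ranking.genes[-n_program_genes:]
            else:
                raise ValueError(f"unknown phenotype {phenotype!r}")
            idx = np.flatnonzero(np.isin(genes, chosen))
            weights[idx] *= 1.0 + signal_strength
            planted.extend(str(x) for x in chosen)
        pop_weights[spec.name] = weights
        program_genes[spec.name] = planted

    columns = []
    cell_ids = []
    cell_population = {}
    for spec in populations:
        weights = pop_weights[spec.name]
        for i in range(n_cells_per_pop):
            cell_id = f"{spec.name}_c{i:04d}"
            cell_ids.append(cell_id)
            cell_population[cell_id] = spec.name
            p = weights.copy()
            if dropout_rate > 0:
                p = p * (rng.random(n_genes) >= dropout_rate)
            total = p.sum()
            if total <= 0:
                raise ValueError("dropout removed every gene of a cell")
            lib = int(rng.integers(lo, hi + 1))
            columns.append(rng.multinomial(lib, p / total))
    counts = sparse.csr_matrix(np.column_stack(columns))
    matrix = CellCounts(counts, genes, np.array(cell_ids, dtype=object))
    truth = SingleCellTruth(
        cell_population=cell_population,
        population_programs={
            spec.name: dict(spec.programs) for spec in populations
        },
        program_genes=program_genes,
        seed=seed,
        params={
            "n_cells_per_pop": n_cells_per_pop,
            "n_program_genes": n_program_genes,
            "signal_strength": signal_strength,
            "library_size_range": list(library_size_range),
            "dropout_rate": dropout_rate,
        },
    )
    return matrix, truth
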