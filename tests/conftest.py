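from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scdrp.rankings import DrugRanking


def make_ranking(scores, drug_id: str = "drugX", genes=None) -> DrugRanking:
    """Ranking with the given (non-increasing) scores and default gene ids."""
    scores = np.asarray(scores, dtype=float)
    if genes is None:
        genes = np.array([f"g{i:03d}" for i in range(len(scores))], dtype=object)
    return DrugRanking(
        drug_id=drug_id,
        genes=np.asarray(genes, dtype=object),
        scores=scores,
        n_lines_used=10,
    )


def descending_scores(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random strictly decreasing scores in (-1, 1)."""
    raw = np.sort(rng.uniform(-1, 1, size=length))[::-1]
    return raw


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_records() -> pd.DataFrame:
    """Two groups x two drugs worth of enrichment records with fdr column."""
    rows = []
    for i in range(6):
        group = "A" if i < 3 else "B"
        es_a = [-0.5, -0.4, -0.6, 0.1, 0.2, 0.3][i]
        rows.append((f"{group}{i}", "d1", es_a, 0.01, 50))
        rows.append((f"{group}{i}", "d2", 0.05 * (i + 1), 0.5, 50))
    frame = pd.DataFrame(
        rows, columns=["cell_id", "drug_id", "es", "p_value", "n_overlap"]
    )
    frame["fdr"] = frame["p_value"]
    return frame


@pytest.fixture
def small_labels(small_records) -> pd.Series:
    cells = small_records["cell_id"].unique()
    return pd.Series({c: c[0] for c in cells})
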