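"""Independent brute-force oracles used to pin expected values in tests.

Everything here recomputes quantities from first principles (explicit
running sums, enumeration, direct formula evaluation) and stays
independent of the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def running_sum_es(
    scores: np.ndarray, hit_mask: np.ndarray, exponent: float = 1.0
) -> float:
    """Walk the full ranked list step by step and return the signed max deviation."""
    scores = np.asarray(scores, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    length = len(scores)
    k = int(hit_mask.sum())
    assert k >= 1
    weights = np.abs(scores[hit_mask]) ** exponent
    total = weights.sum()
    if total <= 0:
        weights = np.ones(k)
        total = float(k)
    miss_step = 1.0 / (length - k) if length > k else 0.0
    running = np.empty(length)
    value = 0.0
    hit_i = 0
    for i in range(length):
        if hit_mask[i]:
            value += weights[hit_i] / total
            hit_i += 1
        else:
            value -= miss_step
        running[i] = value
    hi = running.max()
    lo = running.min()
    # same tie convention as the library: positive branch wins exact ties
    return float(hi) if hi >= -lo - 1e-9 else float(lo)


def fjd_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Direct evaluation of 1 - sum|sign(x_j) + sign(y_j)| / (2m)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = len(x)
    return 1.0 - float(np.abs(np.sign(x) + np.sign(y)).sum()) / (2.0 * m)


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Textbook BH: q_(i) = min over j >= i of p_(j) * n / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    best = np.inf
    for i in range(n - 1, -1, -1):
        best = min(best, p[order[i]] * n / (i + 1))
        q_sorted[i] = min(best, 1.0)
    out = np.empty(n)
    out[order] = q_sorted
    return out
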