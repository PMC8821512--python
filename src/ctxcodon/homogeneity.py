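"""Resampling test of whether two context matrices share substitution dynamics.

The distance between two row-normalized matrices is the sum of squared
differences over the 12 off-diagonal (substitution) rates. Under the null
that both count matrices are drawn from one set of per-row substitution
probabilities, the two matrices are pooled (element-wise sum), per-row
off-diagonal probabilities are computed from the pool, and each matrix's
per-row off-diagonal counts are redrawn from a multinomial with its
original per-row total. The P value is 1 minus the proportion of resampled
pairs with a lesser distance than the original.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import ContextMatrixSet

_OFF = ~np.eye(4, dtype=bool)


def matrix_distance(pi1: np.ndarray, pi2: np.ndarray) -> float:
    """Sum of squared off-diagonal differences between two stochastic matrices."""
    pi1 = np.asarray(pi1, dtype=float)
    pi2 = np.asarray(pi2, dtype=float)
    if pi1.shape != (4, 4) or pi2.shape != (4, 4):
        raise ValueError("matrices must be 4x4")
    d = (pi1 - pi2)[_OFF]
    return float((d**2).sum())


@dataclass
class HomogeneityResult:
    observed_distance: float
    resampled_distances: np.ndarray
    p_value: float

    @property
    def repetitions(self) -> int:
        return len(self.resampled_distances)

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p_value <= alpha


def _rates(counts: np.ndarray) -> np.ndarray:
    """Row-normalize counts (no pseudocounts); empty rows become identity."""
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1, keepdims=True)
    out = np.where(sums > 0, counts / np.where(sums > 0, sums, 1.0), np.eye(4))
    return out


def _rates_batch(counts: np.ndarray) -> np.ndarray:
    sums = counts.sum(axis=2, keepdims=True)
    eye = np.broadcast_to(np.eye(4), counts.shape)
    return np.where(sums > 0, counts / np.where(sums > 0, sums, 1.0), eye)


def homogeneity_test(
    m1: np.ndarray,
    m2: np.ndarray,
    repetitions: int = 100,
    seed: int | np.random.Generator | None = None,
) -> HomogeneityResult:
    """Distance-plus-resampling test for one matrix pair."""
    m1 = np.asarray(m1, dtype=np.int64)
    m2 = np.asarray(m2, dtype=np.int64)
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    for name, m in (("first", m1), ("second", m2)):
        if m[_OFF].sum() == 0:
            raise ValueError(f"{name} matrix has no off-diagonal substitutions")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    observed = matrix_distance(_rates(m1), _rates(m2))

    pooled = (m1 + m2).astype(float)
    pooled[np.eye(4, dtype=bool)] = 0.0
    row_tot = pooled.sum(axis=1)
    probs = np.where(
        row_tot[:, None] > 0, pooled / np.where(row_tot[:, None] > 0, row_tot[:, None], 1.0), 0.0
    )

    res = np.zeros((2, repetitions, 4, 4))
    for k, m in enumerate((m1, m2)):
        diag = np.diag(np.diag(m)).astype(float)
        res[k] += diag[None, :, :]
        off = m.astype(float).copy()
        off[np.eye(4, dtype=bool)] = 0.0
        for i in range(4):
            total = int(off[i].sum())
            if total == 0 or row_tot[i] == 0:
                continue
            res[k, :, i, :] += rng.multinomial(total, probs[i], size=repetitions)

    r1 = _rates_batch(res[0])
    r2 = _rates_batch(res[1])
    d = (((r1 - r2) * _OFF[None, :, :]) ** 2).sum(axis=(1, 2))
    p_value = 1.0 - float((d < observed).sum()) / repetitions
    return HomogeneityResult(observed, d, p_value)


def all_pairs_homogeneity(
    mset: ContextMatrixSet,
    min_substitutions: int = 50,
    repetitions: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
):
    """Pairwise homogeneity tests over a matrix set.

    Returns ``(table, summary)``: a DataFrame with one row per unordered pair
    of matrices that carry at least ``min_substitutions`` substitutions, and
    a summary dict with the rejection fraction at ``alpha`` (no multiple-test
    correction is applied).
    """
    keys = [k for k in mset.keys() if mset.substitutions(k) >= min_substitutions]
    if len(keys) < 2:
        raise ValueError(
            f"need at least 2 matrices with >= {min_substitutions} substitutions, "
            f"found {len(keys)}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for k1, k2 in itertools.combinations(keys, 2):
        result = homogeneity_test(mset[k1], mset[k2], repetitions, seed=rng)
        rows.append(
            {
                "context1": k1,
                "context2": k2,
                "n_subs1": mset.substitutions(k1),
                "n_subs2": mset.substitutions(k2),
                "distance": result.observed_distance,
                "p_value": result.p_value,
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "n_pairs": len(table),
        "alpha": alpha,
        "min_substitutions": min_substitutions,
        "repetitions": repetitions,
        "rejection_fraction": float((table["p_value"] <= alpha).mean()),
    }
    return table, summary
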