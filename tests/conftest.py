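"""Shared fixtures and independently coded statistical oracles.

The oracles re-derive each statistic from its definition (closed form or
brute-force enumeration) without touching the code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as _scipy_stats

from phoscomplex import simulate
from phoscomplex.config import PipelineConfig


@pytest.fixture
def small_truth() -> simulate.ComplexTruth:
    """Two well-separated planted modules plus one multi-assembly protein."""
    modules = [
        simulate.ModuleTruth("M1", {"A": 1.0, "B": 0.8, "C": 1.2, "X": 1.0},
                             apex_fraction=10.0, fwhm=2.0, phosphosites=["S107"]),
        simulate.ModuleTruth("M2", {"D": 1.0, "E": 1.0, "F": 0.9, "X": 0.7},
                             apex_fraction=40.0, fwhm=2.0, phosphosites=["S367"]),
    ]
    return simulate.ComplexTruth(modules)


@pytest.fixture
def default_config() -> PipelineConfig:
    return PipelineConfig(seed=0)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def welch_p_oracle(a, b) -> float:
    """Two-sided Welch t-test from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * _scipy_stats.t.sf(abs(t), df)


def bh_oracle(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up by direct definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        val = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, val)
        q[idx] = min(running_min, 1.0)
    return q


def hypergeom_upper_oracle(k: int, n_pop: int, n_succ: int, n_draw: int) -> float:
    """P(X >= k) by exact enumeration with binomial coefficients."""
    total = math.comb(n_pop, n_draw)
    acc = 0
    for i in range(k, min(n_succ, n_draw) + 1):
        if n_draw - i > n_pop - n_succ:
            continue
        acc += math.comb(n_succ, i) * math.comb(n_pop - n_succ, n_draw - i)
    return acc / total


def silhouette_oracle(d: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette from the definition: s = (b - a) / max(a, b).

    ``a`` excludes the point itself; singleton clusters score 0.
    """
    labels = np.asarray(labels)
    n = len(labels)
    scores = []
    for i in range(n):
        same = (labels == labels[i])
        n_same = same.sum()
        if n_same == 1:
            scores.append(0.0)
            continue
        a = d[i, same].sum() / (n_same - 1)
        b = min(d[i, labels == other].mean()
                for other in np.unique(labels) if other != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def pca_ratio_oracle(x: np.ndarray) -> np.ndarray:
    """Explained-variance ratios via eigendecomposition of the scatter matrix."""
    x = np.asarray(x, float)
    xc = x - x.mean(axis=0, keepdims=True)
    eigvals = np.linalg.eigvalsh(xc.T @ xc)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    k = min(x.shape[0], x.shape[1])
    eigvals = eigvals[:k]
    return eigvals / eigvals.sum()


def protein_long_table(data: dict[tuple[str, str, int], float]) -> pd.DataFrame:
    """Build a protein long table from {(protein, condition, replicate): value}."""
    rows = [{"protein": p, "condition": c, "replicate": r, "intensity": v}
            for (p, c, r), v in data.items()]
    return pd.DataFrame(rows)
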