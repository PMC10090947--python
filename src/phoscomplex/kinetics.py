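"""Treatment time-course profiles and fuzzy c-means clustering.

Interactor responses to the two phosphatase-inhibitor treatments (vanadate
2/20 min, okadaic acid 60/150 min) are expressed as log2 fold change versus
the untreated condition and grouped by response shape with fuzzy c-means on
z-scored profiles (the soft analogue of k-means: every profile receives a
membership in [0, 1] to each cluster, rows summing to one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import KineticsParams
from .errors import ValidationError

log = logging.getLogger(__name__)


def kinetic_profiles(table: pd.DataFrame, conditions: list[str],
                     untreated: str = "untreated") -> pd.DataFrame:
    """Per-protein log2(mean condition / mean untreated), one column per condition.

    Proteins without observed untreated intensity are excluded with a warning.
    """
    if untreated not in set(table["condition"]):
        raise ValidationError(f"untreated condition {untreated!r} not present")
    rows = {}
    for protein, grp in table.groupby("protein", sort=True):
        ref = grp.loc[grp["condition"] == untreated, "intensity"].dropna()
        if len(ref) == 0 or ref.mean() <= 0:
            log.warning("kinetic_profiles: %s missing in untreated; excluded", protein)
            continue
        profile = []
        for cond in conditions:
            vals = grp.loc[grp["condition"] == cond, "intensity"].dropna()
            profile.append(np.log2(vals.mean() / ref.mean()) if len(vals) else np.nan)
        rows[protein] = profile
    out = pd.DataFrame.from_dict(rows, orient="index", columns=conditions)
    out.index.name = "protein"
    return out


@dataclass
class FuzzyClustering:
    """Result of fuzzy c-means: memberships U (rows sum to 1) and centers."""

    membership: pd.DataFrame          # protein x cluster
    centers: np.ndarray               # cluster x timepoint (z-scored space)
    fuzzifier: float
    objective: float
    objective_trace: list[float] = field(default_factory=list)

    def hard_assignments(self) -> pd.Series:
        return self.membership.idxmax(axis=1)


def zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _fcm_once(x: np.ndarray, c: int, m: float, tol: float, max_iter: int,
              rng: np.random.Generator):
    n = x.shape[0]
    u = rng.dirichlet(np.ones(c), size=n)           # rows sum to 1
    trace: list[float] = []
    centers = np.zeros((c, x.shape[1]))
    for _ in range(max_iter):
        w = u ** m
        centers_new = (w.T @ x) / np.maximum(w.sum(axis=0)[:, None], 1e-300)
        d2 = ((x[:, None, :] - centers_new[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        # exact-hit rows: hard-assign to the coincident center
        hits = d2 <= 1e-299
        if hits.any():
            rows = hits.any(axis=1)
            u_new[rows] = hits[rows] / hits[rows].sum(axis=1, keepdims=True)
        obj = float(((u_new ** m) * d2).sum())
        trace.append(obj)
        shift = float(np.abs(centers_new - centers).max())
        centers, u = centers_new, u_new
        if shift < tol:
            break
    return u, centers, trace


def fuzzy_cmeans(profiles: pd.DataFrame, params: KineticsParams | None = None,
                 seed: int = 0) -> FuzzyClustering:
    """Fuzzy c-means on z-scored profiles with seeded restarts.

    ``params.n_clusters`` (c), ``params.fuzzifier`` (m > 1).  The best of
    ``params.restarts`` random initializations (lowest final objective) is
    returned.  ``c`` larger than the number of profiles is an error; ``c = 1``
    returns all memberships exactly one.
    """
    params = params or KineticsParams()
    params.validate()
    clean = profiles.dropna()
    x = zscore_rows(clean.to_numpy(dtype=float))
    n = x.shape[0]
    c = params.n_clusters
    if c > n:
        raise ValidationError(f"n_clusters={c} exceeds the {n} available profiles")
    names = [f"C{i + 1}" for i in range(c)]
    if c == 1:
        u = pd.DataFrame(np.ones((n, 1)), index=clean.index, columns=names)
        return FuzzyClustering(u, x.mean(axis=0, keepdims=True), params.fuzzifier, 0.0, [0.0])
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(params.restarts):
        u, centers, trace = _fcm_once(x, c, params.fuzzifier, params.tol,
                                      params.max_iter, rng)
        if best is None or trace[-1] < best[2][-1]:
            best = (u, centers, trace)
    u, centers, trace = best
    membership = pd.DataFrame(u, index=clean.index, columns=names)
    return FuzzyClustering(membership, centers, params.fuzzifier, trace[-1], trace)
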