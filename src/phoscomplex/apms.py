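"""AP-MS quantification, normalization, imputation and differential statistics.

Protein abundance is the sum of the top two unique peptide intensities per
run; runs are bait-normalized; missing values are imputed either with the
within-condition replicate median (exactly one missing replicate) or by
left-censored draws from a down-shifted normal; differential statistics are
two-sided t-tests on log2 intensities with Benjamini-Hochberg correction
within each contrast.  Interactors are filtered at a strict SAINT-style
score threshold (score > 0.90 retains).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import ApmsParams
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class DifferentialResult:
    protein: str
    log2fc: float
    p: float
    q: float
    n_condition: int
    n_reference: int


def protein_from_top_peptides(peptide_intensities: Sequence[float], top_n: int = 2) -> float:
    """Sum of the ``top_n`` highest observed peptide intensities for one run.

    Fewer than ``top_n`` observed peptides -> sum of all observed; zero
    observed -> ``NaN`` (missing, never zero).
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    values = np.asarray([v for v in peptide_intensities if v is not None and np.isfinite(v)],
                        dtype=float)
    if values.size == 0:
        return float("nan")
    if np.any(values < 0):
        raise ValidationError("peptide intensities must be non-negative")
    return float(np.sort(values)[::-1][:top_n].sum())


def protein_table(peptides: pd.DataFrame, top_n: int = 2) -> pd.DataFrame:
    """Collapse a peptide long table to a (protein, condition, replicate) table."""
    grouped = peptides.groupby(["protein", "condition", "replicate"], sort=True)["intensity"]
    out = grouped.apply(lambda s: protein_from_top_peptides(s.to_numpy(), top_n))
    return out.rename("intensity").reset_index()


def normalize_to_bait(table: pd.DataFrame, bait: str) -> pd.DataFrame:
    """Divide each run by its bait intensity, rescaled by the mean bait level.

    After normalization the bait has identical intensity in every run
    (coefficient of variation zero).  A run in which the bait is missing is a
    hard error naming the run.
    """
    table = table.copy()
    runs = table[["condition", "replicate"]].drop_duplicates()
    bait_rows = table[table["protein"] == bait].set_index(["condition", "replicate"])
    factors = {}
    for cond, rep in runs.itertuples(index=False):
        try:
            v = float(bait_rows.loc[(cond, rep), "intensity"])
        except KeyError:
            v = float("nan")
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(f"bait {bait!r} missing in run {cond}/{rep}")
        factors[(cond, rep)] = v
    mean_bait = float(np.mean(list(factors.values())))
    scale = table.apply(lambda r: factors[(r["condition"], r["replicate"])], axis=1)
    table["intensity"] = table["intensity"] / scale * mean_bait
    return table


def impute_missing(table: pd.DataFrame, params: ApmsParams | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Impute missing protein intensities; adds a boolean ``imputed`` column.

    Per (protein, condition): exactly one missing replicate -> median of the
    observed replicates.  More missing -> left-censored draws from a normal
    centered at the ``impute_percentile`` quantile of that run's observed
    log2-intensity distribution, with sd equal to the median within-condition
    replicate sd (log2 scale).
    """
    params = params or ApmsParams()
    rng = np.random.default_rng(seed)
    table = table.copy()
    table["imputed"] = False

    conditions = table["condition"].unique()
    for cond in conditions:
        sub = table[table["condition"] == cond]
        if sub["intensity"].isna().all():
            raise ValidationError(f"condition {cond!r} has no observed values at all")

    # per-run quantile of observed log2 intensities (the censoring floor)
    obs = table[table["intensity"].notna() & (table["intensity"] > 0)]
    run_floor = (
        np.log2(obs.set_index(["condition", "replicate"])["intensity"])
        .groupby(level=[0, 1])
        .quantile(params.impute_percentile / 100.0)
    )
    # median within-condition replicate sd on log2 scale
    sds = (
        obs.assign(log2=np.log2(obs["intensity"]))
        .groupby(["protein", "condition"])["log2"]
        .std()
        .dropna()
    )
    sigma = float(sds.median()) if len(sds) else 0.3
    if not np.isfinite(sigma) or sigma <= 0:
        sigma = 0.3

    for (protein, cond), grp in table.groupby(["protein", "condition"], sort=True):
        missing = grp.index[grp["intensity"].isna()]
        if len(missing) == 0:
            continue
        observed = grp["intensity"].dropna()
        if len(missing) <= params.max_single_missing_per_condition and len(observed) > 0:
            value = float(observed.median())
            table.loc[missing, "intensity"] = value
        else:
            for idx in missing:
                rep = table.loc[idx, "replicate"]
                floor = float(run_floor.get((cond, rep), run_floor.median()))
                table.loc[idx, "intensity"] = float(2.0 ** rng.normal(floor, sigma))
        table.loc[missing, "imputed"] = True
    return table


def _welch_p(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
        # degenerate: no within-group variance; identical means are maximally
        # non-significant, different means maximally significant
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def differential(table: pd.DataFrame, condition: str, reference: str,
                 params: ApmsParams | None = None) -> pd.DataFrame:
    """Per-protein two-sided t-test on log2 intensities, BH within the contrast.

    ``log2fc = mean(log2 condition) - mean(log2 reference)``.  Proteins with
    fewer than two replicates in either group are skipped with a warning.
    Welch (unequal variance) by default; ``params.equal_var`` switches to the
    pooled-variance test.
    """
    params = params or ApmsParams()
    rows = []
    for protein, grp in table.groupby("protein", sort=True):
        a = grp.loc[grp["condition"] == condition, "intensity"].dropna().to_numpy(float)
        b = grp.loc[grp["condition"] == reference, "intensity"].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            log.warning("differential: %s skipped (<2 replicates after imputation)", protein)
            continue
        la, lb = np.log2(a), np.log2(b)
        rows.append(DifferentialResult(
            protein=protein,
            log2fc=float(la.mean() - lb.mean()),
            p=_welch_p(la, lb, params.equal_var),
            q=float("nan"),
            n_condition=len(a), n_reference=len(b),
        ))
    if not rows:
        return pd.DataFrame(columns=["protein", "log2fc", "p", "q",
                                     "n_condition", "n_reference"])
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def filter_interactors(scores: pd.DataFrame, saint_threshold: float = 0.90) -> set[str]:
    """Retain candidates with confidence score strictly above the threshold."""
    if scores.empty:
        return set()
    keep = scores.loc[scores["score"] > saint_threshold, "protein"]
    return set(keep)
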