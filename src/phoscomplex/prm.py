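"""Targeted PRM peak-group scoring, quantification and KO-panel summaries.

Peak groups are accepted when their retention time matches the assay library
within 5% of the gradient length *and* the cosine between observed fragment
areas and library relative intensities exceeds 0.75 (both strict rules of the
targeted workflow).  Accepted peptides are quantified as the sum of the top
three fragment areas after discarding fragments with signal-to-noise below 5.
Panels are normalized to a reference peptide set per run (geometric mean) and
summarized as per-entity log2 fold changes versus the parental line plus a
PCA of the combined interactor + phosphopeptide fold-change matrix with the
KO-target rows removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PrmParams
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class PeakGroup:
    """One candidate quantification unit: a peptide in one channel/sample."""

    peptide: str
    channel: str                      # "light" | "heavy"
    rt: float                         # apex, minutes
    fragments: dict[str, float]       # fragment id -> integrated area
    sn: dict[str, float] = field(default_factory=dict)


def peak_groups_from_table(fragments: pd.DataFrame) -> list[PeakGroup]:
    """Group a fragment long table into peak groups per (peptide, channel, sample)."""
    groups = []
    for (pep, channel, sample), grp in fragments.groupby(["peptide", "channel", "sample"],
                                                         sort=True):
        pg = PeakGroup(
            peptide=pep, channel=channel, rt=float(grp["rt"].iloc[0]),
            fragments=dict(zip(grp["fragment"], grp["area"].astype(float))),
            sn=dict(zip(grp["fragment"], grp["sn"].astype(float))),
        )
        pg.sample = sample  # type: ignore[attr-defined]
        groups.append(pg)
    return groups


def dot_product(observed: dict[str, float], library: dict[str, float]) -> float:
    """Normalized dot product (cosine) over the shared fragments.

    Scale-invariant in both arguments; an all-zero observed vector gives 0.
    """
    shared = sorted(set(observed) & set(library))
    if len(shared) < 2:
        raise ValidationError("dot product needs >= 2 shared fragments")
    x = np.array([observed[f] for f in shared], dtype=float)
    y = np.array([library[f] for f in shared], dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def accept_peak_group(pg: PeakGroup, library_entry: dict, gradient_length: float,
                      params: PrmParams | None = None) -> tuple[bool, dict]:
    """Accept iff RT within 5% of the gradient of the library RT and dotp > 0.75.

    Returns ``(accepted, reasons)`` with both criteria reported.
    """
    params = params or PrmParams()
    lib_rt = library_entry.get("library_rt")
    if lib_rt is None or not np.isfinite(lib_rt):
        raise ValidationError(f"library RT missing for peptide {pg.peptide!r}")
    rt_ok = abs(pg.rt - lib_rt) <= params.rt_tolerance_fraction * gradient_length
    dotp = dot_product(pg.fragments, library_entry["rel_intensities"])
    dotp_ok = dotp > params.min_dotp
    reasons = {"rt_ok": bool(rt_ok), "rt_delta": float(abs(pg.rt - lib_rt)),
               "dotp": dotp, "dotp_ok": bool(dotp_ok)}
    return bool(rt_ok and dotp_ok), reasons


def quantify_peptide(pg: PeakGroup, params: PrmParams | None = None) -> tuple[float, bool]:
    """Sum of the top-3 fragment areas after dropping fragments with S/N < 5.

    Returns ``(intensity, low_fragment_flag)``; fewer than 3 surviving
    fragments are summed entirely and flagged; none surviving -> ``NaN``.
    """
    params = params or PrmParams()
    surviving = [area for fid, area in pg.fragments.items()
                 if pg.sn.get(fid, np.inf) >= params.min_sn]
    if not surviving:
        return float("nan"), True
    top = sorted(surviving, reverse=True)[:params.quant_top_fragments]
    return float(sum(top)), len(surviving) < params.quant_top_fragments


def light_heavy_ratio(light: float, heavy: float) -> float:
    """log2(light / heavy); light missing -> missing; heavy must be positive."""
    if heavy is None or not np.isfinite(heavy) or heavy <= 0:
        raise ValidationError("heavy reference intensity must be > 0")
    if light is None or not np.isfinite(light):
        return float("nan")
    return float(np.log2(light / heavy))


def library_index(library: pd.DataFrame) -> dict[str, dict]:
    """Index an assay-library table by peptide."""
    out = {}
    for pep, grp in library.groupby("peptide", sort=True):
        out[pep] = {
            "rel_intensities": dict(zip(grp["fragment"], grp["rel_intensity"].astype(float))),
            "library_rt": float(grp["library_rt"].iloc[0]),
        }
    return out


def quantify_panel(fragments: pd.DataFrame, library: pd.DataFrame,
                   gradient_length: float, params: PrmParams | None = None) -> pd.DataFrame:
    """Accept and quantify every light peak group against the library.

    Returns one row per (peptide, sample) with acceptance flags, dotp, and
    the light intensity plus the light/heavy log2 ratio where a heavy
    reference exists in the same sample.
    """
    params = params or PrmParams()
    lib = library_index(library)
    groups = peak_groups_from_table(fragments)
    heavy = {(g.peptide, g.sample): g for g in groups if g.channel == "heavy"}
    rows = []
    for g in groups:
        if g.channel != "light":
            continue
        if g.peptide not in lib:
            log.warning("quantify_panel: no library entry for %s", g.peptide)
            continue
        accepted, reasons = accept_peak_group(g, lib[g.peptide], gradient_length, params)
        intensity, low_frag = (quantify_peptide(g, params) if accepted
                               else (float("nan"), False))
        ratio = float("nan")
        hg = heavy.get((g.peptide, g.sample))
        if accepted and hg is not None:
            h_int, _ = quantify_peptide(hg, params)
            if np.isfinite(h_int) and h_int > 0:
                ratio = light_heavy_ratio(intensity, h_int)
        rows.append({"peptide": g.peptide, "sample": g.sample, "accepted": accepted,
                     "dotp": reasons["dotp"], "rt_ok": reasons["rt_ok"],
                     "intensity": intensity, "low_fragment": low_frag,
                     "log2_light_heavy": ratio})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# panel normalization and summaries
# ---------------------------------------------------------------------------

def normalize_panel(table: pd.DataFrame, mode: str, reference_ids: list[str],
                    bait_entities: list[str] | None = None,
                    phospho_entities: list[str] | None = None) -> pd.DataFrame:
    """Divide each run by the geometric mean of its reference-set intensities.

    ``table`` is a long (entity, condition, replicate, intensity) table; a
    *run* is a (condition, replicate).  In ``bait_peptides`` mode the
    phosphopeptide entities are additionally divided by the run's bait level
    (geometric mean of the bait entities), separating protein-abundance
    variation from phosphorylation changes.  A missing reference in any run
    is an error naming the run and the reference.
    """
    if mode not in {"bait_peptides", "housekeeping_irt", "tag_peptide"}:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    table = table.copy()
    runs = table[["condition", "replicate"]].drop_duplicates().itertuples(index=False)
    by_run = table.set_index(["condition", "replicate", "entity"])["intensity"]
    factors: dict[tuple, float] = {}
    bait_level: dict[tuple, float] = {}
    for cond, rep in runs:
        vals = []
        for ref in reference_ids:
            try:
                v = float(by_run.loc[(cond, rep, ref)])
            except KeyError:
                v = float("nan")
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"reference {ref!r} missing in run {cond}/{rep}")
            vals.append(v)
        factors[(cond, rep)] = float(np.exp(np.mean(np.log(vals))))
        if mode == "bait_peptides" and bait_entities:
            bv = []
            for ent in bait_entities:
                try:
                    v = float(by_run.loc[(cond, rep, ent)])
                except KeyError:
                    continue
                if np.isfinite(v) and v > 0:
                    bv.append(v)
            if not bv:
                raise ValidationError(f"bait peptides missing in run {cond}/{rep}")
            bait_level[(cond, rep)] = float(np.exp(np.mean(np.log(bv))))
    run_keys = list(zip(table["condition"], table["replicate"]))
    table["intensity"] = table["intensity"] / np.array([factors[k] for k in run_keys])
    if mode == "bait_peptides" and bait_entities and phospho_entities:
        is_phospho = table["entity"].isin(set(phospho_entities)).to_numpy()
        bait_factors = np.array([bait_level[k] / factors[k] for k in run_keys])
        table.loc[is_phospho, "intensity"] = (
            table.loc[is_phospho, "intensity"].to_numpy()
            / bait_factors[is_phospho]
        )
    return table


def pca_variance_ratios(matrix: np.ndarray) -> np.ndarray:
    """Explained-variance ratios of a column-centered matrix via SVD; sums to 1."""
    x = np.asarray(matrix, dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    s = np.linalg.svd(x, compute_uv=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        return np.zeros_like(var)
    return var / total


@dataclass
class PanelSummary:
    fold_changes: pd.DataFrame        # entity x line log2FC + p
    pca_variance: np.ndarray
    pca_scores: pd.DataFrame          # sample (line, replicate) x component


def panel_summary(table: pd.DataFrame, parental: str,
                  ko_targets: dict[str, list[str]] | None = None) -> PanelSummary:
    """Per-entity log2FC and t-test p versus the parental line, plus PCA.

    ``ko_targets`` maps each knockout line to the entities it deletes; those
    entities are removed from the PCA input (their trivial absence would
    dominate the components).  PCA operates on the replicate-level log2
    fold-change matrix (samples x entities), centered, unscaled.
    """
    ko_targets = ko_targets or {}
    lines = [c for c in table["condition"].unique() if c != parental]
    if parental not in set(table["condition"]):
        raise ValidationError(f"parental condition {parental!r} missing")
    wide = table.pivot_table(index="entity", columns=["condition", "replicate"],
                             values="intensity", aggfunc="first")
    ref = wide[parental]
    ref_mean = ref.mean(axis=1)
    fc_rows = []
    for line in lines:
        cur = wide[line]
        for entity in wide.index:
            a = np.log2(cur.loc[entity].dropna().to_numpy(dtype=float))
            b = np.log2(ref.loc[entity].dropna().to_numpy(dtype=float))
            if len(a) < 2 or len(b) < 2:
                continue
            if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
                p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            fc_rows.append({"entity": entity, "line": line,
                            "log2fc": float(a.mean() - b.mean()), "p": p})
    fold_changes = pd.DataFrame(fc_rows)

    removed = {e for ents in ko_targets.values() for e in ents}
    keep = [e for e in wide.index if e not in removed]
    samples, sample_ids = [], []
    for line in lines:
        cur = wide[line]
        for rep in cur.columns:
            vec = np.log2(cur[rep].loc[keep].to_numpy(dtype=float) /
                          ref_mean.loc[keep].to_numpy(dtype=float))
            if np.all(np.isfinite(vec)):
                samples.append(vec)
                sample_ids.append((line, rep))
    x = np.array(samples)
    ratios = pca_variance_ratios(x)
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scores = pd.DataFrame(u * s, index=pd.MultiIndex.from_tuples(
        sample_ids, names=["line", "replicate"]))
    return PanelSummary(fold_changes, ratios, scores)
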