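"""Protein correlation profiling over native-PAGE fractions.

The core of the analysis: 64-fraction migration profiles of interactors and
bait phosphopeptides are normalized (iRT per fraction, bait level for
phosphopeptides), filtered on phosphosite localization, imputed from
neighbouring fractions, max-scaled, smoothed with a Gaussian kernel, split at
detected peaks into single-peak traces, and agglomeratively clustered on a
peak-correlation distance into co-migration *modules*.  Each module carries
its interactor members, the bait phosphosignature that co-migrates with it,
an intensity-weighted apex and a molecular-weight estimate interpolated from
a gel calibration curve.

Fractions are 1-based and ordered from highest to lowest native mass
(gel top to bottom).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .config import ClusterParams, PeakParams
from .errors import ValidationError
from .io import fraction_columns
from .simulate import GAUSS_FWHM_TO_SIGMA

log = logging.getLogger(__name__)


@dataclass
class MigrationProfile:
    """One entity's intensity vector over the native fractions."""

    entity_id: str
    entity_kind: str                  # "protein" | "bait_phosphopeptide"
    intensities: np.ndarray           # length = fraction_count; NaN = missing
    localization: np.ndarray | None = None


@dataclass
class Peak:
    apex_fraction: int                # 1-based
    left: int
    right: int
    height: float                     # smoothed, max-normalized
    fwhm: float


@dataclass
class SplitTrace:
    """The portion of a parent profile belonging to one detected peak."""

    parent: str
    kind: str
    peak_index: int
    peak: Peak
    values: np.ndarray                # zero outside [left, right]

    @property
    def trace_id(self) -> str:
        return f"{self.parent}|{self.peak_index}"


@dataclass
class Module:
    module_id: str
    members: list[str]                # interactor proteins (bait excluded)
    phosphosignature: list[str]       # bait phosphosites co-migrating
    traces: list[SplitTrace]
    apex_fraction: float              # intensity-weighted
    mw_kda: float | None = None
    mw_extrapolated: bool = False


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def impute_neighbors(values: np.ndarray) -> np.ndarray:
    """Fill single missing fractions with the mean of the two flanking values.

    Edge fractions (one neighbour) take the single available neighbour; runs
    of consecutive missing values remain missing.
    """
    v = values.astype(float).copy()
    n = len(v)
    out = v.copy()
    for i in np.flatnonzero(np.isnan(v)):
        left = v[i - 1] if i > 0 else np.nan
        right = v[i + 1] if i < n - 1 else np.nan
        if np.isfinite(left) and np.isfinite(right):
            out[i] = 0.5 * (left + right)
        elif np.isfinite(left):
            out[i] = left
        elif np.isfinite(right):
            out[i] = right
    return out


def preprocess_profiles(profiles: pd.DataFrame, irt: np.ndarray,
                        bait_id: str, params: PeakParams | None = None,
                        localization: pd.DataFrame | None = None,
                        fraction_count: int = 64) -> list[MigrationProfile]:
    """Normalize, filter, impute and max-scale raw migration profiles.

    Order of operations: (1) divide each fraction by that fraction's iRT
    intensity; (2) bait phosphopeptides only: divide by the bait protein
    profile; (3) drop phosphopeptides failing the two-level localization
    filter (score > ``loc_any_fraction`` in at least one fraction; fractions
    below ``loc_per_fraction`` censored); (4) impute interior missing values
    from the two flanking fractions; (5) scale each profile to max 1.
    """
    params = params or PeakParams()
    cols = fraction_columns(fraction_count)
    irt = np.asarray(irt, dtype=float)
    if irt.shape != (fraction_count,):
        raise ValidationError(f"iRT vector must have length {fraction_count}")
    bad = np.flatnonzero(~np.isfinite(irt) | (irt <= 0))
    if len(bad):
        raise ValidationError(f"iRT intensity missing or non-positive in fraction {bad[0] + 1}")

    bait_rows = profiles[(profiles["entity"] == bait_id) & (profiles["kind"] == "protein")]
    if bait_rows.empty:
        raise ValidationError(f"bait profile {bait_id!r} not found")
    bait_profile = bait_rows.iloc[0][cols].to_numpy(dtype=float) / irt

    loc_map: dict[str, np.ndarray] = {}
    if localization is not None:
        for _, row in localization.iterrows():
            loc_map[row["entity"]] = row[cols].to_numpy(dtype=float)

    out: list[MigrationProfile] = []
    for _, row in profiles.iterrows():
        entity, kind = row["entity"], row["kind"]
        v = row[cols].to_numpy(dtype=float) / irt
        loc = loc_map.get(entity)
        if kind == "bait_phosphopeptide":
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.where(bait_profile > 0, v / bait_profile, np.nan)
            if loc is not None:
                if np.nanmax(loc) <= params.loc_any_fraction:
                    log.warning("preprocess: %s dropped (max localization %.2f <= %.2f)",
                                entity, np.nanmax(loc), params.loc_any_fraction)
                    continue
                v = np.where(loc > params.loc_per_fraction, v, np.nan)
        v = impute_neighbors(v)
        if not np.any(np.isfinite(v)) or np.nanmax(v) <= 0:
            log.warning("preprocess: %s dropped (no finite signal)", entity)
            continue
        v = v / np.nanmax(v)
        out.append(MigrationProfile(entity, kind, v, loc))
    return out


# ---------------------------------------------------------------------------
# peak detection and splitting
# ---------------------------------------------------------------------------

def _smooth(values: np.ndarray, width: float) -> np.ndarray:
    filled = np.nan_to_num(values, nan=0.0)
    return gaussian_filter1d(filled, sigma=width * GAUSS_FWHM_TO_SIGMA, mode="constant")


def detect_peaks(profile: MigrationProfile, params: PeakParams | None = None) -> list[Peak]:
    """Local maxima of the Gaussian-smoothed trace above the kind threshold.

    Maxima closer than ``width`` fractions are merged keeping the higher one;
    boundaries sit at the nearest local minima of the smoothed trace (or the
    range ends).
    """
    params = params or PeakParams()
    threshold = (params.min_norm_intensity_phospho
                 if profile.entity_kind == "bait_phosphopeptide"
                 else params.min_norm_intensity_protein)
    s = _smooth(profile.intensities, params.width)
    n = len(s)
    padded = np.concatenate(([-np.inf], s, [-np.inf]))
    maxima = [i for i in range(n)
              if padded[i + 1] > padded[i] and padded[i + 1] >= padded[i + 2]]
    maxima = [i for i in maxima if s[i] >= threshold]
    # merge maxima closer than `width`, keeping the higher
    maxima.sort(key=lambda i: -s[i])
    kept: list[int] = []
    for i in maxima:
        if all(abs(i - j) >= params.width for j in kept):
            kept.append(i)
    kept.sort()

    peaks: list[Peak] = []
    for i in kept:
        left = i
        while left > 0 and s[left - 1] < s[left]:
            left -= 1
        right = i
        while right < n - 1 and s[right + 1] < s[right]:
            right += 1
        half = s[i] / 2.0
        lo = i
        while lo > left and s[lo - 1] >= half:
            lo -= 1
        hi = i
        while hi < right and s[hi + 1] >= half:
            hi += 1
        peaks.append(Peak(apex_fraction=i + 1, left=left + 1, right=right + 1,
                          height=float(s[i]), fwhm=float(max(hi - lo, 1))))
    return peaks


def split_profile(profile: MigrationProfile, peaks: list[Peak],
                  params: PeakParams | None = None) -> list[SplitTrace]:
    """One trace per peak; together the traces partition the parent profile.

    Adjacent peaks are cut at the smoothed-trace minimum between their
    apexes; the valley fraction belongs to the left peak.  Outermost peaks
    extend to the profile ends, so the traces sum exactly to the profile.
    """
    if not peaks:
        return []
    params = params or PeakParams()
    s = _smooth(profile.intensities, params.width)
    values = np.nan_to_num(profile.intensities, nan=0.0)
    n = len(values)
    apexes = [p.apex_fraction - 1 for p in peaks]
    cuts = [0]
    for a, b in zip(apexes[:-1], apexes[1:]):
        valley = a + int(np.argmin(s[a:b + 1]))
        cuts.append(valley + 1)       # valley belongs to the left trace
    cuts.append(n)
    traces = []
    for idx, (peak, start, stop) in enumerate(zip(peaks, cuts[:-1], cuts[1:])):
        tv = np.zeros(n)
        tv[start:stop] = values[start:stop]
        traces.append(SplitTrace(parent=profile.entity_id, kind=profile.entity_kind,
                                 peak_index=idx + 1, peak=peak, values=tv))
    return traces


# ---------------------------------------------------------------------------
# distances and clustering
# ---------------------------------------------------------------------------

def peak_distance(trace_a: SplitTrace | np.ndarray, trace_b: SplitTrace | np.ndarray) -> float:
    """1 - Pearson correlation over the union of the two peak supports.

    Disjoint supports -> 2 (maximally dissimilar); a constant trace on the
    union -> 1 by convention.
    """
    a = trace_a.values if isinstance(trace_a, SplitTrace) else np.asarray(trace_a, float)
    b = trace_b.values if isinstance(trace_b, SplitTrace) else np.asarray(trace_b, float)
    sup_a, sup_b = a > 0, b > 0
    if not np.any(sup_a & sup_b):
        return 2.0
    union = sup_a | sup_b
    x, y = a[union], b[union]
    if np.std(x) == 0 or np.std(y) == 0:
        return 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def distance_matrix(traces: list[SplitTrace]) -> np.ndarray:
    n = len(traces)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = peak_distance(traces[i], traces[j])
    return d


def mean_silhouette(distances: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient on a precomputed distance matrix."""
    return float(silhouette_score(distances, labels, metric="precomputed"))


@dataclass
class ClusteringResult:
    traces: list[SplitTrace]
    labels: np.ndarray
    chosen_k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)


def cluster_modules(traces: list[SplitTrace], bait_id: str,
                    params: ClusterParams | None = None) -> ClusteringResult:
    """Average-linkage clustering on the peak-correlation distance matrix.

    The bait's own traces are excluded (the purified protein migrates in
    every module).  k is chosen in [k_min, k_max] maximizing the mean
    silhouette on the same distance matrix (ties -> smaller k).
    """
    params = params or ClusterParams()
    traces = [t for t in traces if t.parent != bait_id]
    n = len(traces)
    if n < 2:
        raise ValidationError("need at least 2 non-bait traces to cluster")
    d = distance_matrix(traces)
    if np.allclose(d, 0):
        return ClusteringResult(traces, np.ones(n, dtype=int), 1, {})
    z = linkage(squareform(d, checks=False), method=params.linkage)
    k_max = params.k_max
    if k_max > n - 1:
        log.warning("cluster_modules: k_max=%d clamped to %d", k_max, n - 1)
        k_max = n - 1
    k_min = max(params.k_min, 2)
    feature = np.array([t.values for t in traces])
    scores: dict[int, float] = {}
    best_k, best_labels = None, None
    for k in range(k_min, k_max + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        if params.silhouette_metric == "euclidean":
            score = float(silhouette_score(feature, labels, metric="euclidean"))
        else:
            score = mean_silhouette(d, labels)
        scores[k] = score
        if best_k is None or score > scores[best_k]:
            best_k, best_labels = k, labels
    if best_k is None:
        return ClusteringResult(traces, np.ones(n, dtype=int), 1, scores)
    return ClusteringResult(traces, best_labels, best_k, scores)


# ---------------------------------------------------------------------------
# module assembly and molecular weight
# ---------------------------------------------------------------------------

def estimate_mw(apex_fraction: float, calibration: list[tuple[float, float]]) -> float:
    """Molecular weight (kDa) by linear interpolation of log10(kDa) vs fraction.

    The calibration must have >= 2 points with kDa strictly decreasing as the
    fraction index increases (smaller assemblies migrate further).  Apexes
    outside the calibrated range are extrapolated from the nearest segment
    and flagged with a warning.
    """
    if len(calibration) < 2:
        raise ValidationError("calibration needs at least 2 points")
    pts = sorted(calibration)
    fr = np.array([p[0] for p in pts], dtype=float)
    kda = np.array([p[1] for p in pts], dtype=float)
    if np.any(np.diff(kda) >= 0):
        raise ValidationError("calibration kDa must be strictly decreasing with fraction")
    logk = np.log10(kda)
    if apex_fraction < fr[0] or apex_fraction > fr[-1]:
        warnings.warn(f"apex {apex_fraction} outside calibrated range; extrapolating",
                      stacklevel=2)
        if apex_fraction < fr[0]:
            slope = (logk[1] - logk[0]) / (fr[1] - fr[0])
            return float(10 ** (logk[0] + slope * (apex_fraction - fr[0])))
        slope = (logk[-1] - logk[-2]) / (fr[-1] - fr[-2])
        return float(10 ** (logk[-1] + slope * (apex_fraction - fr[-1])))
    return float(10 ** np.interp(apex_fraction, fr, logk))


def assemble_modules(result: ClusteringResult,
                     calibration: list[tuple[float, float]] | None = None) -> list[Module]:
    """Collect clusters into modules sorted by apex (high native mass first)."""
    modules = []
    for label in sorted(set(result.labels)):
        traces = [t for t, l in zip(result.traces, result.labels) if l == label]
        members = sorted({t.parent for t in traces if t.kind == "protein"})
        sig = sorted({t.parent for t in traces if t.kind == "bait_phosphopeptide"})
        weights = np.array([t.values.sum() for t in traces])
        apexes = np.array([t.peak.apex_fraction for t in traces], dtype=float)
        apex = float((apexes * weights).sum() / weights.sum()) if weights.sum() > 0 \
            else float(apexes.mean())
        mw, extrapolated = None, False
        if calibration is not None:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                mw = estimate_mw(apex, calibration)
            extrapolated = len(caught) > 0
        modules.append(Module("", members, sig, traces, apex, mw, extrapolated))
    modules.sort(key=lambda m: m.apex_fraction)   # low fraction = high mass
    for i, m in enumerate(modules, start=1):
        m.module_id = f"M{i}"
    return modules


def module_report(modules: list[Module]) -> pd.DataFrame:
    """Long module report: one row per (module, member entity)."""
    rows = []
    for m in modules:
        sig = ";".join(m.phosphosignature)
        for t in m.traces:
            rows.append({
                "module": m.module_id, "member": t.parent, "kind": t.kind,
                "trace": t.trace_id, "trace_apex": t.peak.apex_fraction,
                "module_apex": m.apex_fraction, "mw_kda": m.mw_kda,
                "mw_extrapolated": m.mw_extrapolated, "phosphosignature": sig,
            })
    return pd.DataFrame(rows)
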