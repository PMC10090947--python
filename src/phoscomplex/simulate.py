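"""Ground-truth-labeled synthetic data for every pipeline stage.

Three generators emulate the three experimental layers the pipeline consumes:

* :func:`simulate_bnpage` — native-PAGE migration profiles over 64 gel
  fractions.  Each planted module contributes a Gaussian co-migration peak
  (shared apex, sigma = FWHM / 2.355) to its members; multi-assembly proteins
  belong to several modules and therefore show several peaks.  Bait
  phosphopeptides attached to a module co-migrate with it and carry simulated
  per-fraction localization scores.
* :func:`simulate_apms` — replicate AP-MS peptide tables with planted
  per-condition log2 fold changes, log-normal intensity noise, missingness,
  and SAINT-style confidence scores (true interactors >= 0.95, background < 0.5).
* :func:`simulate_prm` — targeted fragment traces (light/heavy channels) with
  library-consistent relative intensities, retention-time jitter, and decoy
  peak groups (RT-shifted or ratio-shuffled).

All generators are pure functions of (parameters, seed) and emit truth labels
alongside the data; no analysis stage may read the truth — only tests do.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import fraction_columns

GAUSS_FWHM_TO_SIGMA = 1.0 / 2.355


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class ModuleTruth:
    """One planted co-migration module."""

    module_id: str
    members: dict[str, float]          # protein -> stoichiometry weight (> 0)
    apex_fraction: float               # in [1, fraction_count]
    fwhm: float                        # fractions
    phosphosites: list[str] = field(default_factory=list)


@dataclass
class ComplexTruth:
    """Planted module structure for a BN-PAGE simulation."""

    modules: list[ModuleTruth]
    fraction_count: int = 64
    bait_id: str = "BAIT"

    def validate(self) -> None:
        if not self.modules:
            raise ValidationError("truth must contain at least one module")
        for m in self.modules:
            if not m.members:
                raise ValidationError(f"module {m.module_id} has no members")
            if not 1 <= m.apex_fraction <= self.fraction_count:
                raise ValidationError(
                    f"module {m.module_id}: apex {m.apex_fraction} outside "
                    f"[1, {self.fraction_count}]"
                )
            if m.fwhm <= 0:
                raise ValidationError(f"module {m.module_id}: fwhm must be > 0")
            if any(w <= 0 for w in m.members.values()):
                raise ValidationError(f"module {m.module_id}: weights must be > 0")


@dataclass
class ApmsDesign:
    """Design of a synthetic AP-MS experiment."""

    conditions: list[str]
    replicates: int = 3
    reference: str = "untreated"
    true_interactors: list[str] = field(default_factory=list)
    background: list[str] = field(default_factory=list)
    #: planted log2FC vs reference: condition -> {protein -> log2FC}
    log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    missingness: float = 0.0
    noise_sd: float = 0.2              # replicate sd on the log2 scale
    bait_id: str = "BAIT"

    def validate(self) -> None:
        if self.reference not in self.conditions:
            raise ValidationError("reference condition must be listed in conditions")
        if self.replicates < 2:
            raise ValidationError("replicates must be >= 2")
        if not 0.0 <= self.missingness < 1.0:
            raise ValidationError("missingness must lie in [0, 1)")
        for cond, fcs in self.log2fc.items():
            if cond not in self.conditions:
                raise ValidationError(f"log2FC given for unknown condition {cond!r}")
            if any(not np.isfinite(v) for v in fcs.values()):
                raise ValidationError("planted log2FC must be finite")


@dataclass
class PrmAssay:
    """Targeted assay: library fragment patterns and chromatography settings."""

    peptides: list[str]
    n_fragments: int = 6
    gradient_length: float = 90.0      # minutes
    heavy_spike: float = 1000.0
    noise_sd: float = 0.1              # multiplicative log-normal sigma
    rt_jitter_sd: float = 0.9          # minutes (1% of a 90-min gradient)
    sn_true: float = 50.0
    decay: float = 0.45                # geometric decay of library fragment pattern

    def validate(self) -> None:
        if self.n_fragments < 4:
            raise ValidationError("assay needs >= 4 fragments per peptide")
        if self.gradient_length <= 0:
            raise ValidationError("gradient_length must be > 0")
        if not 0 < self.decay < 1:
            raise ValidationError("decay must lie in (0, 1)")


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def default_complex_truth(n_modules: int = 9, fraction_count: int = 64,
                          fwhm: float = 2.0, seed: int = 0,
                          bait_id: str = "BAIT") -> ComplexTruth:
    """A 9-module bait interactome with 3-8 members per module.

    Apexes are evenly placed so neighbours are >= 2 x FWHM apart; roughly a
    fifth of the proteins are multi-assembly (members of two modules), and
    each module carries 0-2 attached bait phosphosites.
    """
    rng = np.random.default_rng(seed)
    lo, hi = 1 + 2 * fwhm, fraction_count - 2 * fwhm
    if n_modules > 1 and (hi - lo) / (n_modules - 1) < 2 * fwhm:
        raise ValidationError("too many modules for the requested apex spacing")
    apexes = np.linspace(lo, hi, n_modules)
    modules: list[ModuleTruth] = []
    protein_counter = itertools.count(1)
    site_counter = itertools.count(1)
    for i, apex in enumerate(apexes):
        size = int(rng.integers(3, 9))
        members = {
            f"P{next(protein_counter):03d}": float(rng.lognormal(0.0, 0.3))
            for _ in range(size)
        }
        n_sites = int(rng.integers(0, 3))
        sites = [f"S{100 + next(site_counter) * 7}" for _ in range(n_sites)]
        modules.append(ModuleTruth(f"M{i + 1}", members, float(apex), fwhm, sites))
    # multi-assembly proteins: move a copy of one member of each even module
    # into the following module
    for i in range(0, n_modules - 1, 2):
        donor = next(iter(modules[i].members))
        modules[i + 1].members[donor] = float(rng.lognormal(0.0, 0.3))
    truth = ComplexTruth(modules, fraction_count, bait_id)
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# BN-PAGE migration profiles
# ---------------------------------------------------------------------------

def _gaussian(fractions: np.ndarray, apex: float, fwhm: float) -> np.ndarray:
    sigma = fwhm * GAUSS_FWHM_TO_SIGMA
    return np.exp(-0.5 * ((fractions - apex) / sigma) ** 2)


def simulate_bnpage(truth: ComplexTruth, noise_sd: float = 0.2,
                    dropout_rate: float = 0.05, seed: int = 0):
    """Simulate migration profiles for every member protein and phosphosite.

    Returns ``(profiles, localization, labels)``: a wide profile matrix
    (columns ``entity``, ``kind``, ``f1..fN``), a localization-score matrix
    for the phosphopeptide rows, and a truth-label table mapping each
    (entity, module) contribution to its planted apex.

    Each protein profile is the weighted sum of Gaussians over the modules it
    belongs to, times multiplicative log-normal noise; ``dropout_rate``
    replaces individual fraction values with missing.  The bait protein is
    present in every module (it is the purified protein), mirroring a bait
    detected across all fractions.
    """
    truth.validate()
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValidationError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    frac = np.arange(1, truth.fraction_count + 1, dtype=float)

    protein_modules: dict[str, list[ModuleTruth]] = {}
    site_modules: dict[str, list[ModuleTruth]] = {}
    for m in truth.modules:
        for p in m.members:
            protein_modules.setdefault(p, []).append(m)
        for s in m.phosphosites:
            site_modules.setdefault(s, []).append(m)

    rows, loc_rows, labels = [], [], []

    def noisy(signal: np.ndarray) -> np.ndarray:
        if noise_sd > 0:
            signal = signal * rng.lognormal(0.0, noise_sd, size=signal.shape)
        if dropout_rate > 0:
            signal = signal.copy()
            signal[rng.random(signal.shape) < dropout_rate] = np.nan
        return signal

    # bait: sum over every module so it appears in all fractions with signal
    bait = sum(_gaussian(frac, m.apex_fraction, m.fwhm) for m in truth.modules)
    rows.append((truth.bait_id, "protein", noisy(np.asarray(bait, dtype=float))))

    for protein, mods in sorted(protein_modules.items()):
        signal = np.zeros_like(frac)
        for m in mods:
            signal += m.members[protein] * _gaussian(frac, m.apex_fraction, m.fwhm)
            labels.append({"entity": protein, "kind": "protein",
                           "module_id": m.module_id, "apex": m.apex_fraction})
        rows.append((protein, "protein", noisy(signal)))

    for site, mods in sorted(site_modules.items()):
        signal = np.zeros_like(frac)
        support = np.zeros_like(frac, dtype=bool)
        for m in mods:
            g = _gaussian(frac, m.apex_fraction, m.fwhm)
            signal += g
            support |= g > 0.05
            labels.append({"entity": site, "kind": "bait_phosphopeptide",
                           "module_id": m.module_id, "apex": m.apex_fraction})
        # phosphopeptide intensity also scales with the bait level at each
        # fraction (it is a bait peptide); bait normalization undoes this
        signal = signal * np.maximum(bait, 1e-9) / np.max(bait)
        rows.append((site, "bait_phosphopeptide", noisy(signal)))
        loc = np.where(support, rng.uniform(0.80, 1.0, frac.shape),
                       rng.uniform(0.50, 1.0, frac.shape))
        loc_rows.append((site, loc))

    cols = fraction_columns(truth.fraction_count)
    profiles = pd.DataFrame(
        [dict(entity=e, kind=k, **dict(zip(cols, v))) for e, k, v in rows]
    )
    localization = pd.DataFrame(
        [dict(entity=e, **dict(zip(cols, v))) for e, v in loc_rows]
    )
    return profiles, localization, pd.DataFrame(labels)


# ---------------------------------------------------------------------------
# AP-MS replicate tables
# ---------------------------------------------------------------------------

def simulate_apms(design: ApmsDesign, seed: int = 0):
    """Simulate a replicate AP-MS peptide table plus a confidence-score table.

    Returns ``(peptides, scores, truth)``.  Per protein, 2-5 peptides with
    log-normal intensities; condition means are offset by the planted log2FC;
    the bait is present at high intensity in every run.  True interactors get
    scores in [0.95, 1], background in [0, 0.5).
    """
    design.validate()
    rng = np.random.default_rng(seed)
    proteins = [design.bait_id] + list(design.true_interactors) + list(design.background)
    records, score_rows, truth_rows = [], [], []
    for protein in proteins:
        is_bait = protein == design.bait_id
        n_pep = 4 if is_bait else int(rng.integers(2, 6))
        base = 24.0 if is_bait else float(rng.normal(20.0, 1.5))
        pep_offsets = rng.normal(0.0, 0.8, n_pep)
        for cond in design.conditions:
            fc = 0.0 if is_bait else design.log2fc.get(cond, {}).get(protein, 0.0)
            for rep in range(1, design.replicates + 1):
                for j in range(n_pep):
                    log2_val = base + pep_offsets[j] + fc + rng.normal(0.0, design.noise_sd)
                    value: float | None = float(2.0 ** log2_val)
                    if (not is_bait and design.missingness > 0
                            and rng.random() < design.missingness):
                        value = np.nan
                    records.append({
                        "protein": protein, "peptide": f"{protein}_pep{j + 1}",
                        "condition": cond, "replicate": rep, "intensity": value,
                    })
        if not is_bait:
            lo, hi = ((0.95, 1.0) if protein in design.true_interactors else (0.0, 0.5))
            score_rows.append({"protein": protein, "score": float(rng.uniform(lo, hi))})
            for cond in design.conditions:
                truth_rows.append({
                    "protein": protein, "condition": cond,
                    "log2fc": design.log2fc.get(cond, {}).get(protein, 0.0),
                    "is_interactor": protein in design.true_interactors,
                })
    return (pd.DataFrame(records), pd.DataFrame(score_rows), pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# PRM fragment traces
# ---------------------------------------------------------------------------

def _library_pattern(assay: PrmAssay, rng: np.random.Generator) -> np.ndarray:
    """Geometrically decaying relative fragment intensities, max-normalized."""
    jitter = rng.uniform(0.8, 1.2, assay.n_fragments)
    pattern = assay.decay ** np.arange(assay.n_fragments) * jitter
    return pattern / pattern.max()


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def simulate_prm(assay: PrmAssay, true_abundances: dict[str, float], seed: int = 0,
                 decoys_per_peptide: int = 1):
    """Simulate PRM fragment traces plus the matching assay library.

    Returns ``(fragments, library, truth)``.  For each peptide one *true*
    light peak group (library-consistent ratios, RT within jitter of the
    library RT) and a heavy reference at the spike level are emitted, plus
    ``decoys_per_peptide`` decoy light peak groups which are either RT-shifted
    by more than 5% of the gradient or have deranged fragment ratios.
    """
    assay.validate()
    rng = np.random.default_rng(seed)
    frag_ids = [f"y{i + 3}" for i in range(assay.n_fragments)]
    lib_rows, frag_rows, truth_rows = [], [], []
    for pep in assay.peptides:
        pattern = _library_pattern(assay, rng)
        lib_rt = float(rng.uniform(0.1, 0.9) * assay.gradient_length)
        for fid, rel in zip(frag_ids, pattern):
            lib_rows.append({"peptide": pep, "fragment": fid,
                             "rel_intensity": float(rel), "library_rt": lib_rt})
        abundance = float(true_abundances.get(pep, 100.0))
        noise = rng.lognormal(0.0, assay.noise_sd, assay.n_fragments)
        rt = lib_rt + float(rng.normal(0.0, assay.rt_jitter_sd))
        for fid, rel, nz in zip(frag_ids, pattern, noise):
            frag_rows.append({"peptide": pep, "fragment": fid, "channel": "light",
                              "sample": "true", "rt": rt,
                              "area": abundance * rel * nz,
                              "sn": assay.sn_true * rel * nz})
        heavy_noise = rng.lognormal(0.0, assay.noise_sd, assay.n_fragments)
        for fid, rel, nz in zip(frag_ids, pattern, heavy_noise):
            frag_rows.append({"peptide": pep, "fragment": fid, "channel": "heavy",
                              "sample": "true", "rt": rt,
                              "area": assay.heavy_spike * rel * nz,
                              "sn": assay.sn_true * rel * nz})
        truth_rows.append({"peptide": pep, "sample": "true", "is_decoy": False,
                           "abundance": abundance})
        for d in range(decoys_per_peptide):
            shuffled = (d + int(rng.integers(0, 2))) % 2 == 0
            if shuffled:
                decoy_pattern = pattern[_derangement(assay.n_fragments, rng)]
                decoy_rt = rt
            else:
                decoy_pattern = pattern
                offset = (float(rng.uniform(0.07, 0.25)) * assay.gradient_length
                          * (1 if rng.random() < 0.5 else -1))
                decoy_rt = lib_rt + offset
            dnoise = rng.lognormal(0.0, assay.noise_sd, assay.n_fragments)
            for fid, rel, nz in zip(frag_ids, decoy_pattern, dnoise):
                frag_rows.append({"peptide": pep, "fragment": fid, "channel": "light",
                                  "sample": f"decoy{d + 1}", "rt": decoy_rt,
                                  "area": abundance * rel * nz,
                                  "sn": assay.sn_true * rel * nz})
            truth_rows.append({"peptide": pep, "sample": f"decoy{d + 1}",
                               "is_decoy": True,
                               "decoy_kind": "shuffled" if shuffled else "rt_shift",
                               "abundance": abundance})
    return (pd.DataFrame(frag_rows), pd.DataFrame(lib_rows), pd.DataFrame(truth_rows))
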