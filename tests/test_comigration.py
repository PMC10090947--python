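"""Migration-profile preprocessing, peak detection/splitting, module clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phoscomplex import comigration, simulate
from phoscomplex.comigration import (MigrationProfile, Peak, SplitTrace,
                                     assemble_modules, cluster_modules,
                                     detect_peaks, estimate_mw, impute_neighbors,
                                     peak_distance, preprocess_profiles,
                                     split_profile)
from phoscomplex.config import ClusterParams, PeakParams
from phoscomplex.errors import ValidationError
from phoscomplex.io import fraction_columns

COLS = fraction_columns(64)


def _gauss(apex, fwhm=2.0, n=64, height=1.0):
    f = np.arange(1, n + 1, dtype=float)
    return height * np.exp(-0.5 * ((f - apex) / (fwhm / 2.355)) ** 2)


def _wide(entities: dict[str, np.ndarray], kind="protein") -> pd.DataFrame:
    return pd.DataFrame([dict(entity=e, kind=kind, **dict(zip(COLS, v)))
                         for e, v in entities.items()])


class TestPreprocess:
    def test_constant_irt_only_rescales_argmax_preserved(self):
        v = _gauss(30)
        profiles = _wide({"BAIT": v, "A": 2.0 * v})
        out = preprocess_profiles(profiles, np.full(64, 7.0), "BAIT")
        a = next(p for p in out if p.entity_id == "A")
        assert np.argmax(a.intensities) + 1 == 30
        assert np.nanmax(a.intensities) == pytest.approx(1.0)

    def test_neighbor_imputation_averages_flanking_fractions(self):
        assert impute_neighbors(np.array([2.0, np.nan, 4.0]))[1] == 3.0
        # edge fraction takes the single available neighbour
        assert impute_neighbors(np.array([np.nan, 4.0, 6.0]))[0] == 4.0

    def test_two_level_localization_filter(self):
        v = _gauss(30)
        loc_pass = np.full(64, 0.6)
        loc_pass[29] = 0.85
        loc_fail = np.full(64, 0.7)
        profiles = _wide({"BAIT": v}, "protein")
        phos = _wide({"pS1": v, "pS2": v}, "bait_phosphopeptide")
        profiles = pd.concat([profiles, phos], ignore_index=True)
        localization = pd.DataFrame([
            dict(entity="pS1", **dict(zip(COLS, loc_pass))),
            dict(entity="pS2", **dict(zip(COLS, loc_fail))),
        ])
        out = preprocess_profiles(profiles, np.ones(64), "BAIT",
                                  localization=localization)
        kept = {p.entity_id for p in out if p.entity_kind == "bait_phosphopeptide"}
        assert kept == {"pS1"}

    def test_zero_irt_names_the_fraction(self):
        irt = np.ones(64)
        irt[4] = 0.0
        with pytest.raises(ValidationError, match="fraction 5"):
            preprocess_profiles(_wide({"BAIT": _gauss(30)}), irt, "BAIT")

    def test_preprocessing_preserves_argmax_through_imputation_and_scaling(self):
        rng = np.random.default_rng(0)
        v = _gauss(22) * 5.0
        v[10] = np.nan
        profiles = _wide({"BAIT": _gauss(22), "A": v})
        irt = rng.uniform(0.5, 2.0)  # constant scalar iRT per fraction
        out = preprocess_profiles(profiles, np.full(64, irt), "BAIT")
        a = next(p for p in out if p.entity_id == "A")
        assert np.nanargmax(a.intensities) + 1 == 22


class TestDetectAndSplit:
    def test_single_planted_gaussian_detected_at_apex(self):
        p = MigrationProfile("A", "protein", _gauss(30))
        peaks = detect_peaks(p)
        assert len(peaks) == 1
        assert abs(peaks[0].apex_fraction - 30) <= 1

    def test_two_planted_gaussians_detected_at_both_apexes(self):
        p = MigrationProfile("A", "protein", _gauss(10) + _gauss(40, height=0.8))
        peaks = detect_peaks(p)
        assert len(peaks) == 2
        assert abs(peaks[0].apex_fraction - 10) <= 1
        assert abs(peaks[1].apex_fraction - 40) <= 1

    def test_flat_low_profile_has_no_peaks(self):
        p = MigrationProfile("A", "protein", np.full(64, 0.1))
        assert detect_peaks(p) == []

    def test_phospho_threshold_is_higher_than_protein_threshold(self):
        # broad peak: smoothed height ~0.24, between the 0.2 and 0.3 gates
        v = _gauss(30, fwhm=6.0, height=0.25)
        assert len(detect_peaks(MigrationProfile("A", "protein", v))) == 1
        assert detect_peaks(MigrationProfile("pS", "bait_phosphopeptide", v)) == []

    def test_single_peak_trace_is_identical_to_profile(self):
        p = MigrationProfile("A", "protein", _gauss(30))
        traces = split_profile(p, detect_peaks(p))
        assert len(traces) == 1
        assert np.array_equal(traces[0].values, p.intensities)

    def test_split_traces_partition_the_profile_exactly(self):
        v = _gauss(10) + _gauss(40, height=0.8) + 0.01
        p = MigrationProfile("A", "protein", v)
        traces = split_profile(p, detect_peaks(p))
        assert len(traces) == 2
        assert np.array_equal(sum(t.values for t in traces), v)

    def test_valley_fraction_belongs_to_the_left_trace(self):
        # symmetric overlapping peaks -> unique valley at fraction 25 (index 24)
        v = _gauss(15, fwhm=8.0) + _gauss(35, fwhm=8.0)
        p = MigrationProfile("A", "protein", v)
        traces = split_profile(p, detect_peaks(p))
        assert len(traces) == 2
        left = traces[0].values
        assert left[24] == v[24]
        assert np.all(left[25:] == 0.0)


class TestPeakDistance:
    def test_identical_traces_have_distance_zero(self):
        t = SplitTrace("A", "protein", 1, Peak(30, 20, 40, 1.0, 2.0), _gauss(30))
        assert peak_distance(t, t) == pytest.approx(0.0, abs=1e-12)

    def test_anti_correlated_traces_have_distance_two(self):
        a = np.zeros(64)
        a[10:20] = np.linspace(1.0, 2.0, 10)
        b = np.zeros(64)
        b[10:20] = np.linspace(2.0, 1.0, 10)
        assert peak_distance(a, b) == pytest.approx(2.0, abs=1e-12)

    def test_disjoint_supports_are_maximally_dissimilar(self):
        a = np.zeros(64)
        a[5:10] = 1.0
        b = np.zeros(64)
        b[40:45] = 1.0
        assert peak_distance(a, b) == 2.0

    def test_constant_trace_on_union_gives_distance_one(self):
        a = np.zeros(64)
        a[10:20] = 1.0
        b = np.zeros(64)
        b[10:20] = np.linspace(1, 2, 10)
        assert peak_distance(a, b) == 1.0

    def test_shifted_gaussians_match_direct_correlation_oracle(self):
        a, b = _gauss(30), _gauss(32)
        union = (a > 0) | (b > 0)
        r = np.corrcoef(a[union], b[union])[0, 1]
        assert peak_distance(a, b) == pytest.approx(1.0 - r, abs=1e-12)


class TestClusterModules:
    def _planted_traces(self, seed=0, noise=0.05):
        rng = np.random.default_rng(seed)
        traces = []
        for apex, names in ((10, "ABCDE"), (40, "FGHIJ")):
            for name in names:
                v = _gauss(apex) * rng.lognormal(0, noise, 64)
                p = MigrationProfile(name, "protein", v / v.max())
                traces.extend(split_profile(p, detect_peaks(p)))
        return traces

    def test_two_planted_complexes_recovered_with_k_two(self):
        traces = self._planted_traces()
        res = cluster_modules(traces, "BAIT", ClusterParams(k_min=2, k_max=6))
        assert res.chosen_k == 2
        truth = [0 if t.peak.apex_fraction < 25 else 1 for t in res.traces]
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_identical_traces_collapse_to_single_degenerate_cluster(self):
        v = _gauss(30)
        traces = []
        for name in "ABC":
            p = MigrationProfile(name, "protein", v.copy())
            traces.extend(split_profile(p, detect_peaks(p)))
        res = cluster_modules(traces, "BAIT")
        assert res.chosen_k == 1
        assert len(set(res.labels)) == 1

    def test_bait_traces_are_excluded_from_all_modules(self):
        traces = self._planted_traces()
        bait_profile = MigrationProfile("BAIT", "protein", _gauss(10) + _gauss(40))
        traces.extend(split_profile(bait_profile, detect_peaks(bait_profile)))
        res = cluster_modules(traces, "BAIT", ClusterParams(k_min=2, k_max=6))
        modules = assemble_modules(res)
        assert all("BAIT" not in m.members for m in modules)
        assert all(t.parent != "BAIT" for m in modules for t in m.traces)


class TestAssembleAndMw:
    CAL = [(10, 1048.0), (20, 480.0), (30, 242.0), (40, 146.0), (50, 66.0)]

    def test_module_collects_members_and_phosphosignature(self):
        traces = []
        for name, kind in (("P1", "protein"), ("P2", "protein"),
                           ("S367", "bait_phosphopeptide")):
            p = MigrationProfile(name, kind, _gauss(20))
            traces.extend(split_profile(p, detect_peaks(p)))
        res = cluster_modules(traces, "BAIT")
        modules = assemble_modules(res, self.CAL)
        assert len(modules) == 1
        assert modules[0].members == ["P1", "P2"]
        assert modules[0].phosphosignature == ["S367"]
        assert modules[0].mw_kda == pytest.approx(480.0, rel=0.05)

    def test_phosphosignature_may_be_empty(self):
        traces = []
        for name in ("P1", "P2"):
            p = MigrationProfile(name, "protein", _gauss(20))
            traces.extend(split_profile(p, detect_peaks(p)))
        modules = assemble_modules(cluster_modules(traces, "BAIT"))
        assert modules[0].phosphosignature == []

    def test_multi_assembly_protein_appears_in_two_modules(self):
        traces = []
        for name, apexes in (("A", (10,)), ("B", (10,)), ("X", (10, 40)),
                             ("C", (40,)), ("D", (40,))):
            v = sum(_gauss(a) for a in apexes)
            p = MigrationProfile(name, "protein", v / v.max())
            traces.extend(split_profile(p, detect_peaks(p)))
        res = cluster_modules(traces, "BAIT", ClusterParams(k_min=2, k_max=4))
        modules = assemble_modules(res)
        in_modules = [m.module_id for m in modules if "X" in m.members]
        assert len(in_modules) == 2

    def test_mw_at_calibration_point_is_exact(self):
        assert estimate_mw(10, self.CAL) == pytest.approx(1048.0)

    def test_mw_midway_interpolates_in_log_space(self):
        cal = [(10, 1000.0), (20, 100.0)]
        assert estimate_mw(15, cal) == pytest.approx(10 ** 2.5, rel=1e-9)

    def test_increasing_calibration_is_rejected(self):
        with pytest.raises(ValidationError, match="decreasing"):
            estimate_mw(15, [(10, 100.0), (20, 1000.0)])

    def test_mw_is_monotone_decreasing_in_apex(self):
        values = [estimate_mw(f, self.CAL) for f in np.linspace(10, 50, 30)]
        assert np.all(np.diff(values) < 0)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="extrapolating"):
            estimate_mw(60, self.CAL)


def test_stoichiometry_preserved_between_fractionated_and_total_intensity():
    """Per-protein intensity summed over fractions tracks the planted
    (unfractionated) stoichiometry weights, r > 0.9 at default noise."""
    truth = simulate.default_complex_truth(seed=11)
    profiles, _, _ = simulate.simulate_bnpage(truth, seed=11)
    totals = {}
    for _, row in profiles.iterrows():
        if row["kind"] != "protein" or row["entity"] == "BAIT":
            continue
        # dropped fractions are neighbour-imputed before summing, as in the
        # pipeline's preprocessing
        totals[row["entity"]] = np.nansum(impute_neighbors(row[COLS].to_numpy(float)))
    planted = {}
    for m in truth.modules:
        for p, w in m.members.items():
            planted[p] = planted.get(p, 0.0) + w
    common = sorted(totals)
    r = np.corrcoef([totals[p] for p in common], [planted[p] for p in common])[0, 1]
    assert r > 0.9
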