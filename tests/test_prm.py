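"""PRM peak-group acceptance, quantification, normalization and PCA summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import pca_ratio_oracle
from phoscomplex import prm
from phoscomplex.config import PrmParams
from phoscomplex.errors import ValidationError
from phoscomplex.prm import (PeakGroup, accept_peak_group, dot_product,
                             light_heavy_ratio, normalize_panel, panel_summary,
                             pca_variance_ratios, quantify_peptide)


class TestDotProduct:
    def test_proportional_vectors_give_one(self):
        lib = {"y3": 1.0, "y4": 0.5, "y5": 0.25}
        obs = {k: 40.0 * v for k, v in lib.items()}
        assert dot_product(obs, lib) == pytest.approx(1.0, abs=1e-12)

    def test_half_overlapping_pattern_gives_half(self):
        obs = {"y3": 1.0, "y4": 0.0, "y5": 1.0}
        lib = {"y3": 1.0, "y4": 1.0, "y5": 0.0}
        assert dot_product(obs, lib) == pytest.approx(0.5, abs=1e-12)

    def test_disjoint_nonzero_fragments_give_zero(self):
        obs = {"y3": 1.0, "y4": 0.0}
        lib = {"y3": 0.0, "y4": 1.0}
        assert dot_product(obs, lib) == 0.0

    def test_all_zero_observed_gives_zero_by_convention(self):
        assert dot_product({"y3": 0.0, "y4": 0.0}, {"y3": 1.0, "y4": 0.5}) == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    def test_scale_invariant_and_bounded(self, sa, sb):
        obs = {"y3": 3.0, "y4": 1.0, "y5": 0.2}
        lib = {"y3": 1.0, "y4": 0.8, "y5": 0.1}
        base = dot_product(obs, lib)
        scaled = dot_product({k: sa * v for k, v in obs.items()},
                             {k: sb * v for k, v in lib.items()})
        assert scaled == pytest.approx(base, rel=1e-9)
        assert 0.0 <= base <= 1.0


class TestAcceptance:
    LIB = {"rel_intensities": {"y3": 1.0, "y4": 0.5, "y5": 0.25}, "library_rt": 45.0}

    def _pg(self, rt, fragments=None):
        fragments = fragments or {"y3": 100.0, "y4": 50.0, "y5": 25.0}
        return PeakGroup("PEP", "light", rt, fragments, {f: 50.0 for f in fragments})

    def test_perfect_match_accepted(self):
        ok, reasons = accept_peak_group(self._pg(45.0), self.LIB, 90.0)
        assert ok and reasons["rt_ok"] and reasons["dotp_ok"]

    def test_rt_offset_beyond_five_percent_of_gradient_rejected(self):
        # 90-min gradient -> tolerance 4.5 min; 5-min offset fails despite dotp 1
        ok, reasons = accept_peak_group(self._pg(50.0), self.LIB, 90.0)
        assert not ok and not reasons["rt_ok"] and reasons["dotp_ok"]

    def test_dot_product_boundary_is_strict(self):
        params = PrmParams()
        obs = {"y3": 1.0, "y4": 1.0}
        lib = {"rel_intensities": {"y3": 1.0, "y4": 0.0}, "library_rt": 45.0}
        # cosine = 1/sqrt(2) ~ 0.707 < 0.75 -> rejected
        ok, reasons = accept_peak_group(self._pg(45.0, obs), lib, 90.0, params)
        assert not ok
        params_exact = PrmParams(min_dotp=reasons["dotp"])
        ok, _ = accept_peak_group(self._pg(45.0, obs), lib, 90.0, params_exact)
        assert not ok      # equality still rejects

    def test_missing_library_rt_is_an_error(self):
        with pytest.raises(ValidationError, match="library RT"):
            accept_peak_group(self._pg(45.0),
                              {"rel_intensities": self.LIB["rel_intensities"],
                               "library_rt": float("nan")}, 90.0)


class TestQuantification:
    def test_sum_of_three_fragments(self):
        pg = PeakGroup("P", "light", 10.0, {"a": 10.0, "b": 20.0, "c": 30.0},
                       {"a": 9.0, "b": 9.0, "c": 9.0})
        value, low = quantify_peptide(pg)
        assert value == 60.0 and not low

    def test_low_sn_fragment_excluded_before_top3(self):
        pg = PeakGroup("P", "light", 10.0,
                       {"a": 40.0, "b": 30.0, "c": 20.0, "d": 10.0},
                       {"a": 4.0, "b": 9.0, "c": 9.0, "d": 9.0})
        value, low = quantify_peptide(pg)
        assert value == 60.0 and not low

    def test_fewer_than_three_survivors_flagged(self):
        pg = PeakGroup("P", "light", 10.0, {"a": 10.0, "b": 20.0},
                       {"a": 9.0, "b": 9.0})
        value, low = quantify_peptide(pg)
        assert value == 30.0 and low

    def test_all_fragments_below_sn_give_missing(self):
        pg = PeakGroup("P", "light", 10.0, {"a": 10.0, "b": 20.0},
                       {"a": 1.0, "b": 2.0})
        value, low = quantify_peptide(pg)
        assert np.isnan(value)

    def test_monotone_in_fragment_area_above_the_gate(self):
        base = PeakGroup("P", "light", 10.0, {"a": 10.0, "b": 20.0, "c": 30.0},
                         {"a": 9.0, "b": 9.0, "c": 9.0})
        bumped = PeakGroup("P", "light", 10.0, {"a": 15.0, "b": 20.0, "c": 30.0},
                           base.sn)
        assert quantify_peptide(bumped)[0] >= quantify_peptide(base)[0]


class TestRatios:
    def test_equal_channels_give_zero_and_fourfold_gives_two(self):
        assert light_heavy_ratio(8.0, 8.0) == 0.0
        assert light_heavy_ratio(32.0, 8.0) == 2.0

    def test_zero_heavy_is_an_error(self):
        with pytest.raises(ValidationError):
            light_heavy_ratio(8.0, 0.0)

    def test_missing_light_propagates_missing(self):
        assert np.isnan(light_heavy_ratio(float("nan"), 8.0))


def _panel_table(values: dict[tuple[str, str, int], float]) -> pd.DataFrame:
    return pd.DataFrame([{"entity": e, "condition": c, "replicate": r, "intensity": v}
                         for (e, c, r), v in values.items()])


class TestNormalizePanel:
    def test_equal_references_leave_table_unchanged(self):
        t = _panel_table({("REF", "a", 1): 10.0, ("REF", "b", 1): 10.0,
                          ("X", "a", 1): 4.0, ("X", "b", 1): 6.0})
        out = normalize_panel(t, "housekeeping_irt", ["REF"])
        ratio = out.loc[out["entity"] == "X", "intensity"].to_numpy()
        assert np.allclose(ratio * 10.0, [4.0, 6.0])

    def test_run_with_double_references_is_halved(self):
        t = _panel_table({("REF", "a", 1): 10.0, ("REF", "b", 1): 20.0,
                          ("X", "a", 1): 4.0, ("X", "b", 1): 4.0})
        out = normalize_panel(t, "housekeeping_irt", ["REF"]).set_index(["entity", "condition"])
        assert out.loc[("X", "b"), "intensity"] == pytest.approx(
            out.loc[("X", "a"), "intensity"] / 2)

    def test_missing_tag_peptide_names_run_and_reference(self):
        t = _panel_table({("X", "a", 1): 4.0})
        with pytest.raises(ValidationError, match="AADITSLYK.*a/1"):
            normalize_panel(t, "tag_peptide", ["AADITSLYK"])

    def test_bait_mode_divides_phosphopeptides_by_bait_level(self):
        t = _panel_table({("REF", "a", 1): 1.0, ("REF", "b", 1): 1.0,
                          ("BAITPEP", "a", 1): 2.0, ("BAITPEP", "b", 1): 4.0,
                          ("pS127", "a", 1): 8.0, ("pS127", "b", 1): 16.0})
        out = normalize_panel(t, "bait_peptides", ["REF"],
                              bait_entities=["BAITPEP"], phospho_entities=["pS127"])
        o = out.set_index(["entity", "condition"])["intensity"]
        # phosphopeptide doubled but bait also doubled -> phospho level unchanged
        assert o[("pS127", "a")] == pytest.approx(o[("pS127", "b")])


class TestPanelSummary:
    def _table(self, seed=0):
        rng = np.random.default_rng(seed)
        values = {}
        for entity, effect in (("I1", 1.0), ("I2", -1.0), ("pS1", 0.5), ("KO1", -3.0)):
            for line in ("parental", "KO_A", "KO_B"):
                shift = effect if line == "KO_A" else 0.0
                for rep in (1, 2, 3):
                    values[(entity, line, rep)] = float(
                        2 ** (10.0 + shift + rng.normal(0, 0.05)))
        return _panel_table(values)

    def test_fold_changes_recover_planted_effects(self):
        out = panel_summary(self._table(), "parental", {"KO_A": ["KO1"]})
        fc = out.fold_changes.set_index(["entity", "line"])["log2fc"]
        assert fc[("I1", "KO_A")] == pytest.approx(1.0, abs=0.2)
        assert fc[("I2", "KO_A")] == pytest.approx(-1.0, abs=0.2)
        assert abs(fc[("I1", "KO_B")]) < 0.2

    def test_ko_target_rows_removed_from_pca_input(self):
        out = panel_summary(self._table(), "parental", {"KO_A": ["KO1"]})
        # 4 entities - 1 removed = 3 features -> at most 3 nonzero components
        assert len(out.pca_variance) <= 6
        assert out.pca_variance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_parental_is_an_error(self):
        with pytest.raises(ValidationError, match="parental"):
            panel_summary(self._table(), "wildtype")

    def test_rank_one_matrix_puts_all_variance_on_pc1(self):
        x = np.outer([1.0, 2.0, 3.0, 4.0], [1.0, -1.0, 0.5])
        ratios = pca_variance_ratios(x)
        assert ratios[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_ratios_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.normal(size=(4, 3))
            assert np.allclose(pca_variance_ratios(x), pca_ratio_oracle(x), atol=1e-9)
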