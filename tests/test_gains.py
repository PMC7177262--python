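"""Selection-response arithmetic, truncation selection, MAS scoring."""

import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from drypea.gains import (
    GainScenario,
    MASPanel,
    gain_direct_ps,
    gain_gs,
    gain_indirect_ps,
    mas_score,
    selection_intensity,
    truncation_select,
)
from drypea.genotypes import GenotypeMatrix


class TestSelectionIntensity:
    @pytest.mark.parametrize(
        "p,expected,tol",
        [
            (1.0, 0.0, 1e-12),
            (0.10, 1.755, 5e-4),  # the equal-intensity scenario
            (0.036, 2.197, 5e-4),  # the equal-cost genomic-selection scenario
            (0.5, 0.7979, 1e-4),
        ],
    )
    def test_reference_values(self, p, expected, tol):
        assert selection_intensity(p) == pytest.approx(expected, abs=tol)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_matches_numeric_truncated_normal_mean(self, p):
        z = scipy.stats.norm.isf(p)
        num, _ = scipy.integrate.quad(
            lambda x: x * scipy.stats.norm.pdf(x), z, 12.0
        )
        assert selection_intensity(p) == pytest.approx(num / p, abs=1e-4)

    def test_strictly_decreasing_in_selected_fraction(self):
        ps = np.linspace(0.01, 0.99, 60)
        vals = [selection_intensity(p) for p in ps]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_fraction_rejected(self):
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                selection_intensity(p)


class TestGains:
    def test_direct_ps_arithmetic(self):
        s = GainScenario(h2_target=0.5, sigma_p=0.2, i_ps=1.755)
        assert gain_direct_ps(s) == pytest.approx(0.1755)
        s2 = GainScenario(h2_target=0.870, sigma_p=0.12, i_ps=1.755)
        assert gain_direct_ps(s2) == pytest.approx(1.755 * 0.870 * 0.12, abs=1e-10)
        assert gain_direct_ps(GainScenario(h2_target=0.0, sigma_p=0.2)) == 0.0

    def test_indirect_ps_zero_correlation_gives_nothing(self):
        s = GainScenario(h2_target=0.5, sigma_p=0.2, h2_selection=0.9, r_g=0.0)
        gain, e_r = gain_indirect_ps(s)
        assert gain == 0.0 and e_r == 0.0

    def test_indirect_ps_self_consistency(self):
        s = GainScenario(h2_target=0.6, sigma_p=0.2, h2_selection=0.6, r_g=1.0)
        _, e_r = gain_indirect_ps(s)
        assert e_r == pytest.approx(1.0)

    def test_gs_break_even_construction(self):
        """r_Ab = H2 i/i'' makes genomic and phenotypic selection equal."""
        h2 = 0.6
        s = GainScenario(
            h2_target=h2, sigma_p=0.15, r_ab=h2 * 1.755 / 2.197,
        )
        gain, e_r = gain_gs(s)
        assert e_r == pytest.approx(1.0)
        assert gain == pytest.approx(gain_direct_ps(s))

    def test_gs_equivalent_accuracy_form(self):
        s = GainScenario(h2_target=0.475, sigma_p=0.2, r_ab=0.35)
        gain, _ = gain_gs(s)
        assert gain == pytest.approx(s.i_gs * s.r_ac * s.sigma_a, abs=1e-12)

    def test_missing_inputs_raise(self):
        s = GainScenario(h2_target=0.5)
        with pytest.raises(ValueError, match="sigma_p"):
            gain_direct_ps(s)
        with pytest.raises(ValueError, match="r_ab"):
            gain_gs(GainScenario(h2_target=0.5, sigma_p=0.1))


class TestTruncationSelect:
    def test_select_all(self):
        v = pd.Series({"a": 1.0, "b": 2.0})
        assert set(truncation_select(v, n=2)) == {"a", "b"}

    def test_top_n_of_thirty(self):
        rng = np.random.default_rng(0)
        v = pd.Series(rng.normal(0, 1, 30), index=[f"l{i:02d}" for i in range(30)])
        sel = truncation_select(v, n=3)
        assert set(sel) == set(v.nlargest(3).index)

    def test_tie_broken_by_line_id(self):
        v = pd.Series({"b": 1.0, "a": 1.0, "c": 2.0, "d": 0.0})
        assert truncation_select(v, n=2) == ["c", "a"]

    def test_per_population_selection(self):
        v = pd.Series({"a1": 3.0, "a2": 1.0, "b1": 0.5, "b2": 2.0})
        pops = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert truncation_select(v, n=1, populations=pops) == ["a1", "b2"]

    def test_overselection_rejected(self):
        with pytest.raises(ValueError, match="cannot select"):
            truncation_select(pd.Series({"a": 1.0}), n=2)


class TestMasScore:
    def _panel(self):
        markers = {f"t{i}": "alt" for i in range(1, 8)}
        regions = {
            "r1": ["t1", "t2"],
            "r2": ["t3", "t4"],
            "r3": ["t5"],
            "r4": ["t6"],
            "r5": ["t7"],
        }
        return MASPanel(markers, regions)

    def _geno(self, rows: dict):
        calls = pd.DataFrame.from_dict(
            rows, orient="index", columns=[f"t{i}" for i in range(1, 8)]
        ).astype(float)
        return GenotypeMatrix(calls)

    def test_extreme_lines(self):
        g = self._geno({"top": [2] * 7, "bottom": [0] * 7, "het": [1] * 7})
        out = mas_score(g, self._panel())
        assert out.loc["top", "allele_count"] == 14
        assert out.loc["top", "region_count"] == 10
        assert out.loc["top", "group"] == "top"
        assert out.loc["bottom", "allele_count"] == 0
        assert out.loc["bottom", "group"] == "bottom"
        assert out.loc["het", "allele_count"] == 7  # mid-range material
        assert out.loc["het", "group"] == "mid"

    def test_region_consensus_rounds_half_down(self):
        # region r1 members carry {2, 0}: mean dosage 1 -> rounds to 1
        g = self._geno({"x": [2, 0, 2, 2, 2, 2, 2]})
        out = mas_score(g, self._panel())
        assert out.loc["x", "region_count"] == 1 + 2 + 2 + 2 + 2

    def test_ref_coded_favorable_allele(self):
        markers = {"t1": "ref"}
        panel = MASPanel(markers, {"r1": ["t1"]})
        calls = pd.DataFrame({"t1": [0.0, 2.0]}, index=["good", "bad"])
        out = mas_score(GenotypeMatrix(calls), panel)
        assert out.loc["good", "allele_count"] == 2
        assert out.loc["bad", "allele_count"] == 0

    def test_missing_panel_marker_rejected(self):
        g = self._geno({"x": [2] * 7})
        g.calls.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            mas_score(g, self._panel())

    def test_panel_validation(self):
        with pytest.raises(ValueError, match="more than one region"):
            MASPanel({"t1": "alt"}, {"r1": ["t1"], "r2": ["t1"]})
        with pytest.raises(ValueError, match="empty"):
            MASPanel({"t1": "alt"}, {"r1": ["t1"], "r2": []})

    def test_simulated_tolerance_panel_spans_score_range(self, study):
        """In the family where every panel locus segregates, both an
        all-favorable and a zero-favorable line exist."""
        from drypea.simulate import default_mas_panel

        panel = default_mas_panel(study.trait_model)
        g = study.genotypes_true
        first = g.subset(lines=g.populations.index[g.populations == "AxI"])
        out = mas_score(first, panel)
        assert (out["group"] == "top").any()
        assert (out["group"] == "bottom").any()
        assert out["allele_count"].max() == 14
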