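"""Variance components, BLUPs, correlations, ANOVAs, group comparisons."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import drypea.phenostats as ps
from conftest import balanced_rcb


# ----------------------------------------------------------------------
# REML variance components
# ----------------------------------------------------------------------
class TestVarComp:
    def test_balanced_reml_equals_anova_estimators(self):
        """For a balanced RCB the REML optimum is the moment solution
        sigma2_e = MSE, sigma2_g = (MS_line - MSE)/r."""
        plots = balanced_rcb(40, 3, sigma_g=1.0, sigma_e=0.7, seed=4)
        vc = ps.fit_varcomp(plots, "E1", "yield")
        # ANOVA oracle from scratch
        y = plots["yield"].to_numpy()
        lines = pd.Categorical(plots["line"])
        blocks = pd.Categorical(plots["block"])
        grand = y.mean()
        line_means = plots.groupby("line")["yield"].mean()
        block_means = plots.groupby("block")["yield"].mean()
        r, n_l = 3, 40
        ss_line = r * ((line_means - grand) ** 2).sum()
        ss_block = n_l * ((block_means - grand) ** 2).sum()
        ss_tot = ((y - grand) ** 2).sum()
        ss_err = ss_tot - ss_line - ss_block
        mse = ss_err / ((n_l - 1) * (r - 1))
        ms_line = ss_line / (n_l - 1)
        assert vc.sigma2_e == pytest.approx(mse, abs=1e-8)
        assert vc.sigma2_g == pytest.approx((ms_line - mse) / r, abs=1e-8)

    def test_unbalanced_reml_matches_mixedlm(self):
        """Independent oracle: statsmodels MixedLM (REML) on unbalanced data."""
        import statsmodels.formula.api as smf

        plots = balanced_rcb(25, 3, sigma_g=0.8, sigma_e=0.5, seed=8)
        plots = plots.drop(plots.index[::7])  # knock out some plots
        vc = ps.fit_varcomp(plots, "E1", "yield")
        m = smf.mixedlm("Q('yield') ~ C(block)", plots, groups=plots["line"]).fit(reml=True)
        assert vc.sigma2_g == pytest.approx(float(m.cov_re.iloc[0, 0]), rel=1e-4)
        assert vc.sigma2_e == pytest.approx(float(m.scale), rel=1e-4)

    def test_h2_closed_form_recovery(self):
        """sigma_g = sigma_e = 1, r = 4 gives H2 = 1/(1 + 1/4) = 0.8."""
        h2s = [
            ps.fit_varcomp(balanced_rcb(300, 4, 1.0, 1.0, seed=s), "E1", "yield").h2
            for s in range(3)
        ]
        assert np.mean(h2s) == pytest.approx(0.8, abs=0.04)

    def test_zero_genetic_variance_truncates(self):
        plots = balanced_rcb(30, 3, sigma_g=0.0, sigma_e=1.0, seed=2)
        vc = ps.fit_varcomp(plots, "E1", "yield")
        assert vc.sigma2_g >= 0.0
        assert 0.0 <= vc.h2 <= 0.15

    def test_h2_affine_invariance(self):
        plots = balanced_rcb(50, 3, 1.0, 1.0, seed=5)
        vc1 = ps.fit_varcomp(plots, "E1", "yield")
        plots2 = plots.assign(**{"yield": 3.0 * plots["yield"] + 7.0})
        vc2 = ps.fit_varcomp(plots2, "E1", "yield")
        assert vc1.h2 == pytest.approx(vc2.h2, abs=1e-6)

    def test_too_few_blocks_rejected(self):
        plots = balanced_rcb(10, 1, 1.0, 1.0, seed=0)
        with pytest.raises(ValueError, match="blocks"):
            ps.fit_varcomp(plots, "E1", "yield")


# ----------------------------------------------------------------------
# BLUP shrinkage
# ----------------------------------------------------------------------
class TestBlup:
    @pytest.mark.parametrize(
        "h2,mean_i,expected",
        [(1.0, 0.50, 0.50), (0.0, 0.50, 0.32), (0.87, 0.50, 0.4766)],
    )
    def test_shrinkage_arithmetic(self, h2, mean_i, expected):
        means = ps.LineMeans("E", "yield", pd.Series({"a": mean_i, "b": 0.32 * 2 - mean_i}), 0.32)
        vc = ps.VarComp("E", "yield", h2, 1 - h2 if h2 < 1 else 0.0, 1, h2, 0.1, 2)
        out = ps.blup_line_values(means, vc)
        assert out.blup["a"] == pytest.approx(expected, abs=1e-10)

    def test_blups_shrink_toward_grand_mean(self, study, varcomps, blups):
        for env, lm in blups.items():
            assert (np.abs(lm.blup - lm.mu) <= np.abs(lm.means - lm.mu) + 1e-12).all()


# ----------------------------------------------------------------------
# Genetic correlation
# ----------------------------------------------------------------------
class TestGeneticCorrelation:
    def _vc(self, h2):
        return ps.VarComp("E", "yield", h2, 1 - h2, 2, h2, 0.1, 3)

    def test_identical_means_clamp_to_one(self):
        m = ps.LineMeans("A", "yield", pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}), 2.0)
        m2 = ps.LineMeans("B", "yield", m.means.copy(), 2.0)
        r = ps.genetic_correlation(m, m2, self._vc(0.81), self._vc(0.81))
        assert r == 1.0  # raw ratio 1/0.81 clamped

    def test_symmetry(self, blups, varcomps):
        a = ps.genetic_correlation(blups["ms"], blups["severe"], varcomps["ms"], varcomps["severe"])
        b = ps.genetic_correlation(blups["severe"], blups["ms"], varcomps["severe"], varcomps["ms"])
        assert a == pytest.approx(b, abs=1e-12)

    def test_independent_environments_near_zero(self):
        rng = np.random.default_rng(0)
        idx = [f"l{i}" for i in range(400)]
        m1 = ps.LineMeans("A", "yield", pd.Series(rng.normal(0, 1, 400), index=idx), 0.0)
        m2 = ps.LineMeans("B", "yield", pd.Series(rng.normal(0, 1, 400), index=idx), 0.0)
        r = ps.genetic_correlation(m1, m2, self._vc(0.9), self._vc(0.9))
        assert abs(r) < 0.15

    def test_zero_heritability_rejected(self, blups, varcomps):
        bad = ps.VarComp("X", "yield", 0.0, 1.0, 2, 0.0, 0.1, 3)
        with pytest.raises(ValueError, match="zero heritability"):
            ps.genetic_correlation(blups["ms"], blups["severe"], bad, varcomps["severe"])


# ----------------------------------------------------------------------
# Combined ANOVA
# ----------------------------------------------------------------------
class TestCombinedAnova:
    def test_ss_decomposition_sums_to_total(self, study):
        tab = ps.combined_anova(study.plots, "yield").table
        total = tab.loc[tab["source"] == "total", "SS"].iloc[0]
        parts = tab.loc[tab["source"] != "total", "SS"].sum()
        assert parts == pytest.approx(total, rel=1e-6)
        df_total = tab.loc[tab["source"] == "total", "df"].iloc[0]
        assert tab.loc[tab["source"] != "total", "df"].sum() == df_total

    def test_single_environment_rejected(self, study):
        sub = study.plots[study.plots["env"] == "ms"]
        with pytest.raises(ValueError, match=">= 2 environments"):
            ps.combined_anova(sub, "yield")

    def test_missing_cell_reported(self, study):
        broken = study.plots[
            ~((study.plots["line"] == study.plots["line"].iloc[0])
              & (study.plots["env"] == "ms"))
        ]
        with pytest.raises(ValueError, match="missing \\(line, environment\\)"):
            ps.combined_anova(broken, "yield")

    def test_interaction_p_uniform_under_null(self):
        """Without generated GxE the interaction test holds its size."""
        rng = np.random.default_rng(3)
        n_sims, hits = 120, 0
        for _ in range(n_sims):
            rows = []
            g = rng.normal(0, 0.3, 12)
            for e, mu in (("A", 1.0), ("B", 2.0)):
                for b in range(2):
                    for i in range(12):
                        rows.append((e, f"b{b}", f"l{i:02d}", "p",
                                     mu + g[i] + rng.normal(0, 0.5)))
            plots = pd.DataFrame(rows, columns=["env", "block", "line", "population", "yield"])
            p = ps.combined_anova(plots, "yield").row("genotype:environment")["p"]
            hits += p < 0.05
        assert scipy.stats.binomtest(hits, n_sims, 0.05).pvalue > 0.01


# ----------------------------------------------------------------------
# Hartley's F-max
# ----------------------------------------------------------------------
class TestHartley:
    def test_equal_variances_give_one(self):
        stat, p = ps.hartley_fmax([1.0, 1.0, 1.0], df=30, n_mc=2000, seed=0)
        assert stat == 1.0
        assert p == pytest.approx(1.0)

    def test_statistic_is_max_over_min(self):
        stat, _ = ps.hartley_fmax([2.0, 1.0, 0.5], df=60, n_mc=2000, seed=0)
        assert stat == pytest.approx(4.0)

    def test_zero_variance_degenerates(self):
        stat, p = ps.hartley_fmax([1.0, 0.0], df=10)
        assert np.isinf(stat) and p == 0.0


# ----------------------------------------------------------------------
# Group comparison (selection experiments)
# ----------------------------------------------------------------------
def _group_trial(effects: dict, n_per_group=3, r=4, sigma_e=0.3, seed=0,
                 parent_effect=0.0):
    rng = np.random.default_rng(seed)
    rows, groups = [], {}
    for grp, eff in effects.items():
        for i in range(n_per_group):
            line = f"{grp}_l{i}"
            groups[line] = grp
            for b in range(r):
                rows.append(("E1", f"b{b}", line, "p",
                             10 + eff + rng.normal(0, sigma_e)))
    parents = set()
    for i in range(2):
        line = f"par_{i}"
        parents.add(line)
        for b in range(r):
            rows.append(("E1", f"b{b}", line, "p",
                         10 + parent_effect + rng.normal(0, sigma_e)))
    plots = pd.DataFrame(rows, columns=["env", "block", "line", "population", "yield"])
    return plots, groups, parents


class TestGroupComparison:
    def test_identical_groups_not_flagged(self):
        plots, groups, parents = _group_trial({"g1": 0.0, "g2": 0.0}, seed=1)
        out = ps.compare_line_groups(plots, groups, parents, n_mc=20_000, seed=0)
        assert not out.dunnett["sig_05"].any()
        diff = out.group_means["g1"] - out.group_means["g2"]
        assert abs(diff) < out.lsd_05

    def test_large_group_effect_detected(self):
        """An effect of ~3 LSD against the parents is flagged at p<0.01."""
        flagged = 0
        for seed in range(5):
            plots, groups, parents = _group_trial(
                {"sel": 1.0, "ctl": 0.0}, sigma_e=0.25, seed=seed
            )
            out = ps.compare_line_groups(plots, groups, parents, n_mc=20_000, seed=seed)
            flagged += bool(out.dunnett.loc["sel", "sig_01"])
        assert flagged == 5

    def test_single_comparison_reduces_to_t(self):
        plots, groups, parents = _group_trial({"g1": 0.2}, seed=3)
        out = ps.compare_line_groups(plots, groups, parents, n_mc=200_000, seed=1)
        err = out.anova_with_parents.row("error")
        t_crit = scipy.stats.t.ppf(0.975, int(err["df"]))
        assert out.dunnett_critical[0.05] == pytest.approx(t_crit, abs=0.03)

    def test_parent_overlap_rejected(self):
        plots, groups, parents = _group_trial({"g1": 0.0}, seed=0)
        bad_parents = parents | {next(iter(groups))}
        with pytest.raises(ValueError, match="parent lines"):
            ps.compare_line_groups(plots, groups, bad_parents)
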