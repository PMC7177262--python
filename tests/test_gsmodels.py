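"""rrBLUP and Bayesian Lasso genomic prediction."""

import numpy as np
import pandas as pd
import pytest

from drypea.genotypes import GenotypeMatrix
from drypea.gsmodels import (
    ChainConfig,
    GSModelFit,
    fit_bayesian_lasso,
    fit_rrblup,
    predict,
)


def _structured_data(n=40, p=25, h2=0.8, seed=0):
    """Inbred-like genotypes with an additive polygenic trait."""
    rng = np.random.default_rng(seed)
    calls = pd.DataFrame(
        rng.choice([0.0, 2.0], size=(n, p)),
        index=[f"l{i:02d}" for i in range(n)],
        columns=[f"m{j:02d}" for j in range(p)],
    )
    beta = rng.normal(0, 0.3, p)
    gv = (calls.to_numpy() - 1.0) @ beta
    noise_sd = np.sqrt(np.var(gv) * (1 - h2) / h2)
    y = pd.Series(1.0 + gv + rng.normal(0, noise_sd, n), index=calls.index)
    return GenotypeMatrix(calls), y, beta


class TestRrblup:
    def test_fixed_lambda_matches_normal_equations(self, toy_genotypes):
        """Direct ridge inversion oracle at a fixed penalty."""
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(0, 1, 6), index=toy_genotypes.line_ids)
        lam = 3.7
        fit = fit_rrblup(toy_genotypes, y, ridge_lambda=lam)
        W = toy_genotypes.calls.to_numpy() - 1.0
        W = W - W.mean(axis=0)
        oracle = np.linalg.solve(
            W.T @ W + lam * np.eye(W.shape[1]), W.T @ (y.to_numpy() - y.mean())
        )
        assert np.abs(fit.beta.to_numpy() - oracle).max() < 1e-8

    def test_marker_and_kinship_formulations_agree(self):
        g, y, _ = _structured_data()
        fit = fit_rrblup(g, y)
        assert np.isfinite(fit.ridge_lambda)
        W = g.calls.to_numpy() - 1.0
        W = W - W.mean(axis=0)
        K = W @ W.T
        y_c = y.to_numpy() - y.mean()
        gebv_kin = fit.mu + K @ np.linalg.solve(K + fit.ridge_lambda * np.eye(len(y)), y_c)
        gebv_marker = predict(fit, g).to_numpy()
        assert np.abs(gebv_kin - gebv_marker).max() < 1e-6

    def test_constant_phenotype_gives_zero_effects(self, toy_genotypes):
        y = pd.Series(0.42, index=toy_genotypes.line_ids)
        fit = fit_rrblup(toy_genotypes, y)
        assert fit.beta.abs().max() == 0.0
        assert fit.mu == pytest.approx(0.42)

    def test_coding_shift_invariance_up_to_intercept(self):
        g, y, _ = _structured_data(seed=3)
        fit1 = fit_rrblup(g, y)
        # same data under 0/1 allele coding scaled to 0/2 after +0 shift is
        # identical; a pure dosage shift cannot change centered effects
        shifted = GenotypeMatrix(2.0 - g.calls, g.populations)  # swap ref/alt
        fit2 = fit_rrblup(shifted, y)
        assert np.abs(fit1.beta.to_numpy() + fit2.beta.to_numpy()).max() < 1e-8
        assert np.abs(
            predict(fit1, g).to_numpy() - predict(fit2, shifted).to_numpy()
        ).max() < 1e-8

    def test_missing_calls_rejected(self, toy_genotypes):
        g = toy_genotypes.copy()
        g.calls.iloc[0, 0] = np.nan
        y = pd.Series(np.arange(6.0), index=g.line_ids)
        with pytest.raises(ValueError, match="knn_impute"):
            fit_rrblup(g, y)


class TestBayesianLasso:
    def test_chain_reproducible_under_seed(self):
        g, y, _ = _structured_data()
        cfg = ChainConfig(iterations=1500, burn_in=300, thin=3, seed=11)
        f1 = fit_bayesian_lasso(g, y, cfg)
        f2 = fit_bayesian_lasso(g, y, cfg)
        assert np.array_equal(f1.beta.to_numpy(), f2.beta.to_numpy())
        assert f1.mu == f2.mu

    def test_total_shrinkage_limit(self):
        """With an enormous fixed regularization the prior dominates and
        all effects collapse to ~0."""
        g, y, _ = _structured_data()
        y = (y - y.mean()) / y.std()
        cfg = ChainConfig(iterations=2000, burn_in=500, thin=3, seed=1,
                          fixed_lambda2=1e12)
        fit = fit_bayesian_lasso(g, y, cfg)
        assert fit.beta.abs().max() < 1e-3

    def test_agrees_with_rrblup_under_dense_small_effects(self):
        g, y, _ = _structured_data(n=60, p=40, h2=0.7, seed=5)
        bl = fit_bayesian_lasso(g, y, ChainConfig(iterations=3000, burn_in=800, seed=2))
        rr = fit_rrblup(g, y)
        r = np.corrcoef(predict(bl, g), predict(rr, g))[0, 1]
        assert r >= 0.95

    def test_recovers_sparse_large_qtl(self, study, imputed):
        """Five large-effect loci among hundreds of markers: the largest
        posterior-mean effects sit at or immediately beside true QTL."""
        tm = study.trait_model
        pos = imputed.positions
        qtl = [m for m in tm.yield_effects.index
               if tm.yield_effects.loc[m, "moderate"] != 0]
        rng = np.random.default_rng(4)
        gv = study.true_values["moderate"]
        y = gv + rng.normal(0, 0.3 * gv.std(), len(gv))
        fit = fit_bayesian_lasso(
            imputed, y.loc[imputed.line_ids],
            ChainConfig(iterations=4000, burn_in=1000, seed=9),
        )
        top = fit.beta.abs().nlargest(5).index

        def near_qtl(m):
            c, x = pos.loc[m, "chrom"], pos.loc[m, "cm"]
            return any(
                q for q in qtl
                if study.genotypes_true.positions.loc[q, "chrom"] == c
                and abs(study.genotypes_true.positions.loc[q, "cm"] - x) <= 5.0
            )

        assert sum(near_qtl(m) for m in top) >= 4

    def test_bad_chain_config_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(iterations=0)
        with pytest.raises(ValueError):
            ChainConfig(iterations=100, burn_in=100)


class TestPredict:
    def test_training_lines_get_fitted_values(self):
        g, y, _ = _structured_data(seed=7)
        fit = fit_rrblup(g, y)
        again = predict(fit, g)
        one = predict(fit, g.subset(lines=[g.line_ids[0]]))
        assert one.iloc[0] == pytest.approx(again.iloc[0])

    def test_gebv_arithmetic(self):
        calls = pd.DataFrame([[2.0, 0.0]], index=["new"], columns=["m1", "m2"])
        fit = GSModelFit(
            kind="rrblup",
            mu=0.5,
            beta=pd.Series({"m1": 0.1, "m2": -0.2}),
            marker_means=pd.Series({"m1": -1.0, "m2": -1.0}),  # uncentered training
            sigma2_beta=1.0,
            sigma2_e=1.0,
        )
        out = predict(fit, GenotypeMatrix(calls))
        # mu + (2-1-(-1))*0.1 + (0-1-(-1))*(-0.2) = 0.5 + 0.2 + 0 = 0.7
        assert out["new"] == pytest.approx(0.7)

    def test_marker_mismatch_rejected(self, toy_genotypes):
        y = pd.Series(np.arange(6.0), index=toy_genotypes.line_ids)
        fit = fit_rrblup(toy_genotypes, y)
        missing = toy_genotypes.subset(markers=["m1", "m2"])
        with pytest.raises(ValueError, match="absent"):
            predict(fit, missing)

    def test_json_round_trip(self, tmp_path):
        g, y, _ = _structured_data(seed=2)
        fit = fit_rrblup(g, y)
        path = tmp_path / "model.json"
        fit.to_json(path)
        back = GSModelFit.from_json(path)
        assert np.allclose(back.beta.to_numpy(), fit.beta.to_numpy())
        assert np.allclose(predict(back, g), predict(fit, g))
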