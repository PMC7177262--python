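"""Genomic prediction models: rrBLUP and Bayesian Lasso.

Both models regress line phenotypes on all markers jointly,

    y = 1 mu + W beta + e,

with W the centered marker matrix (alternate-allele dosage minus one,
column-centered on the training lines). rrBLUP places one common normal
prior variance on every marker effect and estimates the two variance
components by REML through an eigendecomposition of the marker
cross-product; the ridge solution at lambda = sigma2_e / sigma2_beta
gives the effect estimates. The Bayesian Lasso places a double-exponential
prior on each effect (scale mixture of normals) and is fit by Gibbs
sampling, so that few markers may carry large effects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numba
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from drypea.genotypes import GenotypeMatrix

__all__ = ["GSModelFit", "ChainConfig", "fit_rrblup", "fit_bayesian_lasso", "predict"]


@dataclass
class ChainConfig:
    """Gibbs chain settings for the Bayesian Lasso.

    The default regularization hyperprior is lambda^2 ~ Gamma(0.55, 0.1)
    (shape, rate), a weak prior putting most mass on moderate shrinkage.
    """

    iterations: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0
    lambda2_shape: float = 0.55
    lambda2_rate: float = 0.1
    fixed_lambda2: float | None = None  # clamp lambda^2 instead of sampling it

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("non-positive chain configuration")
        if self.burn_in >= self.iterations:
            raise ValueError("burn-in must be shorter than the chain")


@dataclass
class GSModelFit:
    """A fitted genomic prediction model."""

    kind: str  # "rrblup" | "bayesian_lasso"
    mu: float
    beta: pd.Series  # per-marker effect (centered-dosage scale)
    marker_means: pd.Series  # training column means of dosage-1 coding
    sigma2_beta: float | None
    sigma2_e: float
    ridge_lambda: float | None = None  # sigma2_e / sigma2_beta (rrBLUP)
    bl_lambda: float | None = None  # posterior mean of lambda (BL)
    training_lines: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma2_e < 0 or (self.sigma2_beta is not None and self.sigma2_beta < 0):
            raise ValueError("variance components must be non-negative")

    # ------------------------------ I/O -------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "mu": self.mu,
            "markers": list(self.beta.index),
            "beta": self.beta.tolist(),
            "marker_means": self.marker_means.tolist(),
            "sigma2_beta": self.sigma2_beta,
            "sigma2_e": self.sigma2_e,
            "ridge_lambda": self.ridge_lambda,
            "bl_lambda": self.bl_lambda,
            "training_lines": self.training_lines,
            "diagnostics": self.diagnostics,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GSModelFit":
        d = json.loads(Path(path).read_text())
        markers = pd.Index(d["markers"])
        return cls(
            kind=d["kind"],
            mu=d["mu"],
            beta=pd.Series(d["beta"], index=markers),
            marker_means=pd.Series(d["marker_means"], index=markers),
            sigma2_beta=d["sigma2_beta"],
            sigma2_e=d["sigma2_e"],
            ridge_lambda=d["ridge_lambda"],
            bl_lambda=d["bl_lambda"],
            training_lines=d["training_lines"],
            diagnostics=d["diagnostics"],
        )


# ----------------------------------------------------------------------
# Shared plumbing
# ----------------------------------------------------------------------
def _design(genotypes: GenotypeMatrix, phenotypes: pd.Series):
    y = phenotypes.dropna()
    lines = [l for l in genotypes.line_ids if l in y.index]
    if len(lines) < 2:
        raise ValueError("need >= 2 phenotyped lines")
    calls = genotypes.calls.loc[lines]
    if calls.isna().any().any():
        raise ValueError(
            "genotype matrix contains missing calls; run knn_impute first"
        )
    dosage = calls.to_numpy() - 1.0
    means = dosage.mean(axis=0)
    W = dosage - means
    return (
        W,
        y.loc[lines].to_numpy(dtype=float),
        lines,
        pd.Series(means, index=calls.columns),
    )


# ----------------------------------------------------------------------
# rrBLUP
# ----------------------------------------------------------------------
def fit_rrblup(
    genotypes: GenotypeMatrix,
    phenotypes: pd.Series,
    ridge_lambda: float | None = None,
) -> GSModelFit:
    """Ridge-regression BLUP with REML variance components.

    REML maximizes the profile restricted likelihood of the variance
    ratio delta = sigma2_beta / sigma2_e on the spectrum of W W'; the
    marker effects are then the ridge solution at
    lambda = sigma2_e / sigma2_beta. Passing ``ridge_lambda`` skips REML
    and solves at a fixed penalty.
    """
    W, y, lines, means = _design(genotypes, phenotypes)
    n = len(y)
    y_mean = float(y.mean())
    y_c = y - y_mean
    K = W @ W.T
    theta, U = np.linalg.eigh(K)
    theta = np.clip(theta, 0.0, None)
    # REML lives on error contrasts: an orthonormal basis of the
    # orthogonal complement of the intercept column
    qfull, _ = scipy.linalg.qr(np.ones((n, 1)), mode="full")
    C = qfull[:, 1:]
    Wc = C.T @ W
    th, Uc = np.linalg.eigh(Wc @ Wc.T)
    th = np.clip(th, 0.0, None)
    e2 = (Uc.T @ (C.T @ y)) ** 2
    m = n - 1

    if ridge_lambda is None:

        def score(delta: float) -> float:
            d = 1.0 + delta * th
            s2 = np.mean(e2 / d)
            return float(np.sum(e2 * th / d**2) / s2 - np.sum(th / d))

        if np.allclose(e2, 0.0) or score(0.0) <= 0.0:
            delta_hat = 0.0
        else:
            hi = 1.0
            while score(hi) > 0.0 and hi < 1e12:
                hi *= 4.0
            if score(hi) > 0.0:  # noise-free limit: variance ratio unbounded
                delta_hat = hi
            else:
                delta_hat = scipy.optimize.brentq(score, 0.0, hi, xtol=1e-14, rtol=1e-14)
        s2e = float(np.mean(e2 / (1.0 + delta_hat * th)))
        s2b = delta_hat * s2e
        lam = np.inf if delta_hat == 0.0 else 1.0 / delta_hat
    else:
        lam = float(ridge_lambda)
        s2e, s2b = float("nan"), float("nan")

    if np.isinf(lam):
        beta = np.zeros(W.shape[1])
    else:
        inv = 1.0 / (theta + lam)
        beta = W.T @ (U @ (inv * (U.T @ y_c)))
    s2e = 0.0 if math.isnan(s2e) else s2e
    s2b = None if math.isnan(s2b) else s2b
    return GSModelFit(
        kind="rrblup",
        mu=y_mean,
        beta=pd.Series(beta, index=genotypes.marker_ids),
        marker_means=means,
        sigma2_beta=s2b,
        sigma2_e=s2e,
        ridge_lambda=lam,
        training_lines=lines,
        diagnostics={"n_contrasts": int(m)},
    )


# ----------------------------------------------------------------------
# Bayesian Lasso (Gibbs sampler, scale mixture of normals)
# ----------------------------------------------------------------------
@numba.njit(cache=False)
def _rinvgauss(mu: float, lam: float) -> float:
    """Inverse-Gaussian draw (Michael-Schucany-Haas)."""
    v = np.random.normal()
    yv = v * v
    x = (
        mu
        + mu * mu * yv / (2.0 * lam)
        - mu / (2.0 * lam) * math.sqrt(4.0 * mu * lam * yv + mu * mu * yv * yv)
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@numba.njit(cache=False)
def _bl_gibbs(
    W: np.ndarray,
    y: np.ndarray,
    iterations: int,
    burn_in: int,
    thin: int,
    seed: int,
    a_lambda: float,
    b_lambda: float,
    fixed_lambda2: float,
):
    """Single-site Gibbs sampler for the Bayesian Lasso.

    Returns (mu_mean, beta_mean, sigma2_draws, lambda2_draws, fail_iter);
    fail_iter >= 0 flags a non-finite draw at that iteration.
    """
    np.random.seed(seed)
    n, p = W.shape
    wtw = np.empty(p)
    for k in range(p):
        s = 0.0
        for i in range(n):
            s += W[i, k] * W[i, k]
        wtw[k] = s
    beta = np.zeros(p)
    tau2 = np.ones(p)
    mu = y.mean()
    var_y = y.var()
    sigma2 = var_y if var_y > 1e-12 else 1.0
    lambda2 = fixed_lambda2 if fixed_lambda2 > 0.0 else 1.0
    e = y - mu  # residual y - mu - W beta (beta = 0)
    n_keep = (iterations - burn_in + thin - 1) // thin
    beta_sum = np.zeros(p)
    mu_sum = 0.0
    sigma2_draws = np.empty(n_keep)
    lambda2_draws = np.empty(n_keep)
    kept = 0
    for it in range(iterations):
        # intercept
        mu_old = mu
        mean_e = 0.0
        for i in range(n):
            mean_e += e[i]
        mean_e = mean_e / n + mu_old
        mu = mean_e + np.random.normal() * math.sqrt(sigma2 / n)
        for i in range(n):
            e[i] += mu_old - mu
        # marker effects, single site with residual update
        for k in range(p):
            if wtw[k] == 0.0:
                beta[k] = 0.0
                continue
            rk = 0.0
            for i in range(n):
                rk += W[i, k] * e[i]
            rk += wtw[k] * beta[k]
            prec = wtw[k] + 1.0 / tau2[k]
            bmean = rk / prec
            bnew = bmean + np.random.normal() * math.sqrt(sigma2 / prec)
            diff = beta[k] - bnew
            if diff != 0.0:
                for i in range(n):
                    e[i] += W[i, k] * diff
            beta[k] = bnew
        # mixture scales
        for k in range(p):
            b2 = beta[k] * beta[k]
            if b2 < 1e-12:
                b2 = 1e-12
            inv_tau2 = _rinvgauss(math.sqrt(lambda2 * sigma2 / b2), lambda2)
            tau2[k] = 1.0 / inv_tau2
        # error variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        pen = 0.0
        for k in range(p):
            pen += beta[k] * beta[k] / tau2[k]
        shape = 0.5 * (n - 1 + p)
        sigma2 = (sse + pen) / (2.0 * np.random.gamma(shape, 1.0))
        # regularization
        if fixed_lambda2 <= 0.0:
            tsum = 0.0
            for k in range(p):
                tsum += tau2[k]
            lambda2 = np.random.gamma(a_lambda + p, 1.0 / (b_lambda + 0.5 * tsum))
        if not (math.isfinite(sigma2) and math.isfinite(lambda2) and math.isfinite(mu)):
            return mu_sum, beta_sum, sigma2_draws, lambda2_draws, it
        if it >= burn_in and (it - burn_in) % thin == 0:
            mu_sum += mu
            for k in range(p):
                beta_sum[k] += beta[k]
            sigma2_draws[kept] = sigma2
            lambda2_draws[kept] = lambda2
            kept += 1
    return mu_sum / kept, beta_sum / kept, sigma2_draws[:kept], lambda2_draws[:kept], -1


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence estimator."""
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for lag in range(1, n):
        if acf[lag] <= 0:
            break
        s += acf[lag]
    return float(n / (1.0 + 2.0 * s))


def fit_bayesian_lasso(
    genotypes: GenotypeMatrix,
    phenotypes: pd.Series,
    chain_config: ChainConfig | None = None,
) -> GSModelFit:
    """Bayesian Lasso fit by Gibbs sampling.

    Marker effects have the double-exponential prior in its
    scale-mixture-of-normals form (beta_k | tau2_k ~ N(0, sigma2 tau2_k),
    1/tau2_k inverse-Gaussian, lambda^2 with a Gamma hyperprior).
    Posterior means of mu and beta are returned with chain diagnostics
    (effective sample size of sigma2_e).
    """
    cfg = chain_config or ChainConfig()
    W, y, lines, means = _design(genotypes, phenotypes)
    mu, beta, s2_draws, l2_draws, fail = _bl_gibbs(
        np.ascontiguousarray(W),
        np.ascontiguousarray(y),
        cfg.iterations,
        cfg.burn_in,
        cfg.thin,
        cfg.seed,
        cfg.lambda2_shape,
        cfg.lambda2_rate,
        -1.0 if cfg.fixed_lambda2 is None else float(cfg.fixed_lambda2),
    )
    if fail >= 0:
        raise RuntimeError(f"Bayesian Lasso chain diverged at iteration {fail}")
    return GSModelFit(
        kind="bayesian_lasso",
        mu=float(mu),
        beta=pd.Series(beta, index=genotypes.marker_ids),
        marker_means=means,
        sigma2_beta=None,
        sigma2_e=float(s2_draws.mean()),
        bl_lambda=float(np.sqrt(l2_draws.mean())),
        training_lines=lines,
        diagnostics={
            "ess_sigma2_e": _ess(s2_draws),
            "n_kept": int(len(s2_draws)),
            "lambda2_mean": float(l2_draws.mean()),
        },
    )


# ----------------------------------------------------------------------
# Prediction
# ----------------------------------------------------------------------
def predict(fit: GSModelFit, genotypes: GenotypeMatrix) -> pd.Series:
    """Genomic estimated breeding values: GEBV = mu + W_new beta.

    New lines are centered with the training marker means; the marker set
    must match the fit.
    """
    absent = fit.beta.index.difference(genotypes.marker_ids)
    if len(absent):
        raise ValueError(f"markers absent from new lines: {list(absent)[:10]}")
    calls = genotypes.calls[fit.beta.index]
    if calls.isna().any().any():
        raise ValueError("genotypes of new lines contain missing calls; impute first")
    W = (calls.to_numpy() - 1.0) - fit.marker_means.to_numpy()
    gebv = fit.mu + W @ fit.beta.to_numpy()
    return pd.Series(gebv, index=genotypes.line_ids, name="gebv")
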