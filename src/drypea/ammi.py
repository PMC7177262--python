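"""AMMI analysis of genotype x environment interaction.

The additive-main-effects-and-multiplicative-interaction model decomposes
a complete line x environment table of means as

    y_ij = mu + G_i + E_j + sum_n lambda_n gamma_in delta_jn + rho_ij

where the multiplicative axes come from a singular value decomposition of
the doubly centered interaction residual. Axis significance is assessed
by an F-type test of the interaction remaining before each axis against
the pooled plot error; nominal yields drop the environment main effect to
display crossover interaction as lines over the environment PC1 score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["AMMIFit", "fit_ammi", "fr_test", "nominal_yields"]


@dataclass
class AMMIFit:
    """Fitted AMMI decomposition of a line x environment mean table."""

    grand_mean: float
    line_effects: pd.Series  # G_i
    env_effects: pd.Series  # E_j
    singular_values: np.ndarray  # lambda_n, per axis
    line_scores: pd.DataFrame  # gamma_in (lines x axes), orthonormal columns
    env_scores: pd.DataFrame  # delta_jn (envs x axes), orthonormal columns
    interaction_ss: float
    axis_ss: np.ndarray  # lambda_n^2
    pooled_error_ms: float | None = None
    error_df: int | None = None
    n_blocks: int = 1

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)

    def reconstruct(self) -> pd.DataFrame:
        """mu + G + E + all multiplicative axes (equals the input table)."""
        add = (
            self.grand_mean
            + self.line_effects.to_numpy()[:, None]
            + self.env_effects.to_numpy()[None, :]
        )
        inter = (
            self.line_scores.to_numpy()
            @ np.diag(self.singular_values)
            @ self.env_scores.to_numpy().T
        )
        return pd.DataFrame(
            add + inter, index=self.line_effects.index, columns=self.env_effects.index
        )


def fit_ammi(
    cell_means: pd.DataFrame,
    pooled_error_ms: float | None = None,
    error_df: int | None = None,
    n_blocks: int = 1,
) -> AMMIFit:
    """Fit the AMMI model to a complete line x environment table of means.

    ``pooled_error_ms`` and ``error_df`` (from the combined plot-level
    ANOVA) enable the axis F test; ``n_blocks`` is the replication count
    behind each cell mean, used to put the interaction SS of the means on
    the plot scale for that test.

    Sign convention: on each axis the score of the first environment (by
    input column order) is non-negative.
    """
    if cell_means.isna().any().any():
        bad = [
            (i, j)
            for i in cell_means.index
            for j in cell_means.columns
            if pd.isna(cell_means.loc[i, j])
        ]
        raise ValueError(f"cell-mean table has missing cells: {bad[:10]}")
    y = cell_means.to_numpy(dtype=float)
    n_lines, n_envs = y.shape
    if n_lines < 2 or n_envs < 2:
        raise ValueError("need >= 2 lines and >= 2 environments")
    mu = float(y.mean())
    g = y.mean(axis=1) - mu
    e = y.mean(axis=0) - mu
    resid = y - mu - g[:, None] - e[None, :]
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    n_axes = min(n_lines, n_envs) - 1
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    # sign convention: first environment's score non-negative per axis
    flip = np.where(vt[:, 0] < 0, -1.0, 1.0)
    u *= flip[None, :]
    vt *= flip[:, None]
    return AMMIFit(
        grand_mean=mu,
        line_effects=pd.Series(g, index=cell_means.index, name="G"),
        env_effects=pd.Series(e, index=cell_means.columns, name="E"),
        singular_values=s,
        line_scores=pd.DataFrame(
            u, index=cell_means.index, columns=[f"PC{k + 1}" for k in range(n_axes)]
        ),
        env_scores=pd.DataFrame(
            vt.T, index=cell_means.columns, columns=[f"PC{k + 1}" for k in range(n_axes)]
        ),
        interaction_ss=float((resid**2).sum()),
        axis_ss=s**2,
        pooled_error_ms=pooled_error_ms,
        error_df=error_df,
        n_blocks=n_blocks,
    )


def fr_test(fit: AMMIFit, axis: int, n_blocks: int | None = None):
    """F-type test of AMMI axis ``axis`` (1-based) against pooled error.

    The statistic for axis n tests the interaction remaining after fitting
    axes 1..n-1:

        F_R = n_blocks * SS_rem / (df_rem * pooled_error_MS),
        df_rem = (I - n)(J - n)

    against F(df_rem, error_df). Axis n is declared significant when this
    remaining interaction is significant (sequentially, axes stop being
    significant at the first non-significant remainder).

    Returns ``(F, df_num, df_den, p)``.
    """
    if fit.pooled_error_ms is None or fit.error_df is None:
        raise ValueError("fr_test needs pooled_error_ms and error_df from the ANOVA")
    if axis < 1 or axis > fit.n_axes:
        raise ValueError(f"axis must be in 1..{fit.n_axes}")
    n_blocks = fit.n_blocks if n_blocks is None else n_blocks
    n_lines = len(fit.line_effects)
    n_envs = len(fit.env_effects)
    ss_rem = float(fit.axis_ss[axis - 1 :].sum()) * n_blocks
    df_rem = (n_lines - axis) * (n_envs - axis)
    if df_rem <= 0:
        raise ValueError("no residual degrees of freedom for this axis")
    f_stat = ss_rem / (df_rem * fit.pooled_error_ms)
    p = float(scipy.stats.f.sf(f_stat, df_rem, fit.error_df))
    return float(f_stat), int(df_rem), int(fit.error_df), p


def significant_axes(fit: AMMIFit, alpha: float = 0.05) -> list[int]:
    """Axes retained by the sequential remainder test (1-based indices)."""
    kept = []
    for axis in range(1, fit.n_axes + 1):
        _, _, _, p = fr_test(fit, axis)
        if p < alpha:
            kept.append(axis)
        else:
            break
    return kept


def nominal_yields(fit: AMMIFit) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AMMI nominal yields: modeled values without the environment effect.

    nominal_ij = mu + G_i + lambda_1 gamma_i1 delta_j1. Returns the
    nominal table and a per-line response summary with ``intercept``
    (mu + G_i) and ``slope`` (lambda_1^(1/2) gamma_i1) against the scaled
    environment coordinate delta_j1 lambda_1^(1/2) (symmetric-scaling
    convention: plotted lines evaluated at the environment coordinate
    reproduce the nominal yields exactly).
    """
    if fit.n_axes == 0:
        raise ValueError("fit has no multiplicative axis")
    lam1 = fit.singular_values[0]
    gam1 = fit.line_scores.iloc[:, 0]
    del1 = fit.env_scores.iloc[:, 0]
    nominal = (
        fit.grand_mean
        + fit.line_effects.to_numpy()[:, None]
        + lam1 * np.outer(gam1, del1)
    )
    table = pd.DataFrame(nominal, index=fit.line_effects.index, columns=fit.env_effects.index)
    half = np.sqrt(lam1) if lam1 > 0 else 0.0
    responses = pd.DataFrame(
        {
            "intercept": fit.grand_mean + fit.line_effects,
            "slope": half * gam1,
        }
    )
    responses.attrs["env_coordinate"] = (half * del1).to_dict()
    return table, responses
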