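"""Plot-level phenotype analysis.

Per-environment variance components and line-mean heritability by REML,
BLUP line values by heritability shrinkage, genetic correlation across
environments, the combined genotype / environment / block-within-
environment ANOVA, Hartley's error-homogeneity test, and the line-group
comparison ANOVAs (LSD and Dunnett contrasts against the parent group)
used in proof-of-concept selection experiments.

A plot table is a long-format DataFrame with columns ``env``, ``block``,
``line``, ``population`` and one column per trait (yield in t/ha, aerial
biomass in t/ha, onset of flowering in days).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

__all__ = [
    "VarComp",
    "LineMeans",
    "AnovaTable",
    "GroupComparison",
    "fit_varcomp",
    "line_means",
    "blup_line_values",
    "genetic_correlation",
    "combined_anova",
    "hartley_fmax",
    "compare_line_groups",
]


# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------
@dataclass
class VarComp:
    """REML variance components for one environment and trait.

    ``h2`` is broad-sense heritability on a line-mean basis,
    sigma2_g / (sigma2_g + sigma2_e / r); ``sigma_p`` the phenotypic SD of
    the line means.
    """

    environment: str
    trait: str
    sigma2_g: float
    sigma2_e: float
    r: int
    h2: float
    sigma_p: float
    n_lines: int

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")
        if not 0 <= self.h2 <= 1:
            raise ValueError("line-mean heritability must lie in [0, 1]")


@dataclass
class LineMeans:
    """Per-line raw means (and optionally BLUPs) for one environment/trait."""

    environment: str
    trait: str
    means: pd.Series
    mu: float
    blup: pd.Series | None = None


@dataclass
class AnovaTable:
    """Fixed-effects ANOVA decomposition."""

    table: pd.DataFrame  # columns: source, df, SS, MS, F, p

    def __post_init__(self) -> None:
        if (self.table["SS"] < -1e-9).any():
            raise ValueError("negative sum of squares")

    def row(self, source: str) -> pd.Series:
        hit = self.table[self.table["source"] == source]
        if hit.empty:
            raise KeyError(f"no ANOVA source {source!r}")
        return hit.iloc[0]


@dataclass
class GroupComparison:
    """Output of the selection-experiment group analysis."""

    anova_selected: AnovaTable
    anova_with_parents: AnovaTable
    group_means: pd.Series
    lsd_05: float
    dunnett: pd.DataFrame  # per group: diff_to_parents, t, sig_05, sig_01
    dunnett_critical: dict[float, float] = field(default_factory=dict)


# ----------------------------------------------------------------------
# Variance components (REML, one random factor)
# ----------------------------------------------------------------------
def _reml_line_variance(y: np.ndarray, X: np.ndarray, line_codes: np.ndarray):
    """REML for y = X beta + Z u + e with u ~ N(0, sigma2_g I) per line.

    Works on error contrasts: with K an orthonormal basis of the null
    space of X', the contrasts w = K'y have covariance
    sigma2_e (I + gamma K'ZZ'K), gamma = sigma2_g / sigma2_e. The profile
    REML criterion is maximized in gamma by solving the score equation;
    a negative-definite score at 0 truncates gamma at the boundary.
    """
    n = len(y)
    q, _ = scipy.linalg.qr(X, mode="full")
    rank = np.linalg.matrix_rank(X)
    K = q[:, rank:]
    m = K.shape[1]
    n_lines = line_codes.max() + 1
    Z = np.zeros((n, n_lines))
    Z[np.arange(n), line_codes] = 1.0
    KZ = K.T @ Z
    A = KZ @ KZ.T
    theta, U = scipy.linalg.eigh(A)
    theta = np.clip(theta, 0.0, None)
    w = U.T @ (K.T @ y)
    w2 = w**2

    def sigma2_e(gamma: float) -> float:
        return float(np.mean(w2 / (1.0 + gamma * theta)))

    def score(gamma: float) -> float:
        d = 1.0 + gamma * theta
        s2 = np.mean(w2 / d)
        # proportional to d(log REML)/d(gamma); positive -> increase gamma
        return float(np.sum(w2 * theta / d**2) / s2 - np.sum(theta / d))

    if score(0.0) <= 0.0:
        gamma_hat = 0.0
    else:
        hi = 1.0
        while score(hi) > 0.0 and hi < 1e12:
            hi *= 4.0
        if score(hi) > 0.0:  # error-free limit: ratio unbounded
            gamma_hat = hi
        else:
            gamma_hat = scipy.optimize.brentq(score, 0.0, hi, xtol=1e-14, rtol=1e-14)
    s2e = sigma2_e(gamma_hat)
    return gamma_hat * s2e, s2e


def fit_varcomp(plots: pd.DataFrame, environment: str, trait: str) -> VarComp:
    """Line variance, plot error and line-mean heritability for one trial.

    Model: value = mean + block (fixed) + line (random) + error, fit by
    REML. For balanced randomized-complete-block data this reproduces the
    ANOVA estimators sigma2_e = MSE and sigma2_g = (MS_line - MSE)/r,
    truncated at zero.
    """
    sub = plots[plots["env"] == environment]
    if sub.empty:
        raise ValueError(f"no plots for environment {environment!r}")
    lines = pd.Categorical(sub["line"])
    blocks = pd.Categorical(sub["block"])
    if len(lines.categories) < 2:
        raise ValueError("need >= 2 lines")
    if len(blocks.categories) < 2:
        raise ValueError("need >= 2 blocks")
    y = sub[trait].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(y))]
        + [(blocks.codes == b).astype(float) for b in range(1, len(blocks.categories))]
    )
    s2g, s2e = _reml_line_variance(y, X, lines.codes)
    r = int(round(sub.groupby("line").size().mean()))
    h2 = s2g / (s2g + s2e / r) if s2g + s2e > 0 else 0.0
    means = sub.groupby("line")[trait].mean()
    return VarComp(
        environment=environment,
        trait=trait,
        sigma2_g=s2g,
        sigma2_e=s2e,
        r=r,
        h2=h2,
        sigma_p=float(means.std(ddof=1)),
        n_lines=len(lines.categories),
    )


def line_means(plots: pd.DataFrame, environment: str, trait: str) -> LineMeans:
    """Raw line means and their grand mean for one environment/trait."""
    sub = plots[plots["env"] == environment]
    if sub.empty:
        raise ValueError(f"no plots for environment {environment!r}")
    means = sub.groupby("line")[trait].mean()
    return LineMeans(environment, trait, means, float(means.mean()))


def blup_line_values(means: LineMeans, vc: VarComp) -> LineMeans:
    """Shrink line means toward the grand mean by the heritability:
    BLUP_i = mu + H^2 (mean_i - mu)."""
    if means.environment != vc.environment or means.trait != vc.trait:
        raise ValueError("line means and variance components must match")
    blup = means.mu + vc.h2 * (means.means - means.mu)
    return LineMeans(means.environment, means.trait, means.means, means.mu, blup)


def genetic_correlation(
    means_j: LineMeans, means_jp: LineMeans, vc_j: VarComp, vc_jp: VarComp
) -> float:
    """Genetic correlation of line performance across two environments.

    r_g = r_p / (H_j H_j'), the Pearson correlation of line means
    standardized by the square roots of the line-mean heritabilities;
    clamped to [-1, 1].
    """
    if vc_j.h2 <= 0 or vc_jp.h2 <= 0:
        raise ValueError("genetic correlation undefined at zero heritability")
    common = means_j.means.index.intersection(means_jp.means.index)
    if len(common) < 3:
        raise ValueError("need >= 3 common lines")
    r_p = float(
        np.corrcoef(means_j.means.loc[common], means_jp.means.loc[common])[0, 1]
    )
    r_g = r_p / (np.sqrt(vc_j.h2) * np.sqrt(vc_jp.h2))
    return float(np.clip(r_g, -1.0, 1.0))


# ----------------------------------------------------------------------
# Combined ANOVA
# ----------------------------------------------------------------------
def _sequential_anova(
    data: pd.DataFrame, response: str, terms: list[tuple[str, list[str]]]
) -> AnovaTable:
    """Sequential (type I) fixed-effects ANOVA by incremental projection.

    ``terms`` lists (label, factor columns); an entry with two columns is
    their interaction / nesting. SS are computed from residual drops of
    successive least-squares fits on dummy-coded designs.
    """
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    total_ss = float(((y - y.mean()) ** 2).sum())
    X = np.ones((n, 1))
    rss_prev = total_ss
    df_prev = n - 1
    rows = []
    for label, cols in terms:
        if len(cols) == 1:
            codes = pd.Categorical(data[cols[0]]).codes
        else:
            inter = data[cols[0]].astype(str) + "\x1f" + data[cols[1]].astype(str)
            codes = pd.Categorical(inter).codes
        dummies = np.zeros((n, codes.max() + 1))
        dummies[np.arange(n), codes] = 1.0
        X = np.column_stack([X, dummies])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        df = df_prev - (n - rank)
        rows.append((label, df, max(rss_prev - rss, 0.0)))
        rss_prev, df_prev = rss, n - rank
    df_err = df_prev
    rows.append(("error", df_err, rss_prev))
    tab = pd.DataFrame(rows, columns=["source", "df", "SS"])
    mse = rss_prev / df_err if df_err > 0 else np.nan
    tab["MS"] = tab["SS"] / tab["df"].replace(0, np.nan)
    tab["F"] = np.where(tab["source"] == "error", np.nan, tab["MS"] / mse)
    tab["p"] = [
        np.nan
        if src == "error" or df <= 0
        else float(scipy.stats.f.sf(f_val, df, df_err))
        for src, df, f_val in zip(tab["source"], tab["df"], tab["F"])
    ]
    total = pd.DataFrame(
        [("total", n - 1, total_ss, np.nan, np.nan, np.nan)],
        columns=["source", "df", "SS", "MS", "F", "p"],
    )
    return AnovaTable(pd.concat([tab, total], ignore_index=True))


def combined_anova(plots: pd.DataFrame, trait: str = "yield") -> AnovaTable:
    """Combined fixed-effects ANOVA across environments.

    Sources, in sequential order: environment, block within environment,
    genotype (line), genotype x environment, error. Every line must be
    present in every environment.
    """
    envs = plots["env"].unique()
    if len(envs) < 2:
        raise ValueError("combined ANOVA needs >= 2 environments")
    cells = plots.groupby(["line", "env"]).size().unstack()
    missing = [
        (line, env)
        for line in cells.index
        for env in cells.columns
        if pd.isna(cells.loc[line, env])
    ]
    if missing:
        raise ValueError(f"missing (line, environment) cells: {missing[:10]}")
    return _sequential_anova(
        plots,
        trait,
        [
            ("environment", ["env"]),
            ("block(environment)", ["env", "block"]),
            ("genotype", ["line"]),
            ("genotype:environment", ["line", "env"]),
        ],
    )


# ----------------------------------------------------------------------
# Hartley's F-max
# ----------------------------------------------------------------------
def hartley_fmax(
    error_variances: list[float],
    df: int,
    n_mc: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Hartley's variance-homogeneity test: F_max = max / min variance.

    The p-value comes from a seeded Monte-Carlo null (independent
    chi-square variances with ``df`` degrees of freedom each).
    """
    v = np.asarray(error_variances, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 error variances")
    if (v < 0).any():
        raise ValueError("variances must be non-negative")
    if v.min() == 0:
        return float("inf"), 0.0
    stat = float(v.max() / v.min())
    rng = np.random.default_rng(seed)
    draws = rng.chisquare(df, size=(n_mc, len(v))) / df
    null = draws.max(axis=1) / draws.min(axis=1)
    p = float((null >= stat).mean())
    return stat, p


# ----------------------------------------------------------------------
# Line-group comparison (selection experiments)
# ----------------------------------------------------------------------
def _dunnett_critical(
    m_groups: np.ndarray, m_parent: float, df_err: int, alpha: float,
    n_mc: int, rng: np.random.Generator,
) -> float:
    """Two-sided Dunnett critical value by Monte Carlo.

    Simulates the joint null of the k contrast t-statistics (shared
    control mean and shared error variance estimate) and returns the
    1-alpha quantile of max |t|.
    """
    k = len(m_groups)
    s = np.sqrt(rng.chisquare(df_err, size=n_mc) / df_err)
    zg = rng.standard_normal((n_mc, k)) / np.sqrt(m_groups)[None, :]
    z0 = rng.standard_normal(n_mc) / np.sqrt(m_parent)
    t = (zg - z0[:, None]) / (
        s[:, None] * np.sqrt(1.0 / m_groups + 1.0 / m_parent)[None, :]
    )
    return float(np.quantile(np.abs(t).max(axis=1), 1.0 - alpha))


def compare_line_groups(
    plots: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    parents: set[str] | list[str],
    trait: str = "yield",
    use_population_factor: bool = False,
    n_mc: int = 100_000,
    seed: int = 0,
) -> GroupComparison:
    """Compare selected line groups and contrast each against the parents.

    ``groups`` maps line id -> group label for the selected lines; lines in
    ``parents`` form the reference group. The data must be a single-
    environment randomized-complete-block trial containing all these
    lines.

    Two ANOVAs are run: one on selected lines only (group, optional
    population, line within group, block), and one including the parents
    as an additional group (group, line within group, block). The LSD at
    p < 0.05 uses the harmonic mean of plots per group; Dunnett contrasts
    use a seeded Monte-Carlo critical value of the max-|t| null.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    parents = set(parents)
    if parents & set(groups.index):
        raise ValueError("parent lines must not appear in a selected group")
    if plots["env"].nunique() != 1:
        raise ValueError("group comparison expects a single-environment trial")
    sizes = groups.value_counts()
    if (sizes == 1).any():
        warnings.warn(
            f"groups with a single line: {list(sizes.index[sizes == 1])}",
            stacklevel=2,
        )

    sel = plots[plots["line"].isin(groups.index)].copy()
    sel["group"] = groups.loc[sel["line"]].to_numpy()
    terms = [("group", ["group"])]
    if use_population_factor:
        terms.append(("population", ["population"]))
    terms += [("line(group)", ["line"]), ("block", ["block"])]
    anova_sel = _sequential_anova(sel, trait, terms)

    full = plots[plots["line"].isin(set(groups.index) | parents)].copy()
    lab = groups.reindex(full["line"])
    full["group"] = np.where(
        full["line"].isin(parents), "parents", lab.to_numpy()
    )
    anova_full = _sequential_anova(
        full, trait, [("group", ["group"]), ("line(group)", ["line"]), ("block", ["block"])]
    )
    err = anova_full.row("error")
    mse, df_err = float(err["MS"]), int(err["df"])

    group_means = full.groupby("group")[trait].mean()
    plots_per_group = full.groupby("group").size()
    sel_groups = [g for g in group_means.index if g != "parents"]
    m_sel = plots_per_group.loc[sel_groups].to_numpy(dtype=float)
    m_har = len(m_sel) / np.sum(1.0 / m_sel)
    lsd_05 = float(
        scipy.stats.t.ppf(0.975, df_err) * np.sqrt(2.0 * mse / m_har)
    )

    rng = np.random.default_rng(seed)
    m_parent = float(plots_per_group.loc["parents"])
    crit = {
        alpha: _dunnett_critical(m_sel, m_parent, df_err, alpha, n_mc, rng)
        for alpha in (0.05, 0.01)
    }
    diffs = group_means.loc[sel_groups] - group_means.loc["parents"]
    t_stats = diffs / np.sqrt(mse * (1.0 / m_sel + 1.0 / m_parent))
    dunnett = pd.DataFrame(
        {
            "diff_to_parents": diffs,
            "t": t_stats,
            "sig_05": np.abs(t_stats) > crit[0.05],
            "sig_01": np.abs(t_stats) > crit[0.01],
        }
    )
    return GroupComparison(
        anova_selected=anova_sel,
        anova_with_parents=anova_full,
        group_means=group_means,
        lsd_05=lsd_05,
        dunnett=dunnett,
        dunnett_critical=crit,
    )
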