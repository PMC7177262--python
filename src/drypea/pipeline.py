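"""End-to-end study pipeline.

``run_study`` replays the whole analysis on simulated data from one
seeded configuration: simulate connected RIL populations -> genotype QC
and imputation -> per-environment variance components, BLUPs and genetic
correlations -> combined ANOVA, error-homogeneity test and AMMI with the
axis F test -> genomic prediction model evaluation (intra-environment,
cross-environment and cross-population schemes) -> predicted-gain
comparison of phenotypic vs genomic selection -> proof-of-concept
truncation selections (phenotypic, genomic, marker-assisted) on a
held-out line set, evaluated by a fresh simulated trial and a
group-comparison ANOVA against the parent lines.

Every intermediate table is written to the run directory; a summary JSON
collects the headline numbers. The run is reproducible from the seed.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from drypea import ammi as ammi_mod
from drypea import evaluate as ev
from drypea import gains as gains_mod
from drypea import phenostats as ps
from drypea.genotypes import GenotypeMatrix
from drypea.gsmodels import ChainConfig, fit_bayesian_lasso, fit_rrblup, predict
from drypea.qc import filter_markers, knn_impute
from drypea.simulate import (
    SimulatedStudy,
    StudyProfile,
    default_mas_panel,
    simulate_study,
    simulate_trials,
)

__all__ = ["RunConfig", "run_study"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full study run."""

    seed: int = 0
    profile: StudyProfile = field(default_factory=StudyProfile)
    maf_min: float = 0.025
    missing_max: float = 0.2
    knn_k: int = 4
    models: tuple[str, ...] = ("rrblup", "bayesian_lasso")
    cv_folds: int = 10
    cv_reps_rrblup: int = 5
    cv_reps_bl: int = 2
    bl_chain: ChainConfig = field(default_factory=lambda: ChainConfig(4_000, 1_000, 5))
    holdout_per_population: int = 30
    n_selected: int = 3
    outdir: str | Path = "drypea_run"

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min <= 1 or not 0 <= self.missing_max <= 1:
            raise ValueError("QC thresholds must be in [0, 1]")
        if self.holdout_per_population >= min(self.profile.family_sizes):
            raise ValueError("holdout would leave no training lines in some population")
        if self.n_selected > self.holdout_per_population:
            raise ValueError("cannot select more lines than the holdout provides")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        profile = StudyProfile.from_dict(raw.pop("profile", {}))
        chain = raw.pop("bl_chain", None)
        kw = dict(raw)
        kw["profile"] = profile
        if chain is not None:
            kw["bl_chain"] = ChainConfig(**chain)
        if "models" in kw:
            kw["models"] = tuple(kw["models"])
        return cls(**kw)


def _stage(name: str, t0: float) -> float:
    t1 = time.time()
    logger.info("stage %-22s %6.1f s", name, t1 - t0)
    return t1


def run_study(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns the summary dict (also written to
    ``<outdir>/summary.json``)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    summary: dict = {"seed": cfg.seed, "schemes": []}
    t_start = time.time()
    t0 = t_start

    # ------------------------------------------------ simulation
    study: SimulatedStudy = simulate_study(cfg.profile, seed=cfg.seed)
    envs = study.trait_model.environments
    ms_env, severe_env, moderate_env = envs
    study.genotypes_observed.to_vcf(out / "genotypes_observed.vcf")
    study.plots.to_csv(out / "plots.csv", index=False)
    study.true_values.to_csv(out / "true_genetic_values.csv")
    t0 = _stage("simulate", t0)

    # ------------------------------------------------ QC + imputation
    g_filt, report = filter_markers(
        study.genotypes_observed, maf_min=cfg.maf_min, missing_max=cfg.missing_max
    )
    report.to_frame().to_csv(out / "filter_report.csv", index=False)
    g_imp = knn_impute(g_filt, k=cfg.knn_k)
    g_imp.to_table(out / "genotypes_imputed.tsv")
    summary["qc"] = {
        "markers_input": report.n_input,
        "markers_retained": report.n_retained,
    }
    t0 = _stage("qc", t0)

    # ------------------------------------------------ phenotype statistics
    varcomps: dict[str, ps.VarComp] = {}
    blups: dict[str, ps.LineMeans] = {}
    for env in envs:
        vc = ps.fit_varcomp(study.plots, env, "yield")
        lm = ps.blup_line_values(ps.line_means(study.plots, env, "yield"), vc)
        varcomps[env] = vc
        blups[env] = lm
    pd.DataFrame(
        {
            env: {
                "sigma2_g": vc.sigma2_g,
                "sigma2_e": vc.sigma2_e,
                "r": vc.r,
                "h2": vc.h2,
                "sigma_p": vc.sigma_p,
            }
            for env, vc in varcomps.items()
        }
    ).T.to_csv(out / "variance_components.csv")
    pd.DataFrame({env: lm.blup for env, lm in blups.items()}).to_csv(out / "blups.csv")

    rg = {
        f"{a}:{b}": ps.genetic_correlation(blups[a], blups[b], varcomps[a], varcomps[b])
        for a, b in itertools.combinations(envs, 2)
    }
    summary["heritability"] = {env: vc.h2 for env, vc in varcomps.items()}
    summary["genetic_correlation"] = rg

    anova = ps.combined_anova(study.plots, "yield")
    anova.table.to_csv(out / "combined_anova.csv", index=False)
    fmax, fmax_p = ps.hartley_fmax(
        [varcomps[e].sigma2_e for e in envs],
        df=min((vc.n_lines - 1) * (vc.r - 1) for vc in varcomps.values()),
        seed=int(rng.integers(2**31)),
    )
    summary["hartley"] = {"f_max": fmax, "p": fmax_p}
    t0 = _stage("phenostats", t0)

    # ------------------------------------------------ AMMI
    cell_means = pd.DataFrame({env: blups[env].means for env in envs})
    err = anova.row("error")
    r_list = [study.trait_model.replications[e] for e in envs]
    r_harm = len(r_list) / sum(1.0 / r for r in r_list)
    fit = ammi_mod.fit_ammi(
        cell_means,
        pooled_error_ms=float(err["MS"]),
        error_df=int(err["df"]),
        n_blocks=r_harm,
    )
    axis_rows = []
    for axis in range(1, fit.n_axes + 1):
        f_val, dfn, dfd, p = ammi_mod.fr_test(fit, axis)
        axis_rows.append((axis, fit.axis_ss[axis - 1], f_val, dfn, dfd, p))
    pd.DataFrame(
        axis_rows, columns=["axis", "ss", "F_R", "df_num", "df_den", "p"]
    ).to_csv(out / "ammi_axes.csv", index=False)
    nominal, responses = ammi_mod.nominal_yields(fit)
    nominal.to_csv(out / "nominal_yields.csv")
    responses.to_csv(out / "nominal_responses.csv")
    summary["ammi_significant_axes"] = ammi_mod.significant_axes(fit)
    t0 = _stage("ammi", t0)

    # ------------------------------------------------ traits for GS
    traits = {f"yield_{env}": blups[env].blup for env in envs}
    traits["yield_severe_mean"] = (blups[ms_env].blup + blups[severe_env].blup) / 2.0
    pd.DataFrame(traits).to_csv(out / "gs_traits.csv")

    # ------------------------------------------------ intra-environment CV
    cv_rows = []
    cv_results: dict[tuple[str, str, str], ev.CVResult] = {}
    for model in cfg.models:
        reps = cfg.cv_reps_rrblup if model == "rrblup" else cfg.cv_reps_bl
        for trait_name, trait_vals in traits.items():
            for training in ("pooled", "per_population"):
                if training == "per_population" and trait_name != "yield_severe_mean":
                    continue  # the pooled-vs-separate contrast needs one trait
                cv = ev.cross_validate(
                    g_imp,
                    trait_vals,
                    model=model,
                    cfg=ev.CVConfig(
                        folds=cfg.cv_folds,
                        repetitions=reps,
                        seed=int(rng.integers(2**31)),
                        training=training,
                        bl_chain=cfg.bl_chain,
                    ),
                )
                cv_results[(model, trait_name, training)] = cv
                cv_rows.append((model, trait_name, training, cv.r_ab))
                summary["schemes"].append(f"intra-env/{trait_name}/{model}/{training}")
    cv_table = pd.DataFrame(cv_rows, columns=["model", "trait", "training", "r_ab"])
    cv_table.to_csv(out / "cv_intra_env.csv", index=False)
    summary["cv_intra_env"] = cv_table.to_dict("records")
    t0 = _stage("cv-intra", t0)

    # ------------------------------------------------ cross-environment
    xenv_rows = []
    for train_env, valid_env in itertools.permutations(envs, 2):
        r_ab, r_ac = ev.cross_environment_predict(
            g_imp,
            blups[train_env].blup,
            blups[valid_env].blup,
            h2_valid=varcomps[valid_env].h2,
            model="rrblup",
            seed=int(rng.integers(2**31)),
        )
        xenv_rows.append((train_env, valid_env, r_ab, r_ac))
        summary["schemes"].append(f"cross-env/{train_env}->{valid_env}/rrblup")
    xenv = pd.DataFrame(xenv_rows, columns=["train_env", "valid_env", "r_ab", "r_ac"])
    xenv.to_csv(out / "cv_cross_env.csv", index=False)
    summary["cv_cross_env"] = xenv.to_dict("records")
    t0 = _stage("cross-env", t0)

    # ------------------------------------------------ cross-population
    xpop_rows = []
    for trait_name in ("yield_severe_mean", f"yield_{moderate_env}"):
        for n_train in (1, 2):
            scan = ev.cross_population_scan(
                g_imp, traits[trait_name], n_train, model="rrblup",
                seed=int(rng.integers(2**31)),
            )
            xpop_rows.append((trait_name, n_train, scan.r_ab))
            summary["schemes"].append(f"cross-pop/{trait_name}/{n_train}-train/rrblup")
            scan.detail.assign(trait=trait_name, n_train=n_train).to_csv(
                out / f"cv_cross_pop_{trait_name}_{n_train}train.csv", index=False
            )
    xpop = pd.DataFrame(xpop_rows, columns=["trait", "n_train", "r_ab"])
    xpop.to_csv(out / "cv_cross_pop.csv", index=False)
    summary["cv_cross_pop"] = xpop.to_dict("records")
    t0 = _stage("cross-pop", t0)

    # ------------------------------------------------ predicted gains
    best_model = cfg.models[0]
    gain_rows = []
    for env in envs:
        vc = varcomps[env]
        r_ab = cv_results[(best_model, f"yield_{env}", "pooled")].r_ab
        scenario = gains_mod.GainScenario(
            h2_target=vc.h2,
            sigma_p=vc.sigma_p,
            h2_selection=varcomps[ms_env].h2,
            r_g=rg.get(f"{ms_env}:{env}", rg.get(f"{env}:{ms_env}")),
            r_ab=r_ab,
        )
        dg_ps = gains_mod.gain_direct_ps(scenario)
        dg_gs, er_gs = gains_mod.gain_gs(scenario)
        if env != ms_env:
            dg_ind, er_ind = gains_mod.gain_indirect_ps(scenario)
        else:
            dg_ind, er_ind = np.nan, np.nan
        gain_rows.append((env, vc.h2, vc.sigma_p, r_ab, dg_ps, dg_ind, er_ind, dg_gs, er_gs))
    gains_table = pd.DataFrame(
        gain_rows,
        columns=[
            "env", "h2", "sigma_p", "r_ab", "gain_direct_ps",
            "gain_indirect_ps", "er_indirect_ps", "gain_gs", "er_gs",
        ],
    )
    gains_table.to_csv(out / "predicted_gains.csv", index=False)
    summary["predicted_gains"] = gains_table.to_dict("records")
    t0 = _stage("gains", t0)

    # ------------------------------------------------ proof-of-concept selection
    pops = study.genotypes_true.populations
    holdout: list[str] = []
    sel_rng = np.random.default_rng(int(rng.integers(2**31)))
    for pop in sorted(pops.unique()):
        lines = list(pops.index[pops == pop])
        holdout += list(sel_rng.choice(lines, size=cfg.holdout_per_population, replace=False))
    training_lines = [l for l in study.genotypes_true.line_ids if l not in set(holdout)]
    if set(holdout) & set(training_lines):
        raise ValueError("holdout overlaps training lines")

    mean_trait = traits["yield_severe_mean"]
    g_train = g_imp.subset(lines=[l for l in training_lines if l in g_imp.line_ids])
    g_hold = g_imp.subset(lines=[l for l in holdout if l in g_imp.line_ids])
    hold_pops = g_hold.populations

    fit_pooled = (
        fit_rrblup(g_train, mean_trait.loc[g_train.line_ids])
        if best_model == "rrblup"
        else fit_bayesian_lasso(
            g_train, mean_trait.loc[g_train.line_ids],
            ChainConfig(seed=int(rng.integers(2**31))),
        )
    )
    gebv_pooled = predict(fit_pooled, g_hold)
    fit_pooled.to_json(out / "gs_model_pooled.json")

    gebv_perpop = pd.Series(np.nan, index=g_hold.line_ids)
    for pop in sorted(pops.unique()):
        tr = [l for l in g_train.line_ids if pops.loc[l] == pop]
        te = [l for l in g_hold.line_ids if pops.loc[l] == pop]
        fit_pop = fit_rrblup(g_train.subset(lines=tr), mean_trait.loc[tr])
        gebv_perpop.loc[te] = predict(fit_pop, g_hold.subset(lines=te))

    criteria = {
        "ps_ms": blups[ms_env].means.loc[holdout],
        "ps_severe": blups[severe_env].means.loc[holdout],
        "ps_mean": ((blups[ms_env].means + blups[severe_env].means) / 2).loc[holdout],
        "gs_pooled": gebv_pooled,
        "gs_per_population": gebv_perpop,
    }
    # the five selections are grown in one trial, so a line picked by
    # several criteria is charged to the first and later criteria take
    # their next-ranked line instead (groups stay disjoint with
    # n_selected lines per population each)
    groups: dict[str, str] = {}
    selections: dict[str, list[str]] = {}
    for crit, scores in criteria.items():
        chosen: list[str] = []
        for pop in sorted(hold_pops.unique()):
            lines = hold_pops.index[hold_pops == pop]
            ranked = scores.loc[lines].sort_index().sort_values(
                ascending=False, kind="stable"
            )
            picked = 0
            for line in ranked.index:
                if line not in groups:
                    groups[line] = crit
                    chosen.append(line)
                    picked += 1
                    if picked == cfg.n_selected:
                        break
        selections[crit] = chosen
    pd.Series(
        {line: crit for crit, lines in selections.items() for line in lines}
    ).rename("criterion").to_csv(out / "selections.csv")

    # marker-assisted selection on the first population's holdout; the
    # diagnostic panel is scored on dedicated (complete) genotype calls
    # rather than the GBS matrix, whose QC may drop panel markers
    panel = default_mas_panel(study.trait_model)
    panel.to_frame().to_csv(out / "mas_panel.csv", index=False)
    first_pop = sorted(pops.unique())[0]
    mas_lines = [l for l in g_hold.line_ids if hold_pops.loc[l] == first_pop]
    mas = gains_mod.mas_score(study.genotypes_true.subset(lines=mas_lines), panel)
    mas.to_csv(out / "mas_scores.csv")
    summary["mas"] = {
        "n_top": int((mas["group"] == "top").sum()),
        "n_bottom": int((mas["group"] == "bottom").sum()),
    }

    # evaluate the selections in a fresh severe-stress trial with parents
    selected_set = sorted(set(groups))
    parent_hap = study.founders.haplotypes
    parent_ids = [f"parent_{f}" for f in parent_hap.index]
    parent_calls = pd.DataFrame(
        2.0 * parent_hap.to_numpy(), index=parent_ids, columns=parent_hap.columns
    )
    eval_calls = pd.concat(
        [study.genotypes_true.calls.loc[selected_set], parent_calls]
    )
    eval_pops = pd.concat(
        [pops.loc[selected_set], pd.Series("parents", index=parent_ids)]
    )
    g_eval = GenotypeMatrix(eval_calls, eval_pops, study.genotypes_true.positions)
    # the evaluation trial reuses the study's plot-error scale rather than
    # re-deriving it from the (selection-shifted) genetic variance
    tm_eval = study.trait_model
    if tm_eval.error_sd is None:
        main_vc = {e: varcomps[e] for e in envs}
        tm_eval = _with_error_sd(tm_eval, {e: float(np.sqrt(main_vc[e].sigma2_e)) for e in envs})
    trial = simulate_trials(g_eval, tm_eval, seed=int(rng.integers(2**31)))
    exp_plots = trial.plots[trial.plots["env"] == ms_env]
    comparison = ps.compare_line_groups(
        exp_plots,
        groups=groups,
        parents=set(parent_ids),
        trait="yield",
        seed=int(rng.integers(2**31)),
    )
    comparison.anova_with_parents.table.to_csv(
        out / "selection_anova.csv", index=False
    )
    comparison.group_means.rename("mean_yield").to_csv(
        out / "selection_group_means.csv"
    )
    comparison.dunnett.to_csv(out / "selection_dunnett.csv")
    summary["selection_experiment"] = {
        "group_means": comparison.group_means.to_dict(),
        "lsd_05": comparison.lsd_05,
        "criteria": sorted(criteria),
        "gains_over_parents": comparison.dunnett["diff_to_parents"].to_dict(),
    }
    t0 = _stage("selection", t0)

    summary["runtime_s"] = round(time.time() - t_start, 1)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary


def _with_error_sd(tm, error_sd: dict[str, float]):
    """Copy of a trait model with explicit per-environment plot-error SDs."""
    from dataclasses import replace

    return replace(tm, error_sd=error_sd)
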