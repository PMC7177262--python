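"""Predictive-ability estimation for genomic selection models.

Predictive ability r_Ab is the Pearson correlation between observed and
predicted phenotypes, always computed within each population (to avoid
the bias of population mean differences) and then averaged over
cross-validation repetitions and populations. Predictive accuracy
readjusts it by the line-mean heritability of the validated environment,
r_Ac = r_Ab / H_j.

Three schemes are provided: repeated stratified cross-validation within
an environment, cross-environment prediction (train in one environment,
validate the same lines in another), and cross-population prediction
(train on one or two connected populations, validate on a disjoint one).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from drypea.genotypes import GenotypeMatrix
from drypea.gsmodels import ChainConfig, fit_bayesian_lasso, fit_rrblup, predict

__all__ = [
    "CVConfig",
    "CVResult",
    "cross_validate",
    "cross_environment_predict",
    "cross_population_predict",
    "cross_population_scan",
    "prediction_loss",
]


def prediction_loss(r_reference: float, r_transfer: float) -> float:
    """Fractional loss of predictive ability relative to a reference
    scheme, (r_ref - r_transfer) / r_ref — e.g. intra-population CV
    versus cross-population prediction."""
    if r_reference == 0:
        raise ValueError("reference predictive ability must be non-zero")
    return (r_reference - r_transfer) / r_reference

#: Reduced chain used for the Bayesian Lasso inside cross-validation
#: (full-length chains are unnecessary for fold-level point predictions
#: and would dominate the cost of 50 x 10 folds).
CV_BL_CHAIN = ChainConfig(iterations=4_000, burn_in=1_000, thin=5)


@dataclass
class CVConfig:
    """Repeated stratified cross-validation settings."""

    folds: int = 10
    repetitions: int = 50
    seed: int = 0
    training: str = "pooled"  # "pooled" | "per_population"
    center_populations: bool = False  # center phenotypes per population before pooling
    bl_chain: ChainConfig | None = None

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need >= 2 folds")
        if self.training not in ("pooled", "per_population"):
            raise ValueError("training must be 'pooled' or 'per_population'")


@dataclass
class CVResult:
    """Per-population predictive abilities and their pooled summary."""

    scheme: str
    model: str
    per_repetition: pd.DataFrame  # columns: repetition, population, r_ab
    r_ab: float  # mean over repetitions, then over populations
    r_ab_by_population: pd.Series = field(default_factory=pd.Series)
    r_ac: float | None = None
    detail: pd.DataFrame | None = None  # scheme-specific breakdown


def _fit_model(model: str, genotypes: GenotypeMatrix, phenotypes: pd.Series,
               bl_chain: ChainConfig | None, seed: int):
    if model == "rrblup":
        return fit_rrblup(genotypes, phenotypes)
    if model == "bayesian_lasso":
        base = bl_chain or CV_BL_CHAIN
        cfg = ChainConfig(
            iterations=base.iterations,
            burn_in=base.burn_in,
            thin=base.thin,
            seed=seed,
            lambda2_shape=base.lambda2_shape,
            lambda2_rate=base.lambda2_rate,
            fixed_lambda2=base.fixed_lambda2,
        )
        return fit_bayesian_lasso(genotypes, phenotypes, cfg)
    raise ValueError(f"unknown model kind {model!r}")


def _within_population_r(observed: pd.Series, predicted: pd.Series,
                         populations: pd.Series) -> pd.Series:
    out = {}
    for pop in populations.unique():
        lines = populations.index[populations == pop]
        lines = lines.intersection(observed.index)
        o = observed.loc[lines].to_numpy()
        p = predicted.loc[lines].to_numpy()
        if len(lines) < 3 or np.std(o) == 0 or np.std(p) == 0:
            out[pop] = np.nan
        else:
            out[pop] = float(np.corrcoef(o, p)[0, 1])
    return pd.Series(out).sort_index()


def _stratified_folds(populations: pd.Series, folds: int,
                      rng: np.random.Generator) -> pd.Series:
    """Fold label per line; each population spread over every fold."""
    fold_of = {}
    for pop in sorted(populations.unique()):
        lines = list(populations.index[populations == pop])
        if len(lines) < folds:
            raise ValueError(
                f"population {pop!r} has {len(lines)} lines, fewer than {folds} folds"
            )
        order = rng.permutation(len(lines))
        for pos, idx in enumerate(order):
            fold_of[lines[idx]] = pos % folds
    return pd.Series(fold_of).reindex(populations.index)


def cross_validate(
    genotypes: GenotypeMatrix,
    phenotypes: pd.Series,
    model: str = "rrblup",
    cfg: CVConfig | None = None,
) -> CVResult:
    """Repeated population-stratified k-fold cross-validation.

    Every repetition partitions each population's lines over the folds;
    models are refit on the training portion of each fold (pooled across
    populations, or separately per population). r_Ab is the
    within-population correlation of observed and predicted phenotypes,
    computed per fold and averaged over folds, then over repetitions and
    populations.
    """
    cfg = cfg or CVConfig()
    pheno = phenotypes.dropna()
    g = genotypes.subset(lines=[l for l in genotypes.line_ids if l in pheno.index])
    pops = g.populations
    rng = np.random.default_rng(cfg.seed)
    records = []
    for rep in range(cfg.repetitions):
        fold_of = _stratified_folds(pops, cfg.folds, rng)
        # observed-predicted correlation is computed within each fold (and
        # population) and averaged: pooling predictions of different fold
        # models first would mix their offsets into the correlation and
        # biases a signal-free model's r_Ab negative
        fold_r: dict[str, list[float]] = {p: [] for p in pops.unique()}
        for fold in range(cfg.folds):
            test_lines = fold_of.index[fold_of == fold]
            train_lines = fold_of.index[fold_of != fold]
            predicted = pd.Series(np.nan, index=test_lines)
            if cfg.training == "pooled":
                y_train = pheno.loc[train_lines]
                if cfg.center_populations:
                    mean_by_pop = y_train.groupby(pops.loc[train_lines]).transform("mean")
                    y_train = y_train - mean_by_pop + y_train.mean()
                fit = _fit_model(
                    model, g.subset(lines=train_lines), y_train,
                    cfg.bl_chain, seed=int(rng.integers(2**31)),
                )
                predicted.loc[test_lines] = predict(fit, g.subset(lines=test_lines))
            else:
                for pop in pops.unique():
                    tr = [l for l in train_lines if pops.loc[l] == pop]
                    te = [l for l in test_lines if pops.loc[l] == pop]
                    if not te:
                        continue
                    fit = _fit_model(
                        model, g.subset(lines=tr), pheno.loc[tr],
                        cfg.bl_chain, seed=int(rng.integers(2**31)),
                    )
                    predicted.loc[te] = predict(fit, g.subset(lines=te))
            r_by_pop = _within_population_r(
                pheno.loc[test_lines], predicted, pops.loc[test_lines]
            )
            for pop, r in r_by_pop.items():
                if not np.isnan(r):
                    fold_r[pop].append(r)
        for pop, values in fold_r.items():
            records.append((rep, pop, float(np.mean(values)) if values else np.nan))
    per_rep = pd.DataFrame(records, columns=["repetition", "population", "r_ab"])
    by_pop = per_rep.groupby("population")["r_ab"].mean()
    return CVResult(
        scheme=f"intra-env/{cfg.training}",
        model=model,
        per_repetition=per_rep,
        r_ab=float(by_pop.mean()),
        r_ab_by_population=by_pop,
    )


def cross_environment_predict(
    genotypes: GenotypeMatrix,
    train_phenotypes: pd.Series,
    valid_phenotypes: pd.Series,
    h2_valid: float,
    model: str = "rrblup",
    bl_chain: ChainConfig | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Train in one environment, validate the same lines in another.

    The model is fit on all lines' phenotypes from the training
    environment; its predictions are correlated per population with the
    same lines' phenotypes in the validation environment. Returns
    (r_Ab, r_Ac) with r_Ac = r_Ab / sqrt(H_j^2) for the validated
    environment.
    """
    if not 0 < h2_valid <= 1:
        raise ValueError("validation-environment heritability must be in (0, 1]")
    train = train_phenotypes.dropna()
    valid = valid_phenotypes.dropna()
    if set(train.index) != set(valid.index):
        raise ValueError("training and validation environments must share the same lines")
    g = genotypes.subset(lines=[l for l in genotypes.line_ids if l in train.index])
    fit = _fit_model(model, g, train, bl_chain, seed)
    gebv = predict(fit, g)
    r_by_pop = _within_population_r(valid, gebv, g.populations)
    r_ab = float(r_by_pop.mean())
    return r_ab, r_ab / float(np.sqrt(h2_valid))


def cross_population_predict(
    genotypes: GenotypeMatrix,
    phenotypes: pd.Series,
    training_populations: list[str],
    validation_population: str,
    model: str = "rrblup",
    bl_chain: ChainConfig | None = None,
    seed: int = 0,
) -> float:
    """r_Ab of a model trained on other population(s) for one population."""
    if validation_population in training_populations:
        raise ValueError("validation population overlaps the training set")
    pops = genotypes.populations
    train_lines = pops.index[pops.isin(training_populations)]
    valid_lines = pops.index[pops == validation_population]
    if len(train_lines) == 0 or len(valid_lines) == 0:
        raise ValueError("empty training or validation population")
    pheno = phenotypes.dropna()
    train_lines = [l for l in train_lines if l in pheno.index]
    valid_lines = [l for l in valid_lines if l in pheno.index]
    fit = _fit_model(model, genotypes.subset(lines=train_lines),
                     pheno.loc[train_lines], bl_chain, seed)
    gebv = predict(fit, genotypes.subset(lines=valid_lines))
    o = pheno.loc[valid_lines].to_numpy()
    p = gebv.to_numpy()
    return float(np.corrcoef(o, p)[0, 1])


def cross_population_scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.Series,
    n_training: int,
    model: str = "rrblup",
    bl_chain: ChainConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """All combinations of ``n_training`` training populations (1 or 2)
    against each remaining validation population, with the averaged r_Ab."""
    if n_training not in (1, 2):
        raise ValueError("n_training must be 1 or 2")
    pops = sorted(genotypes.populations.unique())
    if len(pops) < n_training + 1:
        raise ValueError("not enough populations")
    records = []
    for valid in pops:
        rest = [p for p in pops if p != valid]
        for combo in itertools.combinations(rest, n_training):
            r = cross_population_predict(
                genotypes, phenotypes, list(combo), valid, model, bl_chain, seed
            )
            records.append(("+".join(combo), valid, r))
    per = pd.DataFrame(records, columns=["training", "population", "r_ab"])
    by_pop = per.groupby("population")["r_ab"].mean()
    return CVResult(
        scheme=f"cross-pop/{n_training}-train",
        model=model,
        per_repetition=per.assign(repetition=0)[["repetition", "population", "r_ab"]],
        r_ab=float(by_pop.mean()),
        r_ab_by_population=by_pop,
        detail=per,
    )
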