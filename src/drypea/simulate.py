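"""Simulation of connected RIL populations and multi-environment trials.

The generator produces the substrate on which the whole analysis chain can
be exercised with known ground truth: three connected biparental
recombinant-inbred-line (RIL) populations derived from three founders by
single-seed descent, marker data with genotyping-by-sequencing-like
missingness, and plot-level yield / biomass / flowering phenotypes in three
environments with a built-in genotype x environment structure.

The default (reference) study conditions are three families of
96 / 92 / 100 F6 lines from three pairwise crosses, ~600 markers on
7 chromosomes of 120 cM, per-environment line-mean heritabilities of
0.87 / 0.475 / 0.522, a genetic correlation of about 0.5 between the two
severe-stress environments and about 0 with the moderate-stress
environment, a major flowering locus whose early allele raises yield only
under severe stress (drought escape), and five intrinsic-tolerance QTL
regions.

Meiosis uses a no-interference (Haldane) crossover model: the number of
crossovers per chromosome is Poisson with mean length/100 (cM), positions
uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from drypea.genotypes import GenotypeMatrix

__all__ = [
    "GeneticMap",
    "FounderPanel",
    "TraitModel",
    "SimulatedStudy",
    "simulate_ril_population",
    "apply_genotyping_noise",
    "simulate_trials",
    "simulate_study",
    "reference_profile",
    "default_mas_panel",
    "StudyProfile",
]


# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------
@dataclass
class GeneticMap:
    """Linkage map: chromosome lengths (cM) and marker positions.

    ``markers`` is indexed by marker id with columns ``chrom`` and ``cm``.
    """

    chromosomes: list[tuple[str, float]]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if self.markers.index.duplicated().any():
            raise ValueError("marker ids must be unique")
        for chrom, grp in self.markers.groupby("chrom"):
            if chrom not in lengths:
                raise ValueError(f"marker chromosome {chrom!r} not in map")
            if (grp["cm"] < 0).any() or (grp["cm"] > lengths[chrom]).any():
                raise ValueError(f"marker position outside chromosome {chrom!r}")
        present = set(self.markers["chrom"])
        for chrom, _ in self.chromosomes:
            if chrom not in present:
                raise ValueError(f"chromosome {chrom!r} carries no marker")

    @property
    def marker_ids(self) -> pd.Index:
        return self.markers.index

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int = 7,
        length_cm: float = 120.0,
        markers_per_chromosome: int = 100,
    ) -> "GeneticMap":
        """Evenly spaced markers on equal-length chromosomes.

        Defaults give 700 candidate markers, so that a few hundred
        polymorphic low-missingness markers survive quality control — the
        working-set scale typical of GBS on biparental pea material.
        """
        chroms = [(f"chr{i + 1}", length_cm) for i in range(n_chromosomes)]
        recs = []
        step = length_cm / markers_per_chromosome
        for ci, (name, _) in enumerate(chroms):
            for k in range(markers_per_chromosome):
                recs.append((f"m{ci + 1}_{k + 1:03d}", name, round((k + 0.5) * step, 4)))
        markers = pd.DataFrame(recs, columns=["id", "chrom", "cm"]).set_index("id")
        return cls(chroms, markers)


@dataclass
class FounderPanel:
    """Fully homozygous founder haplotypes (founders x markers, alleles 0/1)."""

    haplotypes: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.haplotypes.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("founder alleles must be 0/1 (homozygous)")

    @property
    def founder_ids(self) -> pd.Index:
        return self.haplotypes.index

    def segregating(self, founder_a: str, founder_b: str) -> pd.Index:
        hap = self.haplotypes
        diff = hap.loc[founder_a] != hap.loc[founder_b]
        return hap.columns[diff]

    @classmethod
    def random(
        cls, gmap: GeneticMap, founder_ids: Sequence[str] = ("A", "I", "K"), seed: int = 0
    ) -> "FounderPanel":
        rng = np.random.default_rng(seed)
        hap = pd.DataFrame(
            rng.integers(0, 2, size=(len(founder_ids), len(gmap.marker_ids))),
            index=list(founder_ids),
            columns=gmap.marker_ids,
        )
        return cls(hap)


@dataclass
class TraitModel:
    """Generative ground truth for yield, biomass and flowering.

    Yield effects are per alternate allele on centered dosage (a homozygote
    contributes +-a, a residual heterozygote 0, i.e. the mean of the two
    homozygotes). ``h2_target`` drives the plot-error SD: for each
    environment the error variance is set from the realized genetic
    variance so that the line-mean heritability sigma2_g/(sigma2_g +
    sigma2_e/r) hits the target.
    """

    yield_effects: pd.DataFrame  # markers x environments, t/ha per allele
    flowering_effects: pd.Series  # days per allele
    major_flowering_qtl: str
    tolerance_regions: dict[str, list[str]]  # region -> marker ids
    env_means: dict[str, float]  # t/ha
    flowering_base: dict[str, float]  # days from April 1
    replications: dict[str, int]
    h2_target: dict[str, float]
    severe_environments: tuple[str, ...]
    block_sd: float = 0.02
    flowering_error_sd: float = 1.2
    biomass_base: dict[str, float] | None = None
    biomass_yield_slope: float = 2.0
    biomass_error_sd: float = 0.35
    error_sd: dict[str, float] | None = None  # explicit override of h2_target

    def __post_init__(self) -> None:
        if not np.isfinite(self.yield_effects.to_numpy()).all():
            raise ValueError("yield effects must be finite")
        envs = list(self.yield_effects.columns)
        for env in envs:
            if env not in self.env_means or env not in self.replications:
                raise ValueError(f"environment {env!r} lacks mean or replication count")
        for env in self.severe_environments:
            if self.yield_effects.loc[self.major_flowering_qtl, env] == 0:
                raise ValueError("flowering QTL must affect yield under severe stress")
        for env in envs:
            if env not in self.severe_environments:
                if self.yield_effects.loc[self.major_flowering_qtl, env] != 0:
                    raise ValueError(
                        "flowering QTL must not affect yield in moderate-stress environments"
                    )
        if self.biomass_base is None:
            self.biomass_base = {e: 6.0 * m for e, m in self.env_means.items()}

    @property
    def environments(self) -> list[str]:
        return list(self.yield_effects.columns)

    @property
    def qtl_markers(self) -> pd.Index:
        return self.yield_effects.index


@dataclass
class SimulatedStudy:
    """A complete simulated data set with its generative truth."""

    genotypes_true: GenotypeMatrix
    genotypes_observed: GenotypeMatrix
    plots: pd.DataFrame  # env, block, line, population, yield, biomass, flowering
    true_values: pd.DataFrame  # lines x environments genetic yield values
    true_flowering: pd.Series  # lines, genetic flowering value (env-constant part)
    trait_model: TraitModel
    seed: int
    founders: "FounderPanel | None" = None


# ----------------------------------------------------------------------
# Meiosis and single-seed descent
# ----------------------------------------------------------------------
def _gamete(
    hap_pair: np.ndarray,
    chrom_slices: list[tuple[slice, float, np.ndarray]],
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a diploid individual.

    ``hap_pair`` is (2, n_markers); ``chrom_slices`` holds, per chromosome,
    the marker slice, map length and marker positions (cM).
    """
    out = np.empty(hap_pair.shape[1], dtype=np.int8)
    for sl, length, pos in chrom_slices:
        n_xo = rng.poisson(length / 100.0)
        phase0 = rng.integers(0, 2)
        if n_xo == 0:
            out[sl] = hap_pair[phase0, sl]
            continue
        xo = np.sort(rng.uniform(0.0, length, size=n_xo))
        # phase at a marker flips once per crossover to its left
        flips = np.searchsorted(xo, pos)
        phase = (phase0 + flips) % 2
        seg = hap_pair[:, sl]
        out[sl] = seg[phase, np.arange(seg.shape[1])]
    return out


def _chrom_slices(gmap: GeneticMap) -> list[tuple[slice, float, np.ndarray]]:
    slices = []
    start = 0
    lengths = dict(gmap.chromosomes)
    # markers assumed grouped by chromosome in map order, sorted by position
    order = gmap.markers.sort_values(["chrom", "cm"]).index
    if not order.equals(gmap.marker_ids):
        raise ValueError("map markers must be sorted by chromosome and position")
    for chrom, _ in gmap.chromosomes:
        grp = gmap.markers[gmap.markers["chrom"] == chrom]
        n = len(grp)
        slices.append((slice(start, start + n), lengths[chrom], grp["cm"].to_numpy()))
        start += n
    return slices


def simulate_ril_population(
    founder_a: np.ndarray | pd.Series,
    founder_b: np.ndarray | pd.Series,
    n_lines: int,
    gmap: GeneticMap,
    n_selfing: int = 4,
    seed: int = 0,
    line_prefix: str = "ril",
    population: str = "pop1",
) -> GenotypeMatrix:
    """Simulate an F(2 + n_selfing) RIL family by single-seed descent.

    Each line descends from one F2 individual (a selfed F1) through
    ``n_selfing`` further selfing generations, taking a single offspring
    per generation. With the default ``n_selfing=4`` the lines are F6 and
    the expected residual per-locus heterozygosity is (1/2)^5 ~ 3.1%.

    Calls count the allele-1 dosage; markers where the founders agree stay
    monomorphic.
    """
    if n_selfing < 0:
        raise ValueError("n_selfing must be >= 0")
    fa = np.asarray(founder_a, dtype=np.int8)
    fb = np.asarray(founder_b, dtype=np.int8)
    if fa.shape != fb.shape or fa.shape[0] != len(gmap.marker_ids):
        raise ValueError("founder haplotypes must match the map's marker set")
    if (fa == fb).all():
        raise ValueError("cross does not segregate")
    rng = np.random.default_rng(seed)
    slices = _chrom_slices(gmap)
    f1 = np.stack([fa, fb])
    calls = np.empty((n_lines, fa.shape[0]), dtype=float)
    for i in range(n_lines):
        indiv = f1
        for _ in range(n_selfing + 1):  # F1 -> F2 -> ... single-seed descent
            indiv = np.stack(
                [_gamete(indiv, slices, rng), _gamete(indiv, slices, rng)]
            )
        calls[i] = indiv.sum(axis=0)
    ids = [f"{line_prefix}{i + 1:03d}" for i in range(n_lines)]
    df = pd.DataFrame(calls, index=ids, columns=gmap.marker_ids)
    pops = pd.Series(population, index=df.index)
    return GenotypeMatrix(df, pops, gmap.markers.copy())


# ----------------------------------------------------------------------
# Genotyping noise
# ----------------------------------------------------------------------
def _default_missing_profile(n_markers: int, mean: float, rng: np.random.Generator) -> np.ndarray:
    """Per-marker missing rates emulating GBS.

    Rates are Beta(3, 1.5) scaled to [0, 0.55] and rescaled to the
    requested mean, so that the count of markers passing a missing-rate
    threshold rises steeply between 10% and 50%, as observed for GBS SNP
    sets filtered at increasing allowed-missingness thresholds.
    """
    raw = rng.beta(3.0, 1.5, size=n_markers) * 0.55
    rates = raw * (mean / raw.mean()) if raw.mean() > 0 else raw
    return np.clip(rates, 0.0, 1.0)


def apply_genotyping_noise(
    g: GenotypeMatrix,
    missing_rate_per_marker: float | Sequence[float] | None = 0.33,
    error_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Mask calls at GBS-like per-marker missing rates and flip call errors.

    ``missing_rate_per_marker`` may be a scalar (the mean of the default
    per-marker mixture), an explicit per-marker vector, or None / 0 for no
    masking. Errors replace a call by a random different homozygote.
    """
    if error_rate < 0 or error_rate > 1:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = g.calls.to_numpy().copy()
    n_lines, n_markers = calls.shape
    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        flip &= ~np.isnan(calls)
        # homozygotes flip to the other homozygote; heterozygotes to either
        new = np.where(calls == 0.0, 2.0, 0.0)
        het = calls == 1.0
        new[het] = rng.integers(0, 2, size=int(het.sum())) * 2.0
        calls[flip] = new[flip]
    if missing_rate_per_marker is not None:
        if np.isscalar(missing_rate_per_marker):
            m = float(missing_rate_per_marker)
            if m < 0 or m > 1:
                raise ValueError("missing rate must be in [0, 1]")
            rates = (
                np.zeros(n_markers)
                if m == 0
                else _default_missing_profile(n_markers, m, rng)
            )
        else:
            rates = np.asarray(missing_rate_per_marker, dtype=float)
            if rates.shape != (n_markers,):
                raise ValueError("per-marker missing rates must match marker count")
            if (rates < 0).any() or (rates > 1).any():
                raise ValueError("missing rates must be in [0, 1]")
        mask = rng.random(calls.shape) < rates[None, :]
        calls[mask] = np.nan
    out = pd.DataFrame(calls, index=g.calls.index, columns=g.calls.columns)
    pos = None if g.positions is None else g.positions.copy()
    return GenotypeMatrix(out, g.populations.copy(), pos)


# ----------------------------------------------------------------------
# Field trials
# ----------------------------------------------------------------------
def genetic_values(g: GenotypeMatrix, tm: TraitModel) -> pd.DataFrame:
    """True per-environment genetic yield values (lines x environments)."""
    missing = tm.qtl_markers.difference(g.marker_ids)
    if len(missing):
        raise ValueError(f"QTL markers absent from genotype matrix: {list(missing)}")
    dosage = g.calls[tm.qtl_markers].to_numpy() - 1.0
    if np.isnan(dosage).any():
        raise ValueError("genotypes at QTL markers must be complete")
    gv = dosage @ tm.yield_effects.to_numpy()
    return pd.DataFrame(gv, index=g.line_ids, columns=tm.environments)


def simulate_trials(g: GenotypeMatrix, tm: TraitModel, seed: int = 0) -> SimulatedStudy:
    """Grow the lines in every environment of the trait model.

    Plot value = env mean + genetic value + block effect + plot error, in
    randomized complete blocks with the model's replication counts. The
    plot-error SD is derived per environment from the realized genetic
    variance and the target line-mean heritability, unless ``tm.error_sd``
    overrides it. Flowering has an environment-constant genetic part;
    biomass tracks yield through a fixed slope plus independent error.
    """
    for env, r in tm.replications.items():
        if r < 2:
            raise ValueError(
                f"environment {env!r}: need >= 2 replications for line-mean heritability"
            )
    rng = np.random.default_rng(seed)
    gv = genetic_values(g, tm)
    dosage = g.calls[tm.flowering_effects.index].to_numpy() - 1.0
    flw_g = pd.Series(dosage @ tm.flowering_effects.to_numpy(), index=g.line_ids)
    n = g.n_lines
    records = []
    for env in tm.environments:
        r = tm.replications[env]
        var_g = float(gv[env].var(ddof=1))
        if tm.error_sd is not None and env in tm.error_sd:
            sd_e = tm.error_sd[env]
        else:
            h2 = tm.h2_target[env]
            if not 0 < h2 < 1:
                raise ValueError(f"h2 target for {env!r} must be in (0,1)")
            sd_e = float(np.sqrt(r * var_g * (1.0 - h2) / h2))
        block_eff = rng.normal(0.0, tm.block_sd, size=r)
        for b in range(r):
            y = (
                tm.env_means[env]
                + gv[env].to_numpy()
                + block_eff[b]
                + rng.normal(0.0, sd_e, size=n)
            )
            flw = (
                tm.flowering_base[env]
                + flw_g.to_numpy()
                + rng.normal(0.0, tm.flowering_error_sd, size=n)
            )
            bio = (
                tm.biomass_base[env]
                + tm.biomass_yield_slope * gv[env].to_numpy()
                + block_eff[b]
                + rng.normal(0.0, tm.biomass_error_sd, size=n)
            )
            for i, line in enumerate(g.line_ids):
                records.append(
                    (env, f"b{b + 1}", line, g.populations.loc[line], y[i], bio[i], flw[i])
                )
    plots = pd.DataFrame(
        records,
        columns=["env", "block", "line", "population", "yield", "biomass", "flowering"],
    )
    return SimulatedStudy(
        genotypes_true=g,
        genotypes_observed=g,
        plots=plots,
        true_values=gv,
        true_flowering=flw_g,
        trait_model=tm,
        seed=seed,
    )


# ----------------------------------------------------------------------
# The reference study profile
# ----------------------------------------------------------------------
@dataclass
class StudyProfile:
    """Scalar knobs of a full simulated study (map, families, trait model)."""

    n_chromosomes: int = 7
    chromosome_length_cm: float = 120.0
    markers_per_chromosome: int = 100
    founder_ids: tuple[str, ...] = ("A", "I", "K")
    crosses: tuple[tuple[str, str], ...] = (("A", "I"), ("K", "A"), ("K", "I"))
    family_sizes: tuple[int, ...] = (96, 92, 100)
    n_selfing: int = 4
    mean_missing_rate: float = 0.15
    genotyping_error_rate: float = 0.0
    environments: tuple[str, ...] = ("ms", "severe", "moderate")
    severe_environments: tuple[str, ...] = ("ms", "severe")
    env_means: tuple[float, ...] = (0.32, 0.36, 1.38)
    replications: tuple[int, ...] = (4, 3, 3)
    h2_targets: tuple[float, ...] = (0.87, 0.475, 0.522)
    effect_scale: float = 1.0

    @classmethod
    def from_dict(cls, d: dict) -> "StudyProfile":
        kw = dict(d)
        for key in ("founder_ids", "family_sizes", "environments",
                    "severe_environments", "env_means", "replications", "h2_targets"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "crosses" in kw:
            kw["crosses"] = tuple(tuple(c) for c in kw["crosses"])
        return cls(**kw)


def _reference_trait_model(
    gmap: GeneticMap, founders: FounderPanel, profile: StudyProfile
) -> TraitModel:
    """QTL configuration calibrated to the default study conditions.

    Yield effects (t/ha per allele) are split into a shared block (the
    flowering locus plus five intrinsic-tolerance regions, active in both
    severe-stress environments), severe-environment-specific blocks, and an
    independent moderate-environment block, sized so that the genetic
    correlation between the two severe environments is about 0.5 and about
    0 with the moderate one, and so that the yield-flowering phenotypic
    correlation is strongly negative only under severe stress.
    """
    envs = list(profile.environments)
    ms, sv, md = envs
    by_chrom = {
        c: list(gmap.markers.index[gmap.markers["chrom"] == c])
        for c, _ in gmap.chromosomes
    }

    def pick(chrom_i: int, frac: float) -> str:
        ids = by_chrom[gmap.chromosomes[chrom_i][0]]
        return ids[int(frac * (len(ids) - 1))]

    def neighbor(marker: str) -> str:
        """The next marker on the same chromosome (~1-2 cM away)."""
        chrom = gmap.markers.loc[marker, "chrom"]
        ids = by_chrom[chrom]
        i = ids.index(marker)
        return ids[i + 1] if i + 1 < len(ids) else ids[i - 1]

    s = profile.effect_scale
    flowering_qtl = pick(0, 0.5)
    tolerance = [pick(1, 0.25), pick(1, 0.85), pick(2, 0.3), pick(3, 0.5), pick(4, 0.7)]
    ms_specific = [pick(2, 0.85), pick(5, 0.2), pick(6, 0.3)]
    sv_specific = [pick(3, 0.05), pick(4, 0.15), pick(5, 0.75), pick(6, 0.85)]
    md_specific = [pick(0, 0.05), pick(0, 0.95), pick(1, 0.55), pick(5, 0.5), pick(3, 0.95)]
    flw_minor = [pick(2, 0.6), pick(4, 0.45)]

    hap = founders.haplotypes
    f0, f1, f2 = list(hap.index)[:3]
    # the intrinsic-tolerance loci all segregate in the first cross
    # (f0 x f1), so that an all-favorable and a zero-favorable MAS group
    # can exist within one family; the third founder alternates, keeping
    # the populations connected for these loci
    for k, m in enumerate(tolerance):
        hap.loc[f0, m], hap.loc[f1, m], hap.loc[f2, m] = 1, 0, k % 2
    # two regions carry a second, tightly linked diagnostic marker with the
    # same founder pattern (near-perfect LD in the RILs)
    tol_neighbors = [neighbor(tolerance[0]), neighbor(tolerance[1])]
    for m, q in zip(tol_neighbors, tolerance[:2]):
        hap.loc[:, m] = hap.loc[:, q].to_numpy()
    # remaining QTL: one founder carries the alternate allele, rotating, so
    # each locus segregates in exactly two of the three crosses
    other = [flowering_qtl] + ms_specific + sv_specific + md_specific + flw_minor
    for k, m in enumerate(other):
        pattern = np.zeros(len(hap), dtype=int)
        pattern[k % 3] = 1
        hap.loc[:, m] = pattern

    qtl_all = [flowering_qtl] + tolerance + ms_specific + sv_specific + md_specific + flw_minor
    eff = pd.DataFrame(0.0, index=pd.Index(qtl_all, name="marker"), columns=envs)
    eff.loc[flowering_qtl, ms] = -0.080 * s
    eff.loc[flowering_qtl, sv] = -0.045 * s
    for m in tolerance:
        eff.loc[m, ms] = 0.021 * s
        eff.loc[m, sv] = 0.013 * s
    for m in ms_specific:
        eff.loc[m, ms] = 0.0245 * s
    for m in sv_specific:
        eff.loc[m, sv] = 0.036 * s
    for m in md_specific:
        eff.loc[m, md] = 0.080 * s

    flw_eff = pd.Series(0.0, index=eff.index)
    flw_eff[flowering_qtl] = 2.5
    for m in flw_minor:
        flw_eff[m] = 0.6

    regions = {
        "region1": [tolerance[0], tol_neighbors[0]],
        "region2": [tolerance[1], tol_neighbors[1]],
        "region3": [tolerance[2]],
        "region4": [tolerance[3]],
        "region5": [tolerance[4]],
    }
    return TraitModel(
        yield_effects=eff,
        flowering_effects=flw_eff,
        major_flowering_qtl=flowering_qtl,
        tolerance_regions=regions,
        env_means=dict(zip(envs, profile.env_means)),
        flowering_base={ms: 61.0, sv: 55.0, md: 48.0},
        replications=dict(zip(envs, profile.replications)),
        h2_target=dict(zip(envs, profile.h2_targets)),
        severe_environments=tuple(profile.severe_environments),
    )


def default_mas_panel(tm: TraitModel):
    """The diagnostic marker panel implied by the trait model's
    intrinsic-tolerance regions (favorable allele = the alternate allele,
    which carries the positive yield effect)."""
    from drypea.gains import MASPanel

    markers = {
        m: "alt" for members in tm.tolerance_regions.values() for m in members
    }
    return MASPanel(markers=markers, regions={k: list(v) for k, v in tm.tolerance_regions.items()})


def reference_profile() -> StudyProfile:
    """The default study conditions (see module docstring)."""
    return StudyProfile()


def simulate_study(
    profile: StudyProfile | None = None, seed: int = 0
) -> SimulatedStudy:
    """Simulate a full connected-RIL study under a profile.

    Builds the map and founders, simulates each RIL family, pools them into
    one genotype matrix, overlays genotyping noise, and grows the material
    in every environment. Deterministic given (profile, seed).
    """
    if profile is None:
        profile = reference_profile()
    rng = np.random.default_rng(seed)
    gmap = GeneticMap.uniform(
        profile.n_chromosomes, profile.chromosome_length_cm, profile.markers_per_chromosome
    )
    founders = FounderPanel.random(
        gmap, profile.founder_ids, seed=int(rng.integers(2**31))
    )
    tm = _reference_trait_model(gmap, founders, profile)
    mats = []
    for (fa, fb), n in zip(profile.crosses, profile.family_sizes):
        pop = f"{fa}x{fb}"
        mats.append(
            simulate_ril_population(
                founders.haplotypes.loc[fa],
                founders.haplotypes.loc[fb],
                n,
                gmap,
                n_selfing=profile.n_selfing,
                seed=int(rng.integers(2**31)),
                line_prefix=f"{pop}_",
                population=pop,
            )
        )
    calls = pd.concat([m.calls for m in mats])
    pops = pd.concat([m.populations for m in mats])
    g_true = GenotypeMatrix(calls, pops, gmap.markers.copy())
    g_obs = apply_genotyping_noise(
        g_true,
        profile.mean_missing_rate,
        profile.genotyping_error_rate,
        seed=int(rng.integers(2**31)),
    )
    study = simulate_trials(g_true, tm, seed=int(rng.integers(2**31)))
    study.genotypes_observed = g_obs
    study.seed = seed
    study.founders = founders
    return study
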