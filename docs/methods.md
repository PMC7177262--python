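# Methods

`drypea` re-creates, as a tested library, the analysis chain used in
multi-environment genomic-selection studies of pea (*Pisum sativum*)
grain yield under terminal drought: genotype quality control, plot-level
quantitative genetics, AMMI partitioning of genotype x environment (GE)
interaction, rrBLUP / Bayesian Lasso genomic prediction with several
validation schemes, and selection-response theory comparing phenotypic
(PS), genomic (GS) and marker-assisted (MAS) selection. Because the real
field and GBS data are not shipped, a first-class simulator generates
connected recombinant-inbred-line (RIL) material with the GE structure
the analysis assumes, giving every estimator a known truth to recover.

## The synthetic study

**Genomes and families.** Seven chromosomes of 120 cM carry 100 evenly
spaced biallelic markers each (700 candidates). Meiosis is modelled
without crossover interference: the crossover count per chromosome is
Poisson with mean length/100 and positions are uniform, which makes
recombination fractions follow the Haldane map function. Three fully
homozygous founders (A, I, K) are crossed pairwise (A x I, K x A, K x I)
and 96 / 92 / 100 F6 lines are derived by single-seed descent (five
selfing generations from the F1), leaving an expected residual
heterozygosity of (1/2)^5 ~ 3.1% at loci segregating in the cross.

**Trait architecture.** Yield (t/ha) is additive over ~20 QTL whose
effects are environment-specific; a residual heterozygote contributes
the mean of the two homozygotes. Three environments are simulated:

| environment | role | reps | mean yield | target line-mean H² |
|---|---|---|---|---|
| `ms` | managed severe terminal drought (rain-out shelter) | 4 | 0.32 t/ha | 0.87 |
| `severe` | severely drought-stressed field site | 3 | 0.36 t/ha | 0.475 |
| `moderate` | moderate-stress field site | 3 | 1.38 t/ha | 0.522 |

The QTL set splits into (i) one major flowering locus whose early allele
raises yield in the two severe-stress environments only (drought
escape), plus two minor flowering loci; (ii) five intrinsic-tolerance
loci active in both severe environments; (iii) environment-specific
blocks for `ms`, `severe` and `moderate`. Effect sizes were calibrated
once, with the package's own estimators over several seeds, so that the
whole-set genetic correlation is ~0.5 between the severe-stress
environments and ~0 between either of them and the moderate site, and
the line-mean correlation of yield with flowering onset is strongly
negative under managed stress (~ -0.6), moderately negative at the
severe site and ~0 at the moderate site. Because each biallelic locus
can segregate in at most two of three crosses, founder allele patterns
rotate across QTL; the five tolerance loci all segregate in the first
cross so that a MAS panel scored there spans its full range.

**Trials.** Plot values are environment mean + genetic value + block
effect + plot error in randomized complete blocks. The plot-error SD is
derived per environment from the realized genetic variance and the
target line-mean heritability H² = sigma2_g / (sigma2_g + sigma2_e/r),
so heritability recovery is a test of the estimator, not of the error
draw. Aerial biomass tracks the yield genetic value through a fixed
slope plus independent noise; it exists so the plot tables and group
comparisons carry the trait and is not separately calibrated. Flowering
has an environment-constant genetic part and high repeatability.

**Genotyping imperfections.** Observed matrices mask calls with
per-marker missing rates drawn from a Beta(3, 1.5) mixture scaled to a
requested mean — GBS-like in that allowed-missingness thresholds between
10% and 50% admit steeply growing marker counts. The reference profile
uses a mean rate of 0.15 so that the 2.5% MAF / 20% missing-rate filter
retains ~440 polymorphic markers, the working-set scale of a biparental
pea GBS panel; the noise function's standalone default (0.33) emulates
the full steep-rise profile instead. Call-error flips are supported but
default to zero.

**What the generator does not emulate.** Read-level GBS (allele-specific
dropout, depth-dependent error), selection during line development,
dominance and epistasis, spatial field trends (the alpha-lattice designs
of real trials are analysed as complete blocks here), and within-site
year-to-year variation. Passing tests therefore show that the estimators
recover truth under a clean additive RCB world, not that they are robust
to those real-data features.

## Estimators and numerical choices

**Variance components.** The per-environment model is value = mean +
block (fixed) + line (random) + error, fit by REML on error contrasts:
with K an orthonormal basis of the null space of the fixed-effect design,
the contrast covariance is diagonalized once and the profile restricted
likelihood is solved in the variance ratio by root-finding on the
analytic score (Brent, tolerance 1e-14), truncating at zero when the
score at the boundary is non-positive (so H² is in [0, 1] by
construction). On balanced data this equals the ANOVA estimators
sigma2_e = MSE, sigma2_g = (MS_line - MSE)/r to 1e-8; on unbalanced data
it matches statsmodels MixedLM to 1e-4 (test oracle). BLUP line values
are the H²-shrunken line means mu + H²(mean - mu); the genetic
correlation across environments is r_p/(H_j H_j'), clamped to [-1, 1].

**Combined ANOVA.** Sequential (type I) fixed-effects decomposition —
environment, block within environment, genotype, genotype x environment —
by incremental least-squares projection on dummy designs. Missing
line x environment cells are an error (listing the offending pairs).
Hartley's F_max uses a seeded Monte-Carlo null (1e5 draws by default).

**AMMI.** The doubly centered cell-mean table is decomposed by SVD; the
sign convention fixes the first environment's score non-negative on each
axis. The axis test statistic for axis n is F_R = n_blocks x SS_rem /
(df_rem x pooled error MS) with df_rem = (I - n)(J - n), where SS_rem is
the interaction remaining after axes 1..n-1, referred to
F(df_rem, error df); axes are declared significant sequentially until
the first non-significant remainder. The exact numerator convention for
this test is not uniquely standardized; the implementation is isolated
in `fr_test` and calibrated by a null simulation (PC1 false-positive
rate ≤ 0.08 at alpha = 0.05). Nominal yields drop the environment main
effect: nominal_ij = mu + G_i + lambda1 gamma_i1 delta_j1, plotted with
symmetric sqrt(lambda) scaling so response lines evaluated at the
environment coordinate reproduce the nominal values exactly.

**rrBLUP.** Markers are centered (dosage - 1 - column mean); REML for
the single variance ratio runs on the spectrum of WW' in the contrast
space orthogonal to the intercept, again by score root-finding; the
effect vector is the ridge solution at lambda = sigma2_e/sigma2_beta.
When the score stays positive at the search cap (noise-free data) the
ratio is pinned at 1e12, i.e. effectively interpolating. Fixed-lambda
fitting is exposed for oracle comparisons.

**Bayesian Lasso.** Park-Casella Gibbs sampler in the
scale-mixture-of-normals form (beta_k | tau2_k ~ N(0, sigma2 tau2_k);
1/tau2_k inverse-Gaussian; sigma2 scaled-inverse-chi-square; lambda²
Gamma(0.55, 0.1) hyperprior), single-site updates with residual
bookkeeping in a numba kernel. Defaults: 12,000 iterations, 2,000
burn-in, thin 5; inside cross-validation a reduced 4,000/1,000 chain is
used (fold-level point predictions do not need long chains; the full
chain is a flag away). beta² is floored at 1e-12 in the inverse-Gaussian
mean to avoid the known singularity at beta = 0. The effective sample
size of sigma2_e (initial-positive-sequence estimator) is reported as a
diagnostic; a non-finite draw aborts with the iteration index.

**Predictive ability.** r_Ab is the Pearson correlation of observed and
predicted phenotypes computed *within each fold and population*, then
averaged over folds, repetitions and populations. Computing one
correlation per repetition over the pooled fold predictions — a natural
alternative reading — mixes the fold models' offsets into the
correlation; with a signal-free model, predictions collapse to fold
constants and the pooled correlation is biased to ≈ -0.2, while the
per-fold estimator is unbiased under permutation (measured -0.02). This
is the one place the implementation deliberately refines the obvious
pooled definition; population stratification of folds, refitting per
fold, and the repetitions -> populations averaging order are as expected.
Predictive accuracy readjusts by the validated environment's
heritability, r_Ac = r_Ab / H_j. Cross-environment prediction trains on
all lines in one environment and validates the same lines' phenotypes in
another (refusing mismatched line sets); cross-population prediction
trains on one or two connected families and validates on a disjoint one,
scanning all combinations.

**Selection theory.** Selection intensity is the truncated-normal mean
i = phi(z_p)/p. Predicted gains: direct PS i H² sigma_p; indirect PS
i H_j H_j' r_g sigma_p; GS i'' r_Ab sigma_p (equivalently i'' r_Ac
sigma_a). The equal-cost comparison uses i = 1.755 (10% selected
fraction) for PS against i'' = 2.197 (3.6%) for GS, encoding a 2.8-fold
lower cost per genotyped line; efficiencies are reported unclamped.
MAS scores count favorable-allele dosage over a seven-marker panel
grouped in five regions (max 14) and a per-region consensus dosage
(mean member dosage rounded half-down, max 10); all-favorable lines form
the top group, zero-favorable the bottom. Truncation selection breaks
ties by line id and logs them.

**Group comparisons.** The selection experiments are analysed by two
sequential ANOVAs (with and without the parent group); the LSD at
p < 0.05 uses the harmonic mean of plots per group, and Dunnett contrasts
against the parents use a seeded Monte-Carlo critical value of the
max-|t| null (1e5 draws), which reduces to the plain t quantile for a
single comparison.

## Pipeline

`run_study` chains simulation -> QC/imputation -> variance components,
BLUPs, genetic correlations -> combined ANOVA, Hartley, AMMI ->
intra-environment CV (both models, pooled and per-population training),
all six directed cross-environment transfers, cross-population scans ->
the predicted-gain table -> a proof-of-concept selection experiment:
30 lines per family are held out, five criteria (PS in each severe
environment and on their mean; GS pooled and per-population, trained on
the remaining lines) each pick 3 lines per family, a MAS panel is scored
on the first family, and the selections are evaluated against the
parents in a freshly simulated managed-stress trial (which reuses the
main study's plot-error scale rather than re-deriving it from the
selection-shifted genetic variance). A line picked by several criteria
is charged to the first and later criteria take their next-ranked line,
keeping the comparison groups disjoint and full-sized. All randomness
descends from one seed; rerunning a configuration reproduces the
summary and artifacts exactly (modulo the recorded wall time).

Default run sizes keep the full pipeline around 1.5 minutes on one CPU
(rrBLUP CV 5 x 10 folds; Bayesian Lasso CV 2 x 10 folds with the
reduced chain); all counts are configuration fields.

## Known limitations

- The alpha-lattice design of real managed-stress trials is analysed as
  complete blocks; incomplete-block recovery would tighten H² slightly.
- The r_g estimator (standardized line means) and the F_R degrees of
  freedom follow one defensible convention each; both are isolated
  behind single functions and null-calibrated, but other conventions
  exist.
- KNN imputation accuracy depends strongly on marker density: ~94% of
  masked calls are recovered on a tightly linked matrix (1.25 cM
  spacing) but ~82% at the default 1.2-markers-per-cM study map. The
  simple-matching distance uses genome-wide similarity, so sparse maps
  dilute the local haplotype signal.
- Cross-validated r_Ab on ~10-line fold cells is slightly attenuated for
  strong signals (small-sample Pearson bias, about -0.02 at r ~ 0.7).
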