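# Methods

This note documents the statistical models implemented in `cwm_phylo`,
the conventions and numerical choices behind them, what the synthetic
data generator does and does not emulate, and known limitations.

## Community metrics

The community-weighted mean genome size of a subplot is
`CWM = sum_i 1C_i * b_i / B` with `b_i` the dry weight (g) of species
`i` and `B` the subplot total. Subplots with zero total biomass return
a flagged missing value. A species present with biomass but lacking a
1C record is an error by default; `drop_missing_gs` switches to
drop-and-renormalise.

Treatment classification uses only nitrogen (any positive nitrate or
ammonium dose) and phosphorus: the four cells control / N / P / N+P.
Potassium, sodium, magnesium and silicon do not enter the cell factor;
their influence is assessed separately by per-nutrient mixed models
with backward likelihood-ratio elimination, which justifies pooling
subplots into the four cells when none of the minor nutrients
dominates.

Genomic groups cross ploidy class with a genome-size threshold;
"large" is boundary-inclusive (1C >= threshold), with 5 pg the default
and 2.5 / 3 / 6 pg available as a sweep. Species recorded at zero
weight count for neither biomass nor richness. A species with an
intraspecific 1C range is stored at its mean value (the optional
min/max pair is carried through IO but not used downstream).

C-S-R partitioning multiplies a species' biomass by its C:S:R
proportion triple (which must sum to 1), conserving mass exactly; a
lookup translates Grime letter codes ("C", "CSR", "C/CSR", ...) to
triples, averaging the two parts of slashed codes.

## Classical inference

All ANOVA tables use **sequential (Type I) sums of squares** in the
stated formula order (N, then P, then N:P; group terms after the
subplot stratum). The design this pipeline targets is unbalanced
(12/11/16/25 subplots per cell), where sequential and marginal
decompositions genuinely differ; sequential SS sum exactly to the
model SS, which the tests assert. Treatment contrasts are reported
against the control cell. A residual mean square at floating-point
noise level (relative to the response scale) yields an undefined F
with a warning rather than an infinity.

The four-way genomic-group ANOVA (response: square-root biomass or
square-root species count per subplot x group) is a split-plot
decomposition: N, P and N:P vary only between subplots and are tested
against the subplot stratum (df = n_subplots - 4), while the twelve
terms involving genome-size class or ploidy are tested against the
within-subplot residual. With 64 subplots and 4 groups the residual
carries 256 - 64 - 12 = 180 degrees of freedom. The original analysis
is stated only as "subplot treated as a random factor"; the split-plot
error stratification is the standard construction that reproduces the
published degrees of freedom and is the package's documented choice.

The linear mixed model is a Gaussian random-intercept model. The
variance ratio theta = sigma2_group / sigma2_resid is profiled out of
the (restricted) likelihood using the Woodbury identity per group
(cost linear in n), optimised on a coarse log-grid followed by bounded
refinement, with theta = 0 always evaluated as the boundary candidate.
REML is used for reporting, ML for likelihood-ratio model reduction
(REML likelihoods are not comparable across fixed structures and are
rejected). Rank-deficient fixed designs raise an error listing the
aliased columns (QR with pivoting). Backward elimination removes the
least significant nutrient (largest LRT p above 0.05) iteratively;
constant nutrient columns are unidentifiable and dropped up front.
Because each retained term survives a 5% test, occasional spurious
retentions are expected and the recovery tests assert accordingly.

For a subplot-level response, "subplot as a random effect" is
confounded with the residual; the per-nutrient models therefore use a
plot-level random intercept with subplots nested inside plots.

## Phylogenetic signal

The Brownian covariance `C` has `C[i,j]` equal to the branch length
shared from the root to the MRCA of tips i and j. Blomberg's K is

    K = (MSE0 / MSE) / [(tr(C) - n / (1' C^-1 1)) / (n - 1)]

with the phylogenetic mean `a = (1' C^-1 y) / (1' C^-1 1)`, `MSE0` the
ordinary and `MSE` the C^-1-weighted mean squared error about `a`.
K = 1 identically on a star tree and in expectation under Brownian
motion. Significance comes from permuting trait values across tips
(default 999 permutations, add-one correction, seeded).

Pagel's lambda multiplies the off-diagonal entries of C; the ML
estimate maximises the profile likelihood (mean and sigma2 profiled
out) over [0, lambda_max], where lambda_max is the largest value
keeping every off-diagonal below both tip variances, capped at 1.2 —
estimates slightly above 1 are admissible, as observed in real
communities. The LR test against lambda = 0 uses a chi-square with one
degree of freedom. Signal is tested on log 1C by default (genome sizes
are log-normal-ish across communities); a switch allows the raw scale,
since published analyses do not always state which was used.

Constant traits make both statistics undefined; they return flagged
missing values with a warning. Singular covariance matrices (e.g.
zero-length terminal branches giving repeated rows) receive one
relative diagonal jitter of 1e-8 before factorisation, logged.

## PGLS

`gls_fit` is the closed form `beta = (X'V^-1X)^-1 X'V^-1 y` with
`sigma2 = r'V^-1 r / (n - p)` and SEs from `sigma2 (X'V^-1X)^-1`;
V = I reproduces OLS exactly. Corrected group means use cell-means
coding with V = C. The biomass-weighted phylogenetic mean — the
tree-aware analogue of the CWM — is implemented as the GLS intercept
under `V = D^-1/2 C D^-1/2` with `D = diag(w / mean(w))`: with C = I
it is exactly the ordinary weighted mean, with equal weights exactly
the phylogenetic mean. This weighting is one documented interpretation
of an under-specified construction in the literature; the plain CWM
remains the primary descriptive statistic.

## Bayesian phylogenetic mixed model

Only occupied rows (biomass > 0) are modelled; the response is
ln(biomass in g), genome size enters as ln(1C in pg), N, P and ploidy
as 0/1 indicators, pH uncentred (so its slope is per pH unit and the
intercept refers to pH 0), with the 17 fixed terms in a fixed
canonical order (main effects, then all two-, three- and four-way
interactions among GS, N, P, ploidy). Random effects: plot intercepts,
species intercepts, and a second species-level effect with covariance
`sigma2_phylo * C`, where C is scaled so its maximum diagonal is 1 to
make sigma2_phylo comparable across trees. Species absence/occupancy
is out of scope (no zero-inflation component).

The sampler is plain Gibbs: the joint location block (fixed plus all
random effects) has a multivariate-normal full conditional sampled via
a Cholesky factor of the precision matrix (the phylogenetic block
contributes `C^-1 / sigma2_phylo`); each variance component has a
scaled-inverse-chi-square full conditional. The prior (V, nu) maps to
shape nu/2 and scale nu*V/2; nu = 0 is the improper flat limit,
accepted with a warning and rejected outright when a component has no
data. Fixed effects carry a near-flat Gaussian prior (precision 1e-8)
for propriety. With no data rows the variance components are sampled
directly from their priors, which is the sampler's prior-recovery
check.

The default schedule is 60,000 iterations, 10,000 burn-in, thinning 10
(5,000 retained samples). Conjugate Gibbs on Gaussian models mixes
fast — observed fixed-effect effective sample sizes are close to the
retained sample count — so this desk-scale schedule gives Monte Carlo
errors far below the scientific tolerances; a multi-million-iteration
schedule can be configured for strict emulation of published
workflows.

ESS uses Geyer's initial-positive-sequence estimator
`M / (1 + 2 sum rho_t)` (FFT autocorrelations, truncated at the first
non-positive adjacent pair sum), capped at M; constant chains are
flagged. pMCMC is `2 min(#{theta>0}, #{theta<0}) / M`, floored at 1/M
and labelled "< 1/M" when one sign never occurs. The prior-sensitivity
scan reruns the sampler per candidate prior at a reduced schedule and
reports the maximum fixed-effect shift.

## Synthetic data generator

The generator emulates the statistical structure of a long-term
factorial grassland experiment: a pure-birth (Yule) phylogeny
(terminal branches extended by the waiting time to the next speciation
so the tree is strictly positive-definite as a covariance), log 1C
evolved as `MVN(root, sigma2_bm * C(lambda))`, Bernoulli polyploidy
whose 1C multiplier creates the genome-size/ploidy association,
Dirichlet C-S-R triples, a cycled (balanced) 2x2 N/P design with
nitrogen dose levels 48/96/144 kg N ha^-1 yr^-1 and uniform soil pH on
the inclusion range [4.5, 7.0], and log-scale biomass from the same
fixed/random structure the Bayesian model fits (pH centred at 5.75 in
the generator so the intercept refers to the mid-range).

Defaults are the study-scale conditions: 60 species, 16 plots x 4
subplots, lambda = 1, about half the species polyploid with a 2x
genome multiplier, occupancy 0.5, and fixed-effect/variance-component
magnitudes set to published posterior estimates for this system (the
generator's intercept absorbs the pH-centring shift). Occupancy is
Bernoulli and treatment-independent by default; a hook allows
treatment-dependent occupancy for species-richness experiments.

**Recovery fixtures.** Estimator-recovery tests plant a single known
coefficient (beta_P = 0.9, all other fixed effects zero) with small
variance components — 0.01 for each G-side component and 0.05
residual — chosen so that the posterior-mean scatter is well inside
the +/-0.15 recovery band: the band then checks sampler correctness
rather than data noise. Lambda recovery uses 200-tip trees and 100
replicates; LRT calibration uses 1000 null replicates at n = 64.

What the generator does **not** emulate: temporal dynamics,
competition or seed banks; treatment assignment at the plot level
(cells are cycled within plots, which identifies treatment effects
within plots — real long-term experiments often confound treatment
with plot); non-Gaussian biomass errors; and any dependence of
occupancy on traits. Passing recovery tests therefore demonstrate
correctness of the estimators under the assumed model, not robustness
to field-data pathologies.

## Numerical conventions

- Singular covariance/precision matrices: one retry with a relative
  diagonal jitter of 1e-8, logged; hard failure otherwise.
- Profiled LMM likelihoods evaluated at theta = 0 as an explicit
  boundary candidate; degenerate fits reproduce OLS to optimizer
  tolerance.
- Permutation p-values use the add-one correction
  `(1 + #hits) / (n_perm + 1)`.
- All stochastic stages take explicit integer seeds; pipeline stages
  derive independent sub-seeds from the run seed, so disabling one
  stage leaves every other stage's output byte-identical.

## Limitations

- The four-way ANOVA's error stratification reconstructs the published
  degrees of freedom but the original stratification is not fully
  documented; treat between-subplot F tests as approximate.
- The biomass-weighted PGLS mean is one reasonable formalisation of a
  loosely specified construction; alternatives (e.g. subplot-level
  responses) would give different corrected means.
- pMCMC is a sign-probability summary, not a posterior model
  probability; its floor at 1/M reflects Monte Carlo resolution.
- Richness summaries count species per subplot; treatment-level
  figures are means of subplot counts, not pooled species lists.
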