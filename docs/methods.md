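# Methods

This note records the statistical models phylogerm implements, the
defaults of the synthetic study generator, and the numerical and design
choices made where more than one defensible option existed.

## Germination metrics

A `GerminationRecord` is one Petri dish: daily counts `(i, G_i)` with day 1
the first check after sowing, the number of seeds sown, and the number
found dead (tetrazolium-negative) at trial end. From it:

- `GP = Σ G_i / n_sown`, a proportion in [0, 1];
- `GT = Σ(G_i · i) / Σ G_i` in days, **undefined** when `Σ G_i = 0`.
  Undefined GT propagates as NaN, is skipped by aggregation (with a
  contributing-replicate count), and removes the species from GT models
  and from the tree before a GT signal fit. It is never imputed;
- `mortality = n_dead / n_sown`; GP + mortality + viable-ungerminated = 1
  by construction.

Transforms: arcsine-square-root for GP and mortality, natural log for GT.
The log base is immaterial — it rescales GT_t linearly and leaves every F,
P, R² and λ̂ unchanged (λ̂ is affine-invariant; see the property test).
Transforms are applied **after** aggregation to the analysis unit, which is
where the linear models consume them.

Analysis unit: species x temperature means (replicates averaged), giving
670 GP rows and 655 defined GT rows at the full design. Temperature enters
the same ANOVAs as species-level attributes, and modelling replicate dishes
directly would pseudo-replicate the species x regime cell; a
replicate-level unit remains available (`unit="replicate"`).

## Phylogenetic signal

The Brownian-motion tree covariance has `C_ii` = root-to-tip distance
(non-ultrametric trees are accepted as-is) and `C_ij` = shared root-to-MRCA
path. Pagel's λ multiplies only the off-diagonal. For a trait `z` the root
state and rate profile out in closed form,

    z0̂ = (1ᵀC⁻¹z)/(1ᵀC⁻¹1),   σ̂² = (z−z0̂1)ᵀC⁻¹(z−z0̂1)/n,
    log L = −½ [ n log(2π σ̂²) + log|C| + n ],

leaving a 1-D profile likelihood in λ maximised by a 21-point grid scan
plus bounded Brent refinement in the winning bracket (tolerance 1e-6); the
grid guards against flat or multi-modal surfaces near the boundaries. All
algebra is dense Cholesky — solves and log|C| from one triangular
factorisation, no explicit inverse or determinant overflow; at ~10² tips
the O(n) pruning algorithm is unnecessary.

Numerical guards: if `C_λ` fails to factor, one jitter of
`1e-10 · mean(diag)` is added, then the fit fails loudly; a constant trait
drives σ̂² to the 1e-12 floor rather than an infinite likelihood.

The LRT against λ = 0 is referred to χ² with 1 df, the convention of the
analysis this package operationalises, although λ = 0 lies on the boundary
of the parameter space; the test is therefore conservative (empirical
type-I rate ~0.01 at nominal 0.05 in the acceptance run) and this is
documented rather than corrected with a 50:50 mixture.

The λ fit unit is the per-species mean of the transformed response across
regimes (one λ per trait); per-regime fits are available by passing a
filtered metrics table. A robustness variant refits with every branch
length set to 1.

Known property: the profile-ML λ̂ is slightly biased toward the interior at
moderate n. On 134-tip Yule trees the mean bias is about −0.05 at
λ* ∈ {0.25, 0.5}, −0.03 at 0.75, and near 0 at both boundaries (boundary
estimates are biased inward only). The estimator agrees with independent
implementations of the same likelihood to four decimals; the bias is a
finite-sample property of profiling σ² by ML (division by n), not an
optimisation artefact.

## Type III ANOVA engine

Fixed-effects models under sum-to-zero (deviation) coding; interactions as
products of parent columns. Type III SS for term T is
`RSS(model without T's columns) − RSS(full)`, with
`df_T = rank(X_full) − rank(X_minus_T)` from rank-revealing (SVD) least
squares, `F_T = (SS_T/df_T)/MSE` and `R²_T = SS_T/SS_total` (total centred
SS). Type III is coding-dependent in singular designs, so the coding is
part of the contract.

Empty cells: all-zero interaction columns are dropped with a warning, and
remaining interaction columns that are exact linear combinations of the
intercept and main effects are pruned (modified Gram–Schmidt, tolerance
1e-9 relative) **in term order** — intercept, mains, interactions — so the
rank deficiency lands on the interaction, whose achieved df then equals
the observed-cell rank, while main effects keep their full df. Without
this ordering an empty cell silently zeroes the main-effect dfs too.

In unbalanced designs the Type III decomposition need not sum to the model
SS; this is expected and deliberately not enforced. Unused factor levels
are dropped per fit. No multiple-testing correction is applied across the
battery of ANOVAs, matching the analysis convention this package
implements; α = 0.05 throughout, configurable.

Tukey–Kramer: pairwise studentized-range statistic
`q = |m_i − m_j| / sqrt(MSE/2 · (1/n_i + 1/n_j))` with the pooled one-way
MSE, valid for unequal n; with two groups it reduces exactly to the pooled
t-test. The compact letter display uses insert-and-absorb: start from one
all-inclusive letter column, split any column containing a significantly
different pair, absorb subset columns; letters are ordered by descending
group mean. Singleton groups are excluded with a warning.

## Variance partition

The complete model is **main-effects only** (eight factors, 31 model df at
the full design); each incomplete model deletes one factor.
`R²_independent(f) = R²(complete) − R²(complete − f)`. On balanced
orthogonal designs this equals f's one-way R² and the independent
contributions sum to the complete-model R²; under collinearity it shrinks,
and for a perfectly duplicated factor it is 0.

Association rule: flag (A, B) when A's **term-level** Type III R² in the
incomplete model lacking B exceeds its value in the complete model. The
model-level R²s are emitted alongside for inspection. The flag threshold
is ΔR² > 0.001 of total SS — a zero threshold would flag floating-point
noise; 0.001 is an order of magnitude below any substantively interesting
shift at these sample sizes.

## Synthetic study generator

The generator's defaults are the emulated design: 134 species, five
alternating-temperature regimes (5/15 … 10/25 °C), 3 dishes x 50 seeds,
60 daily checks.

- **Tree**: Yule (pure-birth, unit rate), one extra exponential interval
  after the last birth so terminal branches are positive, depth rescaled
  to exactly 1 so σ² reads as variance per total tree depth.
- **Latent traits**: logit-GP with λ = 0.53, σ² = 1.0, mean 0 (50%
  germination at the regime midpoint); log-GT with λ = 0.75, σ² = 0.30,
  mean log 12 days. The λ defaults are the signal strengths the emulated
  study estimated for the two traits.
- **Temperature effects** act additively on the latent scales (keeping
  probabilities and times in range): logit-GP shifts (−0.50, 0.10, 0.40,
  0.25, 0.30) and log-GT shifts (0.35, 0.00, −0.10, −0.20, −0.15) across
  the five regimes, chosen so regime-mean GP spans roughly 38–60% rising
  with warming and GT roughly 17 down to 10 days — the coarse pattern of
  the emulated trial.
- **Dish counts**: germinants ~ Binomial(50, expit(logit-GP + shift));
  each germinant's day is a rounded log-normal centred on
  exp(log-GT + shift) with log-sd 0.35, clipped to [1, 60]. A log-normal
  was chosen because germination-day distributions are positive and
  right-skewed and GT is analysed on the log scale. Leftover seeds die
  with per-regime probability (0.08, 0.12, 0.18, 0.22, 0.25) — mortality
  rising with temperature — else remain viable-ungerminated.
- **Zero-germination species**: the 3 species with lowest latent GP are
  forced to p = 0, reproducing the emulated study's pattern of 3
  non-germinators and exercising the GT-exclusion path (131 of 134 species
  in GT analyses).
- **Attributes**: taxonomic order (14 levels) and family (30) come from
  cutting the tree at its most basal splits, so families nest within
  orders; the other factors (life form 2, seed-size class 5, dispersal
  mode 4, flowering onset 3, duration 3, habitat 3) threshold an auxiliary
  BM trait simulated with λ = `attribute_clustering` (default 0.7) at
  equal-count quantiles — 1 gives clade-like categories, 0 random labels.
  Seed mass is drawn uniformly in log space within the species'
  half-decade mass-class bounds (0.032–9.999 mg).

Randomness: one global seed, split into named substreams keyed by
crc32(stage name), so adding a stage never perturbs another stage's draws
and regeneration is bit-reproducible.

**What the generator does not emulate**: dormancy cycling and seed-bank
dynamics, within-dish spatial effects, regime-by-species interactions
beyond the additive latent shifts, non-random taxon sampling, and real
measurement artefacts (missed checks, miscounts). Passing recovery tests
therefore show the estimators work when their assumptions hold at the
study's scale and noise level — not that any particular field dataset
satisfies those assumptions.

## Problem sizes in the test and acceptance runs

Monte-Carlo checks use sizes chosen for stable statistics at interactive
runtimes: λ recovery 100 replicates per λ* at the full 134-tip scale, LRT
calibration 500 replicates, likelihood-oracle comparison 50 random
(tree, trait, λ) triples, association power 100 replicates of n = 240, and
12 end-to-end replicate datasets for the mean λ̂ report. The whole
acceptance script completes in about a minute on one CPU.

## Known limitations

- No mixed/random effects and no phylogenetic GLS regression: the ANOVAs
  are ordinary fixed-effects models by design.
- Type III with empty cells is reported at the achieved df; hypotheses for
  such terms are those estimable under sum-to-zero coding, as in standard
  GLM implementations.
- The λ̂ interior bias described above means single-dataset λ estimates at
  moderate signal should be read with ±0.1–0.15 uncertainty at this scale.
- Megatree assembly and branch-length smoothing are out of scope: the user
  supplies the phylogeny (or uses the Yule generator).
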