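# phylogerm

Phylogenetic, life-history and environmental analysis of interspecific
seed-germination variation.

## The problem

Community-scale germination trials incubate seeds of many co-occurring
species under a set of temperature regimes and check them daily. Two
statistics summarise each species x regime combination:

- **germination percentage** `GP = Σ G_i / n_sown`, the proportion of sown
  seeds that germinated, and
- **mean germination time** `GT = Σ(G_i · i) / Σ G_i` (days), the
  count-weighted mean germination day, undefined for species that never
  germinate.

The scientific question is where the interspecific variation in GP and GT
comes from: shared ancestry (phylogenetic inertia), life-history attributes
(life form, seed-size class, dispersal mode, flowering onset/duration), or
environment (incubation temperature, collection habitat). phylogerm
answers it with three connected analyses:

1. **Phylogenetic signal.** Under Brownian motion on a phylogeny, tip trait
   values are multivariate normal with covariance `σ² C`, where `C_ij` is
   the shared root-to-MRCA path length. Pagel's λ rescales the off-diagonal
   of `C`; λ is estimated by maximum likelihood on [0, 1] (root state and
   rate profiled out analytically) and tested against λ = 0 with a χ²₁
   likelihood-ratio test. λ = 0 means no signal (star phylogeny), λ = 1
   full Brownian signal.
2. **Type III ANOVA battery.** One-way, two-way (with interaction) and
   multi-factor fixed-effects models of the transformed responses
   (arcsine-square-root GP and mortality, log GT) under sum-to-zero coding,
   with marginal (Type III) sums of squares, per-term `R² = SS/SS_total`,
   and Tukey–Kramer group comparisons with compact letter displays.
3. **Variance partition.** The complete main-effects model is compared with
   each model lacking one factor; the drop in model R² is that factor's
   *independent* contribution, and a factor whose term R² rises when
   another is deleted is flagged as associated with it.

Because such trials rarely come with reusable raw data, the package
includes a first-class synthetic generator that emulates the full study
design — 134 species on a Yule tree, five alternating-temperature regimes,
three replicate dishes of 50 seeds, 60 daily checks, λ-structured latent
traits, phylogenetically clustered attributes — with the generating truth
retained so estimator recovery is testable end to end.

## Worked example

```bash
phylogerm all --seed 0 --out demo/
```

or in Python:

```python
import phylogerm as pg
results = pg.run_pipeline(pg.RunConfig(out_dir="demo", seed=0))
```

The bundle contains `tree.nwk`, `attributes.csv`, `observations.csv`,
`metrics.csv`, `signal.csv`, the ANOVA tables, `partition.csv`,
`associations.csv`, `results.json` and a plain-text `report.txt`, which for
seed 0 begins:

```
== Phylogenetic signal (Pagel's lambda) ==
trait  n_species  lambda_hat  sigma2_hat  z0_hat    logL0   logL1    LRT     p
 GP_t        134       0.667       0.075   0.776    1.536  19.861 36.649 0.000
 GT_t        131       0.683       0.251   2.479 -105.218 -58.061 94.314 0.000
```

Reading this: of the 134 simulated species, 3 never germinated, so the GT
fit uses 131 tips (the GT of a non-germinating species is undefined and
excluded, never imputed). Both traits carry significant phylogenetic
signal (LRT against λ = 0, P < 0.001). The one-way battery in the same
report shows taxonomic order explaining 35.2% of GP variance and
temperature 7.5% (df 13 and 4), and the partition block attributes 39.4%
of GT variance to order independently of the other seven factors — the
qualitative fingerprint the generator is designed to produce: germination
timing dominated by lineage, modulated by temperature.

Stage-by-stage commands (`phylogerm simulate|metrics|signal|anova|partition`)
expose the same steps for user-supplied newick/CSV inputs.

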