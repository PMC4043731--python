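"""Synthetic study generator: phylogeny, species attributes, germination data.

Emulates a community germination trial: ``n_species`` species on a Yule
phylogeny, each germinated under five alternating-temperature regimes with
three replicate dishes of 50 seeds checked daily for 60 days. Two latent
species traits drive the observations —

* ``gp`` on the logit scale: a species' germination probability, simulated
  under Pagel's-lambda-structured Brownian motion on the tree
  (``lambda_gp``, rate ``sigma2_gp``);
* ``gt`` on the log-day scale: a species' characteristic germination time,
  likewise lambda-structured (``lambda_gt``, ``sigma2_gt``).

Temperature acts additively on those latent scales (keeping probabilities
and times in range): warmer regimes raise germination probability and
shorten germination time. Per dish, the number germinating is binomial in
the regime-adjusted probability, and each germinant's day is a discretised
log-normal centred on the regime-adjusted characteristic time, clipped to
the trial window. Seeds left at trial end split into dead vs
viable-ungerminated by a per-regime mortality probability that rises with
temperature. A configurable number of species (default 3, matching the
emulated design) germinate nowhere, exercising the GT exclusion path.

Categorical attributes (taxonomic order/family, life form, seed-size class,
dispersal mode, flowering onset/duration, habitat) are phylogenetically
clustered: each factor thresholds an auxiliary Brownian trait simulated with
lambda equal to the ``clustering`` knob, so clustering=1 gives clade-like
categories and clustering=0 random labels; taxonomic levels instead cut the
most basal clades so families nest within orders.

All randomness flows from one seed through named substreams
(:func:`phylogerm.trees.stage_rng`), so regenerating with the same
configuration is bit-reproducible and adding a stage never perturbs
another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.special import expit

from .metrics import GerminationRecord
from .trees import (
    basal_clade_partition,
    simulate_tree,
    stage_rng,
    tip_labels,
    tree_covariance,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_trait",
    "simulate_attributes",
    "simulate_germination",
    "generate_dataset",
    "DEFAULT_TEMPERATURES",
    "DEFAULT_LEVEL_COUNTS",
]

DEFAULT_TEMPERATURES = ("5/15", "5/20", "5/25", "10/20", "10/25")

# Study-design groupings: 14 orders, annual/perennial, 5 half-decade seed
# mass classes, 4 dispersal modes, 3 flowering-onset and 3 duration classes,
# 3 habitats. Family count chosen so several families hold > 7 species.
DEFAULT_LEVEL_COUNTS = {
    "order": 14,
    "family": 30,
    "life_form": 2,
    "seed_size_class": 5,
    "dispersal_mode": 4,
    "flowering_onset": 3,
    "flowering_duration": 3,
    "habitat": 3,
}

_FACTOR_LABELS = {
    "life_form": ["annual", "perennial"],
    "dispersal_mode": ["unassisted", "ant", "adhesion", "wind"],
    "flowering_onset": ["early", "middle", "late"],
    "flowering_duration": ["short", "median", "long"],
    "habitat": ["bottomland", "north_slope", "south_slope"],
}

# Half-decade (Baker) seed-mass class bounds in mg.
_SEED_MASS_BINS = (0.032, 0.100, 0.316, 1.000, 3.162, 9.999)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters; defaults are the emulated trial's conditions.

    Latent-scale defaults: mean logit-GP 0 (50% germination at the regime
    midpoint) and mean log-GT log(12) (about 12 days). Regime effects were
    set so regime-mean GP spans roughly 38-60% and GT roughly 10-17 days,
    rising GP / falling GT with warming; per-regime mortality among
    non-germinated seeds rises with temperature.
    """

    n_species: int = 134
    temperatures: tuple[str, ...] = DEFAULT_TEMPERATURES
    n_replicates: int = 3
    seeds_per_dish: int = 50
    n_days: int = 60
    lambda_gp: float = 0.53
    lambda_gt: float = 0.75
    sigma2_gp: float = 1.0
    sigma2_gt: float = 0.30
    mean_gp: float = 0.0
    mean_gt: float = 2.4849  # log(12)
    temperature_effects_gp: tuple[float, ...] = (-0.50, 0.10, 0.40, 0.25, 0.30)
    temperature_effects_gt: tuple[float, ...] = (0.35, 0.00, -0.10, -0.20, -0.15)
    mortality_probs: tuple[float, ...] = (0.08, 0.12, 0.18, 0.22, 0.25)
    day_log_sd: float = 0.35
    attribute_clustering: float = 0.7
    n_zero_germination_species: int = 3
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_species, self.n_replicates,
               self.seeds_per_dish, self.n_days) < 1:
            raise ValueError("counts must be strictly positive")
        for lam in (self.lambda_gp, self.lambda_gt, self.attribute_clustering):
            if not 0.0 <= lam <= 1.0:
                raise ValueError("lambda values must lie in [0, 1]")
        if self.sigma2_gp < 0 or self.sigma2_gt < 0:
            raise ValueError("BM rates must be nonnegative")
        k = len(self.temperatures)
        for name, eff in (("temperature_effects_gp", self.temperature_effects_gp),
                          ("temperature_effects_gt", self.temperature_effects_gt),
                          ("mortality_probs", self.mortality_probs)):
            if len(eff) != k:
                raise ValueError(f"{name} must have one entry per regime ({k})")
        if not 0 <= self.n_zero_germination_species <= self.n_species:
            raise ValueError("n_zero_germination_species out of range")


@dataclass
class SyntheticDataset:
    """Tree + attributes + observations, with the generating truth retained."""

    tree: dendropy.Tree
    attributes: pd.DataFrame
    observations: list[GerminationRecord]
    truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def simulate_trait(
    tree: dendropy.Tree,
    lam: float,
    sigma2: float,
    mean: float,
    rng_seed=0,
    *,
    stage: str = "trait",
) -> pd.Series:
    """One multivariate-normal draw of a lambda-structured Brownian trait.

    Tip values have mean ``mean`` and covariance ``sigma2 * C_lambda`` where
    C_lambda is the tree covariance with off-diagonals damped by lambda.
    ``rng_seed`` may be an integer or an already-split numpy Generator.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    labels, C = tree_covariance(tree)
    if len(labels) < 2:
        raise ValueError("tree must have >= 2 tips")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else stage_rng(rng_seed, stage))
    if sigma2 == 0.0:
        return pd.Series(mean, index=labels, dtype=float)
    cov = sigma2 * _lambda_cov(C, lam)
    n = len(labels)
    L = np.linalg.cholesky(cov + 1e-12 * np.mean(np.diag(cov)) * np.eye(n))
    z = mean + L @ rng.standard_normal(n)
    return pd.Series(z, index=labels)


def _quantile_levels(aux: pd.Series, n_levels: int) -> np.ndarray:
    """Equal-count level assignment by rank of the auxiliary trait."""
    order = np.argsort(aux.to_numpy(), kind="stable")
    n = len(order)
    bounds = np.linspace(0, n, n_levels + 1).round().astype(int)
    levels = np.empty(n, dtype=int)
    for k in range(n_levels):
        levels[order[bounds[k]:bounds[k + 1]]] = k
    return levels


def simulate_attributes(
    tree: dendropy.Tree,
    level_counts: dict[str, int] | None = None,
    clustering: float = 0.7,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Phylogenetically clustered categorical attributes, one row per tip.

    Taxonomic keys ("order", "family") are assigned from the most basal
    clades (families refine orders); every other factor thresholds an
    auxiliary BM trait simulated with lambda = ``clustering`` at equal-count
    quantiles. A continuous ``seed_mass`` (mg) is drawn uniformly within
    each species' seed-size-class bounds when that factor is requested.
    """
    level_counts = dict(DEFAULT_LEVEL_COUNTS if level_counts is None
                        else level_counts)
    labels = tip_labels(tree)
    n = len(labels)
    for factor, k in level_counts.items():
        if k < 2:
            raise ValueError(f"{factor}: need >= 2 levels")
        if k > n:
            raise ValueError(f"{factor}: more levels ({k}) than tips ({n})")
    out = pd.DataFrame(index=pd.Index(labels, name="species"))
    rng = stage_rng(rng_seed, "attributes")
    for factor, k in level_counts.items():
        if factor in ("order", "family"):
            part = basal_clade_partition(tree, k)
            codes = np.array([part[sp] for sp in labels])
        else:
            aux = simulate_trait(tree, clustering, 1.0, 0.0, rng)
            codes = _quantile_levels(aux.loc[labels], k)
        names = _FACTOR_LABELS.get(factor)
        if names is not None and len(names) == k:
            out[factor] = [names[c] for c in codes]
        elif factor in ("order", "family"):
            out[factor] = [f"{factor}{c + 1:02d}" for c in codes]
        else:
            out[factor] = [f"{factor}_{c + 1}" for c in codes]
    if "seed_size_class" in level_counts and level_counts["seed_size_class"] == 5:
        cls = out["seed_size_class"].str.rsplit("_", n=1).str[-1].astype(int) - 1
        lo = np.log10(np.array(_SEED_MASS_BINS[:-1]))[cls]
        hi = np.log10(np.array(_SEED_MASS_BINS[1:]))[cls]
        out["seed_mass"] = 10 ** rng.uniform(lo, hi)
        out["seed_size_class"] = [
            f"{_SEED_MASS_BINS[c]:g}-{_SEED_MASS_BINS[c + 1]:g}mg" for c in cls
        ]
    return out.reset_index()


def simulate_germination(
    truth_gp: pd.Series,
    truth_gt: pd.Series,
    config: SimulationConfig,
) -> list[GerminationRecord]:
    """Binomial dish counts with discretised log-normal germination days.

    ``truth_gp`` is on the logit scale (-inf allowed: a species that never
    germinates), ``truth_gt`` on the log-day scale; both indexed by species.
    """
    if set(truth_gp.index) != set(truth_gt.index):
        raise ValueError("GP and GT truths must cover the same species")
    rng = stage_rng(config.rng_seed, "germination")
    records: list[GerminationRecord] = []
    for sp in truth_gp.index:
        for t_idx, regime in enumerate(config.temperatures):
            p = float(expit(truth_gp[sp] + config.temperature_effects_gp[t_idx]))
            mu = float(truth_gt[sp] + config.temperature_effects_gt[t_idx])
            for rep in range(1, config.n_replicates + 1):
                n_germ = int(rng.binomial(config.seeds_per_dish, p))
                if n_germ > 0:
                    days = np.rint(
                        np.exp(rng.normal(mu, config.day_log_sd, size=n_germ))
                    ).astype(int)
                    days = np.clip(days, 1, config.n_days)
                    uniq, cnt = np.unique(days, return_counts=True)
                    counts = tuple((int(d), int(c)) for d, c in zip(uniq, cnt))
                else:
                    counts = ((1, 0),)
                leftover = config.seeds_per_dish - n_germ
                n_dead = int(rng.binomial(leftover, config.mortality_probs[t_idx]))
                records.append(GerminationRecord(
                    species=str(sp), temperature=regime, replicate=rep,
                    daily_counts=counts, n_sown=config.seeds_per_dish,
                    n_dead_end=n_dead,
                ))
    return records


def generate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Full synthetic study: tree, attributes, observations, retained truth."""
    config = config or SimulationConfig()
    tree = simulate_tree(config.n_species, config.rng_seed)
    labels = tip_labels(tree)
    gp = simulate_trait(tree, config.lambda_gp, config.sigma2_gp,
                        config.mean_gp, config.rng_seed, stage="trait_gp")
    gt = simulate_trait(tree, config.lambda_gt, config.sigma2_gt,
                        config.mean_gt, config.rng_seed, stage="trait_gt")
    gp = gp.loc[labels]
    gt = gt.loc[labels]
    if config.n_zero_germination_species:
        lowest = gp.nsmallest(config.n_zero_germination_species).index
        gp.loc[lowest] = -np.inf
    # cap taxonomic level counts for small communities; the study-design
    # defaults assume the full 134-species scale
    level_counts = {f: min(k, config.n_species)
                    for f, k in DEFAULT_LEVEL_COUNTS.items()}
    attributes = simulate_attributes(
        tree, level_counts, config.attribute_clustering, config.rng_seed
    )
    observations = simulate_germination(gp, gt, config)
    truth = pd.DataFrame({
        "species": labels,
        "logit_gp": gp.to_numpy(),
        "log_gt": gt.to_numpy(),
        "lambda_gp": config.lambda_gp,
        "lambda_gt": config.lambda_gt,
        "sigma2_gp": config.sigma2_gp,
        "sigma2_gt": config.sigma2_gt,
    })
    return SyntheticDataset(tree=tree, attributes=attributes,
                            observations=observations, truth=truth,
                            config=config)
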