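"""Seeded generators for synthetic census and reproduction datasets.

The generators emulate the statistical structure the analysis pipeline
assumes about a beekeeping pre/post experiment:

* heterogeneous per-(plant, pollinator) base visit rates (multiplicative
  plant attractiveness x pollinator activity x lognormal noise), which
  produce a nested interaction matrix;
* a super-generalist invader entering only in the second (apis) period,
  its expected visit share calibrated to a target fraction of all visits
  and concentrated on the most attractive plants;
* multiplicative suppression of wild visit rates in the apis period plus
  the complete dropout of a configurable number of wild species;
* a paired reproduction design with per-plant random effects shared across
  periods, and a distance-from-apiary gradient whose invader pressure
  decays exponentially with distance.

Counts are Poisson per census by default (visits in a 5-min bout are small
counts); a negative-binomial option adds overdispersion.  Every generator
is fully determined by its ``seed``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .census_io import (
    DISTANCE_COLUMNS,
    NO_VISIT,
    REPRODUCTION_COLUMNS,
    SurveyDataset,
)

__all__ = [
    "CommunityParams",
    "ReproductionParams",
    "DistanceParams",
    "generate_censuses",
    "generate_reproduction",
    "generate_distance_gradient",
]


# ----------------------------------------------------------------------
@dataclasses.dataclass
class CommunityParams:
    """Parameters of the synthetic plant-pollinator community.

    Defaults mirror the motivating study where it states a value: 17 plant
    species, ~10 focal individuals per plant species, 86 censuses per
    plant species and period, an invader visit share and wild-rate
    suppression of the magnitude reported for high-density beekeeping, and
    the dropout of a few wild pollinator species in the apis period.  The
    wild pollinator pool (98 species) and the visit-rate distribution are
    set so the pre-period network has a connectance and mean visit rate of
    the observed order.
    """

    P: int = 17                       # plant species
    A: int = 98                       # wild pollinator species
    rate_shape: tuple = (-4.8, 1.5)   # lognormal (mu, sigma) of per-pair rates
    nestedness_skew: float = 1.0      # Zipf exponent of marginal heterogeneity
    individuals_per_plant: int = 10
    censuses_per_plant_per_period: int = 86
    apis_share: float = 0.4           # invader's target share of apis-period visits
    suppression: float = 0.5          # multiplier on wild rates in apis period
    dropout_k: int = 3                # wild species forced to zero in apis period
    apis_top_q: int = 4               # invader concentrates on this many top plants
    apis_top_share: float = 0.8       # ... receiving this share of invader visits
    year: int = 2008
    apis_name: str = "Apis mellifera"
    nb_dispersion: float | None = None  # negative-binomial k; None = Poisson
    seed: int = 0

    def validate(self) -> None:
        if self.P < 1 or self.A < 1:
            raise ValueError("P and A must be positive")
        if not 0 <= self.suppression <= 1:
            raise ValueError("suppression must be in [0, 1]")
        if not 0 <= self.apis_share < 1:
            raise ValueError("apis_share must be in [0, 1)")
        if self.dropout_k < 0 or self.dropout_k > self.A:
            raise ValueError("dropout_k must be in [0, A]")
        if self.censuses_per_plant_per_period < 1 or self.individuals_per_plant < 1:
            raise ValueError("census and individual counts must be positive")


def _zipf_weights(n: int, skew: float) -> np.ndarray:
    """Decreasing Zipf-like weights with mean 1."""
    w = (np.arange(1, n + 1, dtype=float)) ** (-skew)
    return w * n / w.sum()


def _draw_counts(rng, lam: np.ndarray, k: float | None) -> np.ndarray:
    if k is None:
        return rng.poisson(lam)
    # negative binomial with mean lam and dispersion k (variance lam + lam^2/k)
    p = k / (k + np.maximum(lam, 1e-12))
    return np.where(lam > 0, rng.negative_binomial(k, p), 0)


def generate_censuses(params: CommunityParams) -> SurveyDataset:
    """Simulate the full two-period census dataset as a :class:`SurveyDataset`."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    P, A = params.P, params.A
    mu, sigma = params.rate_shape

    a = _zipf_weights(P, params.nestedness_skew)          # plant attractiveness
    b = _zipf_weights(A, params.nestedness_skew)          # pollinator activity
    noise = np.exp(rng.normal(mu, sigma, size=(P, A)))
    lam = noise * a[:, None] * b[None, :]                 # visits per census

    # the invader's exploitative competition removes the most active wild
    # foragers first (large generalists), so dropout hits the top-activity
    # species — losing those connector interactions fragments the network
    drop = np.argsort(-b)[: params.dropout_k] if params.dropout_k else []
    lam_apis = lam * params.suppression
    lam_apis[:, list(drop)] = 0.0

    n_c = params.censuses_per_plant_per_period
    if params.apis_share > 0:
        wild_expected = lam_apis.sum() * n_c
        apis_total = params.apis_share / (1 - params.apis_share) * wild_expected
        top = np.argsort(-a)[: params.apis_top_q]
        w = np.zeros(P)
        w[top] = params.apis_top_share * a[top] / a[top].sum()
        rest = np.setdiff1d(np.arange(P), top)
        if len(rest):
            w[rest] = (1 - params.apis_top_share) * a[rest] / a[rest].sum()
        else:
            w[top] /= w[top].sum()
        apis_rate = apis_total * w / n_c                  # per census on plant i
    else:
        apis_rate = np.zeros(P)

    plants = [f"Plant_{i + 1:02d}" for i in range(P)]
    wild = [f"Wild_{j + 1:02d}" for j in range(A)]
    # per-individual census allocation: as even as possible
    n_ind = params.individuals_per_plant
    base, extra = divmod(n_c, n_ind)
    ind_sizes = [base + (1 if k < extra else 0) for k in range(n_ind)]

    rows: list[tuple] = []
    for period in ("pre", "apis"):
        for i, plant in enumerate(plants):
            rates = lam[i] if period == "pre" else lam_apis[i]
            cnum = 0
            for ind_k, size in enumerate(ind_sizes):
                if size == 0:
                    continue
                counts = _draw_counts(rng, np.tile(rates, (size, 1)),
                                      params.nb_dispersion)
                if period == "apis" and apis_rate[i] > 0:
                    apis_counts = rng.poisson(apis_rate[i], size=size)
                else:
                    apis_counts = np.zeros(size, dtype=int)
                for s in range(size):
                    cid = f"{params.year}-{period}-{plant}-{cnum:03d}"
                    cnum += 1
                    ind = f"{plant}-ind{ind_k + 1:02d}"
                    nz = np.nonzero(counts[s])[0]
                    any_row = False
                    for j in nz:
                        rows.append((cid, params.year, period, "focal5min", plant,
                                     ind, wild[j], int(counts[s, j]), 5.0))
                        any_row = True
                    if apis_counts[s] > 0:
                        rows.append((cid, params.year, period, "focal5min", plant,
                                     ind, params.apis_name, int(apis_counts[s]), 5.0))
                        any_row = True
                    if not any_row:
                        rows.append((cid, params.year, period, "focal5min", plant,
                                     ind, NO_VISIT, 0, 5.0))

    records = pd.DataFrame(
        rows,
        columns=["census_id", "year", "period", "census_type", "plant_species",
                 "plant_individual", "pollinator_species", "count", "duration_min"],
    )
    return SurveyDataset.from_records(records, apis_name=params.apis_name)


# ----------------------------------------------------------------------
@dataclasses.dataclass
class ReproductionParams:
    """Paired pre/apis reproduction design with shared plant effects.

    Period means emulate the direction reported for plants highly visited
    by honeybees: fruit-set rises but seeds per fruit fall in the apis
    period.
    """

    species: str = "FocalPlant"
    n_plants: int = 25
    flowers_mean: float = 60.0
    fruit_set: tuple = (0.38, 0.62)       # (pre, apis) fruit-set probability
    seeds_mean: tuple = (2.1, 1.6)        # (pre, apis) seeds per fruit
    ovules_extra_mean: float = 4.0        # aborted ovules per fruit
    seed_mass_mg: tuple = (10.0, 9.0)     # (pre, apis) mean seed mass
    mass_sigma: float = 0.25
    plant_sd: float = 0.3                 # SD of the shared plant random effect
    seed: int = 0


def generate_reproduction(params: ReproductionParams) -> pd.DataFrame:
    """Per-fruit reproduction table; same plants measured in both periods."""
    rng = np.random.default_rng(params.seed)
    rows = []
    logit = lambda p: np.log(p / (1 - p))
    inv_logit = lambda x: 1 / (1 + np.exp(-x))
    for k in range(params.n_plants):
        plant = f"{params.species}-{k + 1:03d}"
        u = rng.normal(0.0, params.plant_sd)
        for pi, period in enumerate(("pre", "apis")):
            flowers = int(rng.poisson(params.flowers_mean))
            if flowers == 0:
                warnings.warn(f"plant {plant} had no flowers in {period}; excluded")
                continue
            p = inv_logit(logit(params.fruit_set[pi]) + u)
            fruits = int(rng.binomial(flowers, p))
            if fruits == 0:
                rows.append((params.species, plant, period, flowers, 0,
                             np.nan, np.nan, np.nan, np.nan))
                continue
            lam = params.seeds_mean[pi] * np.exp(u)
            seeds = rng.poisson(lam, size=fruits)
            ovules = seeds + rng.poisson(params.ovules_extra_mean, size=fruits)
            mass = np.exp(rng.normal(np.log(params.seed_mass_mg[pi]),
                                     params.mass_sigma, size=fruits))
            mass = np.where(seeds > 0, mass, np.nan)
            for f in range(fruits):
                rows.append((params.species, plant, period, flowers, fruits,
                             f"F{f + 1:03d}", int(seeds[f]), int(ovules[f]),
                             mass[f]))
    return pd.DataFrame(rows, columns=REPRODUCTION_COLUMNS)


# ----------------------------------------------------------------------
@dataclasses.dataclass
class DistanceParams:
    """Distance-from-apiary gradient for one plant species.

    Invader pressure decays as exp(-d / L); near the hives fruits are
    empty more often, carry fewer seeds, and the surviving seeds are
    heavier.  Per-class plant numbers and the 50-fruit collection mirror
    the motivating design.
    """

    species: str = "FocalPlant"
    classes: tuple = (0, 100, 500, 1000, 2000, 4000)
    n_plants_per_class: tuple = (60, 45, 30, 34, 19, 31)
    fruits_per_plant: int = 50
    decay_L: float = 300.0                # metres
    empty_p: tuple = (0.40, 0.03)         # (near-hive, far) empty-fruit probability
    seeds_mean: tuple = (1.5, 2.5)        # (near, far) seeds per non-empty fruit
    mass_mg: tuple = (11.0, 9.0)          # (near, far) seed mass
    aborted_mean: tuple = (6.0, 3.0)      # (near, far) aborted ovules per fruit
    mass_sigma: float = 0.2
    plant_sd: float = 0.2
    seed: int = 0


def _pressure(d: float, L: float) -> float:
    if L <= 0:
        return 1.0 if d == 0 else 0.0
    return float(np.exp(-d / L))


def generate_distance_gradient(params: DistanceParams) -> pd.DataFrame:
    """Per-fruit distance-gradient table."""
    if len(params.classes) != len(params.n_plants_per_class):
        raise ValueError("classes and n_plants_per_class must have equal length")
    rng = np.random.default_rng(params.seed)
    rows = []
    for d, n_plants in zip(params.classes, params.n_plants_per_class):
        pi = _pressure(d, params.decay_L)
        p_empty = params.empty_p[1] + (params.empty_p[0] - params.empty_p[1]) * pi
        lam = params.seeds_mean[1] + (params.seeds_mean[0] - params.seeds_mean[1]) * pi
        mass_mu = params.mass_mg[1] + (params.mass_mg[0] - params.mass_mg[1]) * pi
        abort = params.aborted_mean[1] + (params.aborted_mean[0] - params.aborted_mean[1]) * pi
        for k in range(n_plants):
            plant = f"{params.species}-d{d}-{k + 1:03d}"
            u = rng.normal(0.0, params.plant_sd)
            empty = rng.random(params.fruits_per_plant) < p_empty
            seeds = np.where(
                empty, 0, rng.poisson(lam * np.exp(u), size=params.fruits_per_plant)
            )
            ovules = seeds + rng.poisson(abort, size=params.fruits_per_plant)
            mass = np.exp(rng.normal(np.log(mass_mu) + u * 0.1, params.mass_sigma,
                                     size=params.fruits_per_plant))
            mass = np.where(seeds > 0, mass, np.nan)
            for f in range(params.fruits_per_plant):
                rows.append((params.species, plant, d, f"F{f + 1:03d}",
                             int(seeds[f]), int(ovules[f]), mass[f]))
    return pd.DataFrame(rows, columns=DISTANCE_COLUMNS)
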