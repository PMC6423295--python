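"""From census records to interaction matrices.

The quantitative matrix ``W`` holds the average visit rate of each
pollinator species to each plant species: total visits divided by the number
of censuses watched on that plant.  Because 5-min focal censuses and short
spot censuses differ in duration, each census type keeps its own
denominator and the per-type rates are summed.  Presence-only "extra"
records enter the qualitative 0/1 matrix ``B`` but never a rate.

Also here: interaction accumulation curves (sample-based rarefaction over
census order) and effort-matched subsampling of a control period.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census_io import NO_VISIT, SurveyDataset, ValidationError

__all__ = [
    "InteractionMatrix",
    "CensusArrays",
    "build_matrix",
    "compile_censuses",
    "matrix_from_arrays",
    "accumulation_curve",
    "subsample_control",
]

RATE_MODES = ("pooled", "individual_mean")

#: census types that carry visit-rate information (extras are presence-only)
_RATE_TYPES = ("focal5min", "spot")


@dataclasses.dataclass
class InteractionMatrix:
    """A plant x pollinator interaction matrix for one period/year slice.

    Attributes
    ----------
    W : (P, A) float array
        Mean visits per census (rates; per census type, then summed).
    B : (P, A) int8 array
        Qualitative matrix: ``B[i, j] = 1`` iff ``W[i, j] > 0`` or an
        extra (presence-only) record exists for the pair.
    plants, pollinators : list of str
        Row / column labels.
    period, year
        Slice labels (``None`` when pooled).
    provenance : dict
        Censuses used, species excluded, rate mode.
    """

    W: np.ndarray
    B: np.ndarray
    plants: list
    pollinators: list
    period: object = None
    year: object = None
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def P(self) -> int:
        return self.W.shape[0]

    @property
    def A(self) -> int:
        return self.W.shape[1]

    @property
    def I(self) -> int:
        """Number of links (ones in the qualitative matrix)."""
        return int(self.B.sum())

    def drop_species(self, names) -> "InteractionMatrix":
        """Return a copy with the named species (either guild) removed."""
        names = set(names)
        rk = [i for i, p in enumerate(self.plants) if p not in names]
        ck = [j for j, a in enumerate(self.pollinators) if a not in names]
        return InteractionMatrix(
            W=self.W[np.ix_(rk, ck)].copy(),
            B=self.B[np.ix_(rk, ck)].copy(),
            plants=[self.plants[i] for i in rk],
            pollinators=[self.pollinators[j] for j in ck],
            period=self.period,
            year=self.year,
            provenance=dict(self.provenance, dropped=sorted(names)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.plants, columns=self.pollinators)


# ----------------------------------------------------------------------
# Compiled census arrays: the fast path shared by bootstrap / permutation
# ----------------------------------------------------------------------

@dataclasses.dataclass
class CensusArrays:
    """Dense per-census arrays for one period/year slice.

    One row of ``counts`` per census (focal or spot); extras are folded into
    ``extra_B``.  ``strata`` groups censuses by
    (plant_species, plant_individual, census_type) — the resampling unit of
    the census bootstrap.
    """

    plants: list
    pollinators: list
    counts: np.ndarray          # (n_cens, A) int
    plant_idx: np.ndarray       # (n_cens,) row index per census
    type_idx: np.ndarray        # (n_cens,) 0 = focal5min, 1 = spot
    period: np.ndarray          # (n_cens,) period label per census
    census_ids: list            # (n_cens,) original census identifiers
    strata: list                # list of int arrays of census indices
    stratum_plant: np.ndarray   # (n_strata,) plant row of each stratum
    extra_B: np.ndarray         # (P, A) presence from extra records (pooled)
    extra_B_by_period: dict     # period -> (P, A) presence matrix
    denom: np.ndarray           # (P, 2) census count per plant x type

    @property
    def n_censuses(self) -> int:
        return self.counts.shape[0]


def compile_censuses(
    data: SurveyDataset,
    period: str | None = None,
    year: int | None = None,
) -> CensusArrays:
    """Compile a dataset slice into :class:`CensusArrays`."""
    sub = data.filter(period=period, year=year)
    df = sub.records
    plants = sorted(sub.plants)
    polls = sorted(sub.pollinators)
    p_ix = {p: i for i, p in enumerate(plants)}
    a_ix = {a: j for j, a in enumerate(polls)}
    P, A = len(plants), len(polls)

    rate = df[df["census_type"].isin(_RATE_TYPES)]
    extra = df[df["census_type"] == "extra"]

    cens = rate.groupby("census_id", sort=False)
    ids = list(cens.groups)
    n = len(ids)
    counts = np.zeros((n, A), dtype=np.int64)
    plant_idx = np.zeros(n, dtype=np.intp)
    type_idx = np.zeros(n, dtype=np.intp)
    period_arr = np.empty(n, dtype=object)
    stratum_key = []
    for k, (cid, g) in enumerate(cens):
        plant = g["plant_species"].iat[0]
        ctype = g["census_type"].iat[0]
        plant_idx[k] = p_ix[plant]
        type_idx[k] = 0 if ctype == "focal5min" else 1
        period_arr[k] = g["period"].iat[0]
        stratum_key.append((plant, g["plant_individual"].iat[0], ctype))
        vis = g[(g["pollinator_species"] != NO_VISIT) & (g["count"] > 0)]
        for sp, c in zip(vis["pollinator_species"], vis["count"]):
            counts[k, a_ix[sp]] += int(c)

    order: dict = {}
    for k, key in enumerate(stratum_key):
        order.setdefault(key, []).append(k)
    strata = [np.asarray(v, dtype=np.intp) for v in order.values()]
    stratum_plant = np.asarray(
        [plant_idx[v[0]] for v in strata], dtype=np.intp
    ) if strata else np.zeros(0, dtype=np.intp)

    extra_B = np.zeros((P, A), dtype=np.int8)
    extra_B_by_period: dict = {}
    ev = extra[(extra["pollinator_species"] != NO_VISIT) & (extra["count"] > 0)]
    for sp, pl, per in zip(ev["pollinator_species"], ev["plant_species"], ev["period"]):
        extra_B[p_ix[pl], a_ix[sp]] = 1
        extra_B_by_period.setdefault(per, np.zeros((P, A), dtype=np.int8))[
            p_ix[pl], a_ix[sp]
        ] = 1

    denom = np.zeros((P, 2), dtype=np.int64)
    np.add.at(denom, (plant_idx, type_idx), 1)

    return CensusArrays(
        plants=plants,
        pollinators=polls,
        counts=counts,
        plant_idx=plant_idx,
        type_idx=type_idx,
        period=period_arr,
        census_ids=ids,
        strata=strata,
        stratum_plant=stratum_plant,
        extra_B=extra_B,
        extra_B_by_period=extra_B_by_period,
        denom=denom,
    )


def matrix_from_arrays(
    arr: CensusArrays,
    census_indices: np.ndarray | None = None,
    drop_empty: bool = True,
    extra_B: np.ndarray | None = None,
    period=None,
    year=None,
) -> InteractionMatrix:
    """Build a pooled-rate matrix from (a resample of) compiled censuses.

    ``census_indices`` may repeat indices (bootstrap) or select a subset
    (permutation).  Rate denominators are recomputed from the selection so
    the construction is exactly the one applied to the observed data.
    ``extra_B`` overrides the presence matrix contributed by extra records
    (used when the compiled slice pools several periods).
    """
    P = len(arr.plants)
    A = len(arr.pollinators)
    if census_indices is None:
        ci = np.arange(arr.n_censuses, dtype=np.intp)
    else:
        ci = np.asarray(census_indices, dtype=np.intp)
    # group censuses by (plant, type) and sum counts at C speed
    gid = arr.plant_idx[ci] * 2 + arr.type_idx[ci]
    order = np.argsort(gid, kind="stable")
    gs = gid[order]
    totals = np.zeros((P * 2, A), dtype=np.float64)
    denom = np.zeros(P * 2, dtype=np.float64)
    if len(gs):
        starts = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])
        groups = gs[starts]
        sums = np.add.reduceat(arr.counts[ci[order]], starts, axis=0)
        totals[groups] = sums
        denom[groups] = np.diff(np.r_[starts, len(gs)])
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(denom[:, None] > 0, totals / np.maximum(denom[:, None], 1), 0.0)
    W = rates.reshape(P, 2, A).sum(axis=1)
    eB = arr.extra_B if extra_B is None else extra_B
    B = ((W > 0) | (eB > 0)).astype(np.int8)
    m = InteractionMatrix(W=W, B=B, plants=list(arr.plants),
                          pollinators=list(arr.pollinators), period=period, year=year)
    if drop_empty:
        m = _drop_empty(m)
    return m


def _drop_empty(m: InteractionMatrix) -> InteractionMatrix:
    """Restrict to species with at least one link (the observed network)."""
    rk = m.B.sum(axis=1) > 0
    ck = m.B.sum(axis=0) > 0
    if rk.all() and ck.all():
        return m
    return InteractionMatrix(
        W=m.W[np.ix_(rk.nonzero()[0], ck.nonzero()[0])],
        B=m.B[np.ix_(rk.nonzero()[0], ck.nonzero()[0])],
        plants=[p for p, k in zip(m.plants, rk) if k],
        pollinators=[a for a, k in zip(m.pollinators, ck) if k],
        period=m.period,
        year=m.year,
        provenance=dict(
            m.provenance,
            excluded_plants=[p for p, k in zip(m.plants, rk) if not k],
            excluded_pollinators=[a for a, k in zip(m.pollinators, ck) if not k],
        ),
    )


# ----------------------------------------------------------------------
# The user-facing constructor
# ----------------------------------------------------------------------

def build_matrix(
    data: SurveyDataset,
    period: str | None = None,
    year: int | None = None,
    rate_mode: str = "pooled",
    drop_empty: bool = True,
) -> InteractionMatrix:
    """Build the interaction matrix for one period/year slice.

    Parameters
    ----------
    rate_mode
        ``"pooled"`` (default): W[i, j] = total visits / total censuses on
        plant i, per census type, summed over types.  Weights censuses by
        effort.  ``"individual_mean"``: mean over plant individuals of each
        individual's own mean rate; every individual weighs equally
        regardless of how often it was watched.
    drop_empty
        Restrict the matrix to species with at least one link.  Plant
        species observed in zero censuses in the slice are excluded with a
        warning either way.
    """
    if rate_mode not in RATE_MODES:
        raise ValueError(f"rate_mode must be one of {RATE_MODES}")
    arr = compile_censuses(data, period=period, year=year)
    if rate_mode == "pooled":
        m = matrix_from_arrays(arr, drop_empty=drop_empty, period=period, year=year)
    else:
        m = _individual_mean_matrix(arr, drop_empty=drop_empty, period=period, year=year)

    sampled = {arr.plants[i] for i in np.unique(arr.plant_idx)} | {
        arr.plants[i] for i in np.nonzero(arr.extra_B.any(axis=1))[0]
    }
    missing = sorted(set(arr.plants) - sampled)
    if missing:
        warnings.warn(f"plant species with zero censuses excluded: {missing}")
    m.provenance.update(
        rate_mode=rate_mode,
        n_censuses=int(arr.n_censuses),
        plants_without_censuses=missing,
    )
    return m


def _individual_mean_matrix(arr: CensusArrays, drop_empty, period, year) -> InteractionMatrix:
    P, A = len(arr.plants), len(arr.pollinators)
    # per-stratum (= per individual x type) mean rate, then average over the
    # individuals of each plant, per census type
    W = np.zeros((P, 2, A))
    n_ind = np.zeros((P, 2))
    for s, idx in enumerate(arr.strata):
        i = arr.stratum_plant[s]
        t = arr.type_idx[idx[0]]
        W[i, t] += arr.counts[idx].mean(axis=0)
        n_ind[i, t] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(n_ind[:, :, None] > 0, W / np.maximum(n_ind[:, :, None], 1), 0.0)
    W = W.sum(axis=1)
    B = ((W > 0) | (arr.extra_B > 0)).astype(np.int8)
    m = InteractionMatrix(W=W, B=B, plants=list(arr.plants),
                          pollinators=list(arr.pollinators), period=period, year=year)
    return _drop_empty(m) if drop_empty else m


# ----------------------------------------------------------------------
# Interaction accumulation curves
# ----------------------------------------------------------------------

def accumulation_curve(
    data: SurveyDataset,
    period: str | None = None,
    year: int | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample-based rarefaction of distinct links over census order.

    Censuses (focal and spot; extras excluded) are accumulated in ``n_perm``
    random orders; the curve reports the mean and SD of the number of
    distinct plant-pollinator links after each census.  The final point
    always equals the total number of distinct links in the censuses, with
    zero SD.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    arr = compile_censuses(data, period=period, year=year)
    n = arr.n_censuses
    if n == 0:
        raise ValidationError("no censuses in the requested slice")

    A = len(arr.pollinators)
    link_of_census: list[np.ndarray] = [
        arr.plant_idx[k] * A + np.nonzero(arr.counts[k])[0] for k in range(n)
    ]
    links = np.unique(np.concatenate(link_of_census)) if any(
        len(x) for x in link_of_census
    ) else np.array([], dtype=int)
    L = len(links)
    # incidence: which censuses contain each link
    inc = np.zeros((L, n), dtype=bool)
    pos_of = {l: r for r, l in enumerate(links)}
    for k, ls in enumerate(link_of_census):
        for l in ls:
            inc[pos_of[l], k] = True

    rng = np.random.default_rng(seed)
    curves = np.zeros((n_perm, n), dtype=np.int64)
    big = n + 1
    for p in range(n_perm):
        order = rng.permutation(n)
        pos = np.empty(n, dtype=np.int64)
        pos[order] = np.arange(n)
        if L:
            first = np.where(inc, pos[None, :], big).min(axis=1)
            curves[p] = np.cumsum(np.bincount(first, minlength=n)[:n])
    return pd.DataFrame(
        {
            "n_censuses": np.arange(1, n + 1),
            "mean_links": curves.mean(axis=0),
            "sd_links": curves.std(axis=0, ddof=0),
        }
    )


# ----------------------------------------------------------------------
# Effort-matched control subsampling
# ----------------------------------------------------------------------

def subsample_control(
    data: SurveyDataset,
    target_sizes: Mapping,
    seed: int | None = None,
) -> SurveyDataset:
    """Subsample censuses so each (plant_species, period) stratum matches a
    target census count; used to give a control year the same sampling
    effort as the experimental years.

    ``target_sizes`` maps ``(plant_species, period)`` to the desired number
    of censuses.  Sampling is without replacement and seeded.  Strata not
    named keep all their censuses; presence-only extra records pass through
    untouched.
    """
    rng = np.random.default_rng(seed)
    df = data.records
    is_extra = df["census_type"] == "extra"
    cens = df[~is_extra].groupby("census_id", sort=False)[["plant_species", "period"]].first()

    keep_ids: list = []
    offending = []
    for (plant, period), want in sorted(target_sizes.items()):
        ids = cens.index[(cens["plant_species"] == plant) & (cens["period"] == period)]
        if want > len(ids):
            offending.append((plant, period, want, len(ids)))
            continue
        chosen = rng.choice(np.asarray(ids, dtype=object), size=want, replace=False)
        keep_ids.extend(chosen.tolist())
    if offending:
        raise ValidationError(
            "target exceeds available censuses for strata "
            + ", ".join(f"{p}/{q}: want {w}, have {h}" for p, q, w, h in offending)
        )
    named = {(p, q) for p, q in target_sizes}
    untouched = cens.index[~cens[["plant_species", "period"]].apply(tuple, axis=1).isin(named)]
    keep = set(keep_ids) | set(untouched)
    out = df[is_extra | df["census_id"].isin(keep)].reset_index(drop=True)
    return SurveyDataset(
        records=out,
        plants=set(data.plants),
        pollinators=set(data.pollinators),
        apis_name=data.apis_name,
    )
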