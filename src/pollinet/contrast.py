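"""Resampling tests for pre- vs apis-period differences in network metrics.

Two randomization schemes are provided, because the motivating study
describes its test in two not-quite-identical ways:

``label_permutation`` (default for p-values)
    Within every (plant species, plant individual, census type) stratum the
    period labels of the censuses are reshuffled, preserving each period's
    census count in the stratum.  This is a proper exchangeability null:
    under no beekeeping effect the period label carries no information.

``bootstrap``
    Each period's censuses are resampled with replacement within the same
    strata (sample sizes preserved exactly), mirroring the study's
    z-score construction: the null distribution describes the sampling
    variability of the difference rather than a no-effect null.

In both modes the difference is reported as (apis - pre); the z-score is
the observed difference standardised by the null distribution, and two
p-values are reported: the empirical permutation rank (with +1 continuity
correction) and the normal tail area of the z-score.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .census_io import SurveyDataset, ValidationError
from .modularity import consensus_modules
from .network_build import (
    CensusArrays,
    InteractionMatrix,
    compile_censuses,
    matrix_from_arrays,
)
from .network_metrics import METRICS

__all__ = [
    "ContrastResult",
    "resample_censuses",
    "contrast_metric",
    "contrast_battery",
    "make_nM_metric",
    "make_Q_metric",
]

MODES = ("bootstrap", "label_permutation")


@dataclasses.dataclass
class ContrastResult:
    """Observed pre/apis difference of one metric with its null distribution."""

    metric_name: str
    observed_pre: float
    observed_apis: float
    observed_diff: float          # apis - pre
    null_diffs: np.ndarray
    z_score: float
    p_value: float                # empirical rank p (two-sided, +1 corrected)
    p_normal: float               # normal tail area of the z-score
    mode: str
    seed: object
    n_redraws: int = 0

    def summary(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("null_diffs")
        d["n_resamples"] = int(len(self.null_diffs))
        return d


# ----------------------------------------------------------------------
def resample_censuses(
    data: SurveyDataset,
    period: str | None = None,
    year: int | None = None,
    seed: int | None = None,
) -> SurveyDataset:
    """One census bootstrap of a dataset slice.

    Censuses are drawn with replacement within
    (plant species, plant individual, census type) strata, preserving each
    stratum's size exactly, so spot censuses are resampled among
    themselves.  Presence-only extra records pass through unchanged.
    Duplicated draws receive suffixed census ids to keep ids unique.
    """
    rng = np.random.default_rng(seed)
    sub = data.filter(period=period, year=year)
    df = sub.records
    is_extra = df["census_type"] == "extra"
    cens = df[~is_extra].groupby("census_id", sort=False)[
        ["plant_species", "plant_individual", "census_type"]
    ].first()
    if len(cens) == 0:
        raise ValidationError("no censuses to resample in the requested slice")

    strata = cens.groupby(["plant_species", "plant_individual", "census_type"],
                          sort=True).groups
    rows_by_id = {cid: g for cid, g in df[~is_extra].groupby("census_id", sort=False)}
    out = [df[is_extra]]
    for key in sorted(strata):
        ids = list(strata[key])
        draw = rng.integers(0, len(ids), size=len(ids))
        for k, d in enumerate(draw):
            block = rows_by_id[ids[d]].copy()
            block["census_id"] = f"{ids[d]}#b{k}"
            out.append(block)
    import pandas as pd

    records = pd.concat(out, ignore_index=True)
    return SurveyDataset(
        records=records,
        plants=set(sub.plants),
        pollinators=set(sub.pollinators),
        apis_name=sub.apis_name,
    )


# ----------------------------------------------------------------------
# The fast array-level engine
# ----------------------------------------------------------------------

class _Engine:
    """Precompiled resampling engine over one year slice with both periods."""

    def __init__(self, data: SurveyDataset, year=None,
                 period_pre: str = "pre", period_apis: str = "apis"):
        self.arr = compile_censuses(data, year=year)
        self.period_pre = period_pre
        self.period_apis = period_apis
        per = self.arr.period
        self.pre_all = np.flatnonzero(per == period_pre)
        self.apis_all = np.flatnonzero(per == period_apis)
        if len(self.pre_all) == 0 or len(self.apis_all) == 0:
            raise ValidationError("both periods must be present in the data")
        P, A = len(self.arr.plants), len(self.arr.pollinators)
        zero = np.zeros((P, A), dtype=np.int8)
        self.eB_pre = self.arr.extra_B_by_period.get(period_pre, zero)
        self.eB_apis = self.arr.extra_B_by_period.get(period_apis, zero)
        # per-stratum index arrays split by period
        self.strata_pre = []
        self.strata_apis = []
        for idx in self.arr.strata:
            mask = per[idx] == period_pre
            self.strata_pre.append(idx[mask])
            self.strata_apis.append(idx[~mask])

    def observed(self):
        m_pre = matrix_from_arrays(self.arr, self.pre_all, extra_B=self.eB_pre,
                                   period=self.period_pre)
        m_apis = matrix_from_arrays(self.arr, self.apis_all, extra_B=self.eB_apis,
                                    period=self.period_apis)
        return m_pre, m_apis

    def draw(self, rng: np.random.Generator, mode: str):
        """Index arrays (pre, apis) for one resample."""
        pre_parts = []
        apis_parts = []
        if mode == "bootstrap":
            for sp, sa in zip(self.strata_pre, self.strata_apis):
                if len(sp):
                    pre_parts.append(sp[rng.integers(0, len(sp), size=len(sp))])
                if len(sa):
                    apis_parts.append(sa[rng.integers(0, len(sa), size=len(sa))])
        else:  # label_permutation
            for idx, sp in zip(self.arr.strata, self.strata_pre):
                n_pre = len(sp)
                perm = rng.permutation(idx)
                pre_parts.append(perm[:n_pre])
                apis_parts.append(perm[n_pre:])
        pre = np.concatenate(pre_parts) if pre_parts else np.zeros(0, dtype=np.intp)
        apis = np.concatenate(apis_parts) if apis_parts else np.zeros(0, dtype=np.intp)
        return pre, apis

    def matrices(self, pre_idx, apis_idx):
        m_pre = matrix_from_arrays(self.arr, pre_idx, extra_B=self.eB_pre,
                                   period=self.period_pre)
        m_apis = matrix_from_arrays(self.arr, apis_idx, extra_B=self.eB_apis,
                                    period=self.period_apis)
        return m_pre, m_apis


def _finish(metric_name, obs_pre, obs_apis, null, mode, seed, n_redraws) -> ContrastResult:
    null = np.asarray(null, dtype=float)
    obs_diff = obs_apis - obs_pre
    mu = null.mean()
    sd = null.std(ddof=1) if len(null) > 1 else 0.0
    z = (obs_diff - mu) / sd if sd > 0 else (0.0 if obs_diff == mu else np.inf * np.sign(obs_diff - mu))
    p_emp = (np.sum(np.abs(null - mu) >= abs(obs_diff - mu)) + 1) / (len(null) + 1)
    p_norm = float(2 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return ContrastResult(
        metric_name=metric_name,
        observed_pre=float(obs_pre),
        observed_apis=float(obs_apis),
        observed_diff=float(obs_diff),
        null_diffs=null,
        z_score=float(z),
        p_value=float(p_emp),
        p_normal=p_norm,
        mode=mode,
        seed=seed,
        n_redraws=n_redraws,
    )


def contrast_metric(
    data: SurveyDataset,
    metric_fn: Callable[[InteractionMatrix], float],
    metric_name: str = "metric",
    year: int | None = None,
    n_resamples: int = 5000,
    mode: str = "label_permutation",
    seed: int | None = None,
    max_failure_frac: float = 0.05,
) -> ContrastResult:
    """Test the pre/apis difference of one network metric by resampling.

    The observed difference is computed once from the real matrices; the
    null distribution holds the metric difference across ``n_resamples``
    stratified resamples (see module docstring for the two modes).  A
    resample on which the metric fails (e.g. a degenerate matrix) is
    redrawn; more than ``max_failure_frac`` failures aborts.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    eng = _Engine(data, year=year)
    m_pre, m_apis = eng.observed()
    obs_pre = metric_fn(m_pre)
    obs_apis = metric_fn(m_apis)

    rng = np.random.default_rng(seed)
    null = np.empty(n_resamples)
    redraws = 0
    max_fail = max(1, int(np.ceil(max_failure_frac * n_resamples)))
    k = 0
    while k < n_resamples:
        pre_idx, apis_idx = eng.draw(rng, mode)
        try:
            r_pre, r_apis = eng.matrices(pre_idx, apis_idx)
            null[k] = metric_fn(r_apis) - metric_fn(r_pre)
        except Exception:
            redraws += 1
            if redraws > max_fail:
                raise RuntimeError(
                    f"metric {metric_name!r} failed on more than "
                    f"{max_failure_frac:.0%} of resamples"
                )
            continue
        k += 1
    return _finish(metric_name, obs_pre, obs_apis, null, mode, seed, redraws)


def contrast_battery(
    data: SurveyDataset,
    metrics: Mapping[str, Callable] | Sequence[str],
    year: int | None = None,
    n_resamples: int = 5000,
    mode: str = "label_permutation",
    seed: int | None = None,
    max_failure_frac: float = 0.05,
) -> list[ContrastResult]:
    """Contrast several metrics on a *shared* resample stream.

    Every metric sees exactly the same resampled matrices, so the battery
    is comparable metric-to-metric.  ``metrics`` is either a mapping
    name -> callable or a sequence of names from
    :data:`pollinet.network_metrics.METRICS`.
    """
    if not isinstance(metrics, Mapping):
        metrics = {name: METRICS[name] for name in metrics}
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    eng = _Engine(data, year=year)
    m_pre, m_apis = eng.observed()
    names = list(metrics)
    obs_pre = {n: metrics[n](m_pre) for n in names}
    obs_apis = {n: metrics[n](m_apis) for n in names}

    rng = np.random.default_rng(seed)
    null = {n: np.empty(n_resamples) for n in names}
    redraws = 0
    max_fail = max(1, int(np.ceil(max_failure_frac * n_resamples)))
    k = 0
    while k < n_resamples:
        pre_idx, apis_idx = eng.draw(rng, mode)
        try:
            r_pre, r_apis = eng.matrices(pre_idx, apis_idx)
            vals = {n: metrics[n](r_apis) - metrics[n](r_pre) for n in names}
        except Exception:
            redraws += 1
            if redraws > max_fail:
                raise RuntimeError(
                    f"battery failed on more than {max_failure_frac:.0%} of resamples"
                )
            continue
        for n in names:
            null[n][k] = vals[n]
        k += 1
    return [
        _finish(n, obs_pre[n], obs_apis[n], null[n], mode, seed, redraws)
        for n in names
    ]


# ----------------------------------------------------------------------
# Modularity-based metrics for the battery (reduced effort, documented)
# ----------------------------------------------------------------------

def make_nM_metric(n_runs: int = 5, steps: int = 2000, seed: int = 0) -> Callable:
    """Metric callable returning the mean number of modules over a reduced
    number of annealing runs (full 50-run consensus would be prohibitive
    inside a resampling loop).  Deterministic for a given matrix."""

    def nM(m: InteractionMatrix) -> float:
        res = consensus_modules(m, n_runs=n_runs, seed=seed, steps=steps)
        return res.mean_nM

    nM.__name__ = "nM"
    return nM


def make_Q_metric(n_runs: int = 5, steps: int = 2000, seed: int = 0) -> Callable:
    """Metric callable returning the best modularity Q over a reduced number
    of annealing runs."""

    def Q(m: InteractionMatrix) -> float:
        res = consensus_modules(m, n_runs=n_runs, seed=seed, steps=steps)
        return float(res.Q_per_run.max())

    Q.__name__ = "Q"
    return Q
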