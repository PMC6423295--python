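"""Weighted bipartite modularity via simulated annealing, multi-run
consensus, and species topological roles.

Modularity follows Barber's bipartite formulation with interaction
weights::

    Q = (1/F) * sum_ij [ W_ij - r_i * s_j / F ] * delta(module_i, module_j)

with ``F`` the total interaction weight, ``r`` and ``s`` the plant and
pollinator marginal totals, and the delta ranging over plant-pollinator
pairs only.  A single shared module gives Q = 0; well-separated blocks
approach Q = 1 - 1/k.

The optimiser is a simulated-annealing search in the spirit of the QuanBiMo
algorithm: single-species reassignments plus occasional module merges,
geometric cooling, and a final greedy polish to the nearest local optimum.
Module counts vary between runs, so the consensus machinery reports the
mean (+/- SD) number of modules over many runs and a modal per-species
assignment after aligning module labels across runs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .network_build import InteractionMatrix

__all__ = [
    "ModulePartition",
    "ConsensusResult",
    "modularity_Q",
    "quanbimo_anneal",
    "consensus_modules",
    "species_roles",
    "role_thresholds",
    "role_trend_test",
    "ROLE_CLASSES",
]

ROLE_CLASSES = ("peripheral", "connector", "module_hub", "network_hub")


@dataclasses.dataclass
class ModulePartition:
    """A module assignment for every species of both guilds."""

    assignment: dict          # species name -> module id (0..nM-1)
    Q: float
    nM: int
    seed: object = None

    def modules_of(self, names) -> np.ndarray:
        return np.asarray([self.assignment[n] for n in names], dtype=int)


@dataclasses.dataclass
class ConsensusResult:
    consensus: ModulePartition
    mean_nM: float
    sd_nM: float
    nM_per_run: np.ndarray
    Q_per_run: np.ndarray


# ----------------------------------------------------------------------
def _mmat(m: InteractionMatrix) -> np.ndarray:
    W = np.asarray(m.W, dtype=float)
    F = W.sum()
    if F <= 0:
        raise ValueError("modularity undefined for an all-zero matrix")
    r = W.sum(axis=1)
    s = W.sum(axis=0)
    return W / F - np.outer(r, s) / F**2


def modularity_Q(m: InteractionMatrix, assignment: Mapping) -> float:
    """Barber weighted bipartite modularity of a given partition."""
    if not assignment:
        raise ValueError("empty assignment")
    names = list(m.plants) + list(m.pollinators)
    missing = [n for n in names if n not in assignment]
    if missing:
        raise ValueError(f"assignment misses species: {missing[:5]}")
    g = np.asarray([assignment[p] for p in m.plants])
    h = np.asarray([assignment[a] for a in m.pollinators])
    M = _mmat(m)
    return float((M * (g[:, None] == h[None, :])).sum())


def _q_of_state(M, g, h) -> float:
    return float((M * (g[:, None] == h[None, :])).sum())


def _canonical_labels(g: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Relabel modules 0..nM-1 in order of first appearance (plants first)."""
    remap: dict = {}
    for v in list(g) + list(h):
        if v not in remap:
            remap[v] = len(remap)
    g2 = np.asarray([remap[v] for v in g])
    h2 = np.asarray([remap[v] for v in h])
    return g2, h2, len(remap)


def _move_sweeps(M: np.ndarray, g: np.ndarray, h: np.ndarray, max_sweeps: int = 100):
    """Greedy best-move sweeps until no single reassignment improves Q."""
    P, A = M.shape
    K = P + A
    for _ in range(max_sweeps):
        improved = False
        H = np.zeros((A, K))
        H[np.arange(A), h] = 1.0
        scores = M @ H                      # (P, K): gain of plant i in module k
        for i in range(P):
            best = int(np.argmax(scores[i]))
            if scores[i, best] > scores[i, g[i]] + 1e-15:
                g[i] = best
                improved = True
        G = np.zeros((P, K))
        G[np.arange(P), g] = 1.0
        scores = M.T @ G                    # (A, K)
        for j in range(A):
            best = int(np.argmax(scores[j]))
            if scores[j, best] > scores[j, h[j]] + 1e-15:
                h[j] = best
                improved = True
        if not improved:
            break
    return g, h


def _polish(M: np.ndarray, g: np.ndarray, h: np.ndarray):
    """Local optimum under single moves, pairwise module merges, and
    extraction of a (plant, pollinator) pair into a fresh module."""
    P, A = M.shape
    K = P + A
    while True:
        g, h = _move_sweeps(M, g, h)
        used = np.unique(np.concatenate([g, h]))
        best_gain, best_action = 1e-15, None

        for ai in range(len(used)):
            ga, ha = g == used[ai], h == used[ai]
            for bi in range(ai + 1, len(used)):
                gb, hb = g == used[bi], h == used[bi]
                gain = float(M[ga][:, hb].sum() + M[gb][:, ha].sum())
                if gain > best_gain:
                    best_gain, best_action = gain, ("merge", used[ai], used[bi])

        # pair extraction: dQ = M[i, j] - (i's other in-module links)
        #                            - (j's other in-module links)
        same = g[:, None] == h[None, :]
        in_mod_i = np.where(same, M, 0.0).sum(axis=1)   # plant i's in-module total
        in_mod_j = np.where(same, M, 0.0).sum(axis=0)
        gain_ij = np.where(same, 2 * M - in_mod_i[:, None] - in_mod_j[None, :], -np.inf)
        i, j = np.unravel_index(np.argmax(gain_ij), gain_ij.shape)
        if gain_ij[i, j] > best_gain:
            best_gain, best_action = gain_ij[i, j], ("extract", i, j)

        if best_action is None:
            return g, h
        if best_action[0] == "merge":
            _, a, b = best_action
            g[g == b] = a
            h[h == b] = a
        else:
            _, i, j = best_action
            fresh = next(k for k in range(K) if k not in set(g) | set(h))
            g[i] = fresh
            h[j] = fresh


def quanbimo_anneal(
    m: InteractionMatrix,
    seed: int | None = None,
    steps: int = 10_000,
    t0: float = 1.0,
    cooling: float = 0.995,
    n_restarts: int = 1,
) -> ModulePartition:
    """Simulated-annealing search for the maximum-modularity partition.

    Every species starts in its own module; each step proposes either a
    single-species reassignment (to any module slot, occupied or empty —
    which doubles as a split move) or, with small probability, the merge of
    two occupied modules.  Worse moves are accepted with Boltzmann
    probability under a geometric temperature schedule (``t0 * cooling**step``).
    A greedy polish then moves species until no single reassignment
    improves Q, so the result is a local optimum.  Deterministic given
    ``seed``; with ``n_restarts > 1`` the best of several independent
    restarts is returned.
    """
    if m.I < 1:
        raise ValueError("modularity search needs at least one link")
    rng = np.random.default_rng(seed)
    M = _mmat(m)
    P, A = M.shape
    K = P + A

    best = None
    for _ in range(max(1, n_restarts)):
        g = np.arange(P)
        h = P + np.arange(A)
        Q = _q_of_state(M, g, h)
        # temperature is scaled to the typical move size (~1/K of total Q range)
        temp = t0 / K
        for step in range(steps):
            if K > 2 and rng.random() < 0.05:
                # merge two occupied modules
                used = np.unique(np.concatenate([g, h]))
                if len(used) >= 2:
                    a, b = rng.choice(used, size=2, replace=False)
                    ga, gb = g == a, g == b
                    ha, hb = h == a, h == b
                    dQ = float(M[ga][:, hb].sum() + M[gb][:, ha].sum())
                    if dQ > 0 or rng.random() < np.exp(dQ / max(temp, 1e-300)):
                        g[gb] = a
                        h[hb] = a
                        Q += dQ
            else:
                node = int(rng.integers(K))
                target = int(rng.integers(K))
                if node < P:
                    cur = g[node]
                    if target != cur:
                        dQ = float(M[node] @ ((h == target).astype(float) - (h == cur)))
                        if dQ > 0 or rng.random() < np.exp(dQ / max(temp, 1e-300)):
                            g[node] = target
                            Q += dQ
                else:
                    j = node - P
                    cur = h[j]
                    if target != cur:
                        dQ = float(((g == target).astype(float) - (g == cur)) @ M[:, j])
                        if dQ > 0 or rng.random() < np.exp(dQ / max(temp, 1e-300)):
                            h[j] = target
                            Q += dQ
            temp *= cooling
        g, h = _polish(M, g, h)
        Q = _q_of_state(M, g, h)
        if best is None or Q > best[0] + 1e-15:
            best = (Q, g.copy(), h.copy())

    Q, g, h = best
    g, h, nM = _canonical_labels(g, h)
    assignment = {p: int(v) for p, v in zip(m.plants, g)}
    assignment.update({a: int(v) for a, v in zip(m.pollinators, h)})
    return ModulePartition(assignment=assignment, Q=float(Q), nM=nM, seed=seed)


# ----------------------------------------------------------------------
def consensus_modules(
    m: InteractionMatrix,
    n_runs: int = 50,
    seed: int | None = None,
    **anneal_kwargs,
) -> ConsensusResult:
    """Run the annealer ``n_runs`` times; report module-count statistics and
    a modal consensus assignment.

    Module ids are nominal, so runs are first aligned to the highest-Q run
    by greedy maximal species overlap; each species then takes its most
    frequent aligned module (ties broken by the lowest module id).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_runs)
    runs = [quanbimo_anneal(m, seed=int(s), **anneal_kwargs) for s in seeds]
    names = list(m.plants) + list(m.pollinators)
    nM = np.asarray([r.nM for r in runs], dtype=float)
    Qs = np.asarray([r.Q for r in runs])

    ref = runs[int(np.argmax(Qs))]
    aligned = [_align_labels(r, ref, names) for r in runs]

    consensus_assignment = {}
    for n in names:
        vals, counts = np.unique([a[n] for a in aligned], return_counts=True)
        consensus_assignment[n] = int(vals[counts == counts.max()].min())
    cg = np.asarray([consensus_assignment[p] for p in m.plants])
    ch = np.asarray([consensus_assignment[a] for a in m.pollinators])
    cg, ch, c_nM = _canonical_labels(cg, ch)
    consensus_assignment = {p: int(v) for p, v in zip(m.plants, cg)}
    consensus_assignment.update({a: int(v) for a, v in zip(m.pollinators, ch)})
    cons = ModulePartition(
        assignment=consensus_assignment,
        Q=modularity_Q(m, consensus_assignment),
        nM=c_nM,
        seed=seed,
    )
    return ConsensusResult(
        consensus=cons,
        mean_nM=float(nM.mean()),
        sd_nM=float(nM.std(ddof=1)) if n_runs > 1 else 0.0,
        nM_per_run=nM,
        Q_per_run=Qs,
    )


def _align_labels(run: ModulePartition, ref: ModulePartition, names) -> dict:
    """Greedy maximal-overlap relabelling of *run*'s modules onto *ref*'s."""
    overlap: dict = {}
    for n in names:
        key = (run.assignment[n], ref.assignment[n])
        overlap[key] = overlap.get(key, 0) + 1
    mapping: dict = {}
    used_ref = set()
    for (rm, fm), _ in sorted(overlap.items(), key=lambda kv: (-kv[1], kv[0])):
        if rm not in mapping and fm not in used_ref:
            mapping[rm] = fm
            used_ref.add(fm)
    fresh = max(list(used_ref) + [ref.nM - 1], default=-1) + 1
    out = {}
    for n in names:
        rm = run.assignment[n]
        if rm not in mapping:
            mapping[rm] = fresh
            used_ref.add(fresh)
            fresh += 1
        out[n] = mapping[rm]
    return out


# ----------------------------------------------------------------------
# Species roles: participation coefficient and within-module degree
# ----------------------------------------------------------------------

def species_roles(
    m: InteractionMatrix,
    partition: ModulePartition,
    weight_mode: str = "weighted",
) -> pd.DataFrame:
    """Per-species participation coefficient c and within-module z-score.

    c_i = 1 - sum_s (k_is / k_i)^2 over modules s, where k_is is species
    i's (weighted or binary) degree toward module s of the opposite guild;
    c = 0 when all links stay inside the species' own module.  z_i
    standardises the species' own-module degree against the same-guild
    members of its module; a singleton or zero-variance module gives z = 0,
    flagged in the ``degenerate_z`` column.
    """
    if weight_mode not in ("weighted", "binary"):
        raise ValueError("weight_mode must be 'weighted' or 'binary'")
    W = np.asarray(m.W, dtype=float) if weight_mode == "weighted" else np.asarray(
        m.B, dtype=float
    )
    g = partition.modules_of(m.plants)
    h = partition.modules_of(m.pollinators)
    K = max(g.max(initial=0), h.max(initial=0)) + 1

    H = np.zeros((len(h), K))
    H[np.arange(len(h)), h] = 1.0
    G = np.zeros((len(g), K))
    G[np.arange(len(g)), g] = 1.0

    rows = []
    for names, guild, own, kis_all in (
        (m.plants, "plant", g, W @ H),        # plants' degree toward pollinator modules
        (m.pollinators, "pollinator", h, W.T @ G),
    ):
        k = kis_all.sum(axis=1)
        own_deg = kis_all[np.arange(len(names)), own]
        for idx, name in enumerate(names):
            if k[idx] > 0:
                c = 1.0 - float(((kis_all[idx] / k[idx]) ** 2).sum())
            else:
                c = 0.0
            rows.append(
                {
                    "species": name,
                    "guild": guild,
                    "module": int(own[idx]),
                    "degree": float(k[idx]),
                    "own_module_degree": float(own_deg[idx]),
                    "c": c,
                }
            )
    roles = pd.DataFrame(rows)

    # z within guild and module
    z = np.zeros(len(roles))
    degen = np.zeros(len(roles), dtype=bool)
    for (_, _), grp in roles.groupby(["guild", "module"]):
        vals = grp["own_module_degree"].to_numpy()
        if len(vals) < 2 or np.std(vals, ddof=1) == 0:
            degen[grp.index] = True
        else:
            z[grp.index] = (vals - vals.mean()) / np.std(vals, ddof=1)
    roles["z"] = z
    roles["degenerate_z"] = degen
    return roles


def role_thresholds(roles: pd.DataFrame, percentile: float = 0.95):
    """Empirical percentile thresholds on c and z, plus a role class per species.

    Classes follow the c-z plane convention of pollination-web studies:
    species strictly above both thresholds are network hubs, above only the
    c threshold connectors, above only the z threshold module hubs, and
    peripheral otherwise.
    """
    if len(roles) < 2:
        raise ValueError("need at least two species to set thresholds")
    c_star = float(np.quantile(roles["c"], percentile))
    z_star = float(np.quantile(roles["z"], percentile))
    out = roles.copy()

    def classify(row):
        hi_c = row["c"] > c_star
        hi_z = row["z"] > z_star
        if hi_c and hi_z:
            return "network_hub"
        if hi_c:
            return "connector"
        if hi_z:
            return "module_hub"
        return "peripheral"

    out["role_class"] = out.apply(classify, axis=1)
    return c_star, z_star, out


def role_trend_test(roles_pre: pd.DataFrame, roles_apis: pd.DataFrame) -> dict:
    """Binomial sign tests on per-species changes of c and z between periods.

    Species present in both periods are paired by name; zero differences
    are dropped.  Two-sided exact binomial p-values; an all-tie variable is
    flagged with ``p = nan``.
    """
    merged = roles_pre.merge(roles_apis, on="species", suffixes=("_pre", "_apis"))
    if merged.empty:
        raise ValueError("no species shared between the two periods")
    out: dict = {"n_shared": int(len(merged))}
    for var in ("c", "z"):
        d = merged[f"{var}_apis"] - merged[f"{var}_pre"]
        down = int((d < 0).sum())
        up = int((d > 0).sum())
        out[f"n_down_{var}"] = down
        out[f"n_up_{var}"] = up
        if down + up == 0:
            out[f"p_{var}"] = float("nan")
            out[f"all_ties_{var}"] = True
        else:
            out[f"p_{var}"] = float(
                binomtest(down, down + up, 0.5, alternative="two-sided").pvalue
            )
            out[f"all_ties_{var}"] = False
    return out
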