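import itertools

import numpy as np
import pandas as pd
import pytest

from pollinet.modularity import (
    consensus_modules,
    modularity_Q,
    quanbimo_anneal,
    role_thresholds,
    role_trend_test,
    species_roles,
)
from pollinet.network_build import InteractionMatrix


def as_matrix(W):
    W = np.asarray(W, dtype=float)
    return InteractionMatrix(
        W=W,
        B=(W > 0).astype(np.int8),
        plants=[f"p{i}" for i in range(W.shape[0])],
        pollinators=[f"a{j}" for j in range(W.shape[1])],
    )


def two_block():
    W = np.zeros((4, 4))
    W[:2, :2] = 1.0
    W[2:, 2:] = 1.0
    return as_matrix(W)


def planted_partition():
    return {"p0": 0, "p1": 0, "a0": 0, "a1": 0, "p2": 1, "p3": 1, "a2": 1, "a3": 1}


# ----------------------------------------------------------------------
# Independent oracle: exhaustive search over all set partitions
# ----------------------------------------------------------------------

def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def exhaustive_best_Q(m):
    names = list(m.plants) + list(m.pollinators)
    best = -np.inf
    for part in set_partitions(names):
        assignment = {n: k for k, block in enumerate(part) for n in block}
        best = max(best, modularity_Q(m, assignment))
    return best


# ----------------------------------------------------------------------
class TestModularityQ:
    def test_planted_two_block_is_half(self):
        assert modularity_Q(two_block(), planted_partition()) == pytest.approx(0.5)

    def test_single_module_is_zero(self):
        rng = np.random.default_rng(0)
        m = as_matrix(rng.poisson(1.0, size=(3, 4)) + 0.1)
        one = {n: 0 for n in m.plants + m.pollinators}
        assert modularity_Q(m, one) == pytest.approx(0.0, abs=1e-12)

    def test_planted_partition_is_exhaustive_optimum(self):
        m = two_block()
        assert exhaustive_best_Q(m) == pytest.approx(0.5, abs=1e-12)

    def test_incomplete_assignment_rejected(self):
        with pytest.raises(ValueError, match="misses"):
            modularity_Q(two_block(), {"p0": 0})


class TestAnneal:
    def test_recovers_planted_blocks(self):
        m = two_block()
        hits = sum(
            abs(quanbimo_anneal(m, seed=s, steps=2000).Q - 0.5) < 1e-12
            for s in range(40)
        )
        assert hits >= 38  # >= 95% of seeded runs

    def test_uniform_matrix_has_no_modular_signal(self):
        m = as_matrix(np.ones((4, 4)))
        qs = [quanbimo_anneal(m, seed=s, steps=2000).Q for s in range(10)]
        assert max(qs) <= 0.05

    def test_seed_determinism(self):
        m = two_block()
        a = quanbimo_anneal(m, seed=7, steps=1500)
        b = quanbimo_anneal(m, seed=7, steps=1500)
        assert a.assignment == b.assignment and a.Q == b.Q

    def test_never_below_single_module_baseline(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            m = as_matrix(rng.poisson(0.8, size=(3, 3)) + (rng.random((3, 3)) < 0.2))
            if m.I == 0:
                continue
            assert quanbimo_anneal(m, seed=1, steps=1000).Q >= -1e-12

    def test_reported_Q_matches_reported_assignment(self):
        rng = np.random.default_rng(9)
        m = as_matrix(rng.poisson(1.0, size=(4, 5)) + 0.05)
        part = quanbimo_anneal(m, seed=2, steps=1500)
        assert part.Q == pytest.approx(modularity_Q(m, part.assignment), abs=1e-12)


class TestConsensus:
    def test_two_block_mean_module_count(self):
        res = consensus_modules(two_block(), n_runs=10, seed=0, steps=2000)
        assert res.mean_nM == 2.0
        assert res.sd_nM == 0.0
        assert res.consensus.Q == pytest.approx(0.5)

    def test_single_run_consensus_equals_that_run(self):
        m = two_block()
        res = consensus_modules(m, n_runs=1, seed=5, steps=2000)
        assert res.consensus.Q == pytest.approx(res.Q_per_run[0])
        assert res.sd_nM == 0.0

    def test_alignment_invariant_to_module_id_permutation(self):
        """Module ids are nominal: consensus classes must not change if a
        run's labels are arbitrarily permuted."""
        from pollinet.modularity import ModulePartition, _align_labels

        m = two_block()
        ref = quanbimo_anneal(m, seed=0, steps=2000)
        run = quanbimo_anneal(m, seed=1, steps=2000)
        names = m.plants + m.pollinators
        permuted = ModulePartition(
            assignment={n: 99 - v for n, v in run.assignment.items()},
            Q=run.Q,
            nM=run.nM,
        )
        a1 = _align_labels(run, ref, names)
        a2 = _align_labels(permuted, ref, names)
        assert a1 == a2


class TestSpeciesRoles:
    def test_all_links_internal_gives_zero_participation(self):
        m = two_block()
        roles = species_roles(m, quanbimo_anneal(m, seed=0, steps=2000))
        assert (roles["c"] == 0).all()

    def test_even_split_participation(self):
        # one pollinator linked equally to plants in two / three modules
        W = np.ones((3, 1))
        m = as_matrix(W)
        part2 = {"p0": 0, "p1": 0, "p2": 1, "a0": 0}
        roles = species_roles(
            m,
            type("P", (), {"modules_of": lambda self, names: np.array(
                [part2[n] for n in names])})(),
        )
        c_a0 = roles.loc[roles.species == "a0", "c"].iloc[0]
        # links: 2 in module 0, 1 in module 1 -> c = 1 - (4/9 + 1/9)
        assert c_a0 == pytest.approx(1 - 5 / 9)

    def test_hand_oracle_three_modules(self):
        """Hand-built network: pollinator a0 splits its (weighted) links
        1:1:2 across three modules; c and z match direct computation."""
        W = np.array(
            [[1.0], [1.0], [2.0]]
        )
        m = as_matrix(W)
        assignment = {"p0": 0, "p1": 1, "p2": 2, "a0": 0}

        class P:
            def modules_of(self, names):
                return np.array([assignment[n] for n in names])

        roles = species_roles(m, P(), weight_mode="weighted")
        c_a0 = roles.loc[roles.species == "a0", "c"].iloc[0]
        assert c_a0 == pytest.approx(1 - (0.25**2 + 0.25**2 + 0.5**2))

    def test_degree_conservation(self):
        rng = np.random.default_rng(4)
        m = as_matrix(rng.poisson(1.0, size=(4, 6)) + 0.01)
        part = quanbimo_anneal(m, seed=3, steps=1500)
        roles = species_roles(m, part, weight_mode="weighted")
        for _, row in roles[roles.guild == "plant"].iterrows():
            i = m.plants.index(row.species)
            assert row.degree == pytest.approx(m.W[i].sum())


class TestRoleThresholds:
    def test_all_equal_c_none_strictly_above(self):
        roles = pd.DataFrame({"species": list("abcd"), "c": [0.3] * 4,
                              "z": [0.0, 1.0, 2.0, 3.0]})
        c_star, _, out = role_thresholds(roles)
        assert c_star == 0.3
        assert not (out["c"] > c_star).any()

    def test_threshold_is_empirical_quantile(self):
        c = np.linspace(0.05, 1.0, 20)
        roles = pd.DataFrame({"species": [f"s{i}" for i in range(20)],
                              "c": c, "z": np.zeros(20)})
        c_star, _, _ = role_thresholds(roles, percentile=0.95)
        assert c_star == pytest.approx(np.quantile(c, 0.95))

    def test_raising_c_never_demotes_connector(self):
        roles = pd.DataFrame({"species": [f"s{i}" for i in range(10)],
                              "c": np.linspace(0, 0.9, 10), "z": np.zeros(10)})
        _, _, out = role_thresholds(roles)
        assert out.loc[out["c"].idxmax(), "role_class"] in ("connector", "network_hub")
        roles.loc[roles["c"].idxmax(), "c"] = 0.95
        _, _, out2 = role_thresholds(roles)
        assert out2.loc[out2["c"].idxmax(), "role_class"] in ("connector", "network_hub")


class TestRoleTrendTest:
    @staticmethod
    def roles_frame(c_vals, z_vals=None):
        n = len(c_vals)
        return pd.DataFrame(
            {"species": [f"s{i}" for i in range(n)], "c": c_vals,
             "z": z_vals if z_vals is not None else np.zeros(n)}
        )

    def test_all_decreases_exact_binomial(self):
        pre = self.roles_frame(np.ones(10))
        post = self.roles_frame(np.zeros(10))
        res = role_trend_test(pre, post)
        assert res["p_c"] == pytest.approx(2 * 0.5**10)

    def test_balanced_changes_give_p_one(self):
        pre = self.roles_frame(np.zeros(10))
        post = self.roles_frame(np.r_[np.ones(5), -np.ones(5)])
        assert role_trend_test(pre, post)["p_c"] == pytest.approx(1.0)

    def test_all_ties_flagged(self):
        pre = self.roles_frame(np.ones(5))
        res = role_trend_test(pre, pre.copy())
        assert res["all_ties_c"] and np.isnan(res["p_c"])

    def test_no_shared_species_errors(self):
        pre = self.roles_frame(np.ones(3))
        post = self.roles_frame(np.ones(3))
        post["species"] = ["x1", "x2", "x3"]
        with pytest.raises(ValueError, match="shared"):
            role_trend_test(pre, post)
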