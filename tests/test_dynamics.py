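"""Point-environment stage-1 dynamics: consumption, growth laws, reproduction."""

import copy
import math

import numpy as np
import pytest

from evogrid.dynamics import (
    MutationSettings,
    PointEnvironment,
    ReproductionParams,
    allocate_consumption,
    cohort_fitness,
    growth_coefficient_c,
    growth_coefficient_nc,
    interaction_multiplier,
    node_step,
    reproduce,
    synthesize_and_secrete,
)
from evogrid.genome import GeneSlot, Population, TrophicStructure

from conftest import one_node_habitat, simple_population, simple_structure


def _env(substrates, pops):
    env = PointEnvironment(index=0, substrates=dict(substrates))
    for pop in pops:
        env.add_population(pop)
    return env


class TestAllocateConsumption:
    def test_unconstrained_demand_is_granted(self):
        # 10 cells * k_max 1 * c 1 = demand 10 against a pool of 100
        pop = simple_population(cohorts={0: {(): 10.0}})
        env = _env({"N": 100.0}, [pop])
        alloc = allocate_consumption(env)
        assert alloc["sp"][()]["N"] == pytest.approx(10.0)
        assert env.substrates["N"] == pytest.approx(90.0)

    def test_scarce_pool_split_demand_proportionally(self):
        a = simple_population("a", cohorts={0: {(): 100.0}})
        b = simple_population("b", cohorts={0: {(): 100.0}})
        env = _env({"N": 100.0}, [a, b])
        alloc = allocate_consumption(env)
        assert alloc["a"][()]["N"] == pytest.approx(50.0)
        assert alloc["b"][()]["N"] == pytest.approx(50.0)
        assert env.substrates["N"] == pytest.approx(0.0)

    def test_empty_pool_grants_nothing(self):
        pop = simple_population(cohorts={0: {(): 10.0}})
        env = _env({"N": 0.0}, [pop])
        alloc = allocate_consumption(env)
        assert alloc["sp"][()]["N"] == 0.0

    def test_pool_decrement_equals_total_allocation(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pool = float(rng.uniform(0, 300))
            counts = rng.uniform(1, 200, size=3)
            pops = [
                simple_population(f"s{i}", cohorts={0: {(): float(c)}})
                for i, c in enumerate(counts)
            ]
            env = _env({"N": pool}, pops)
            alloc = allocate_consumption(env)
            granted = sum(alloc[f"s{i}"][()]["N"] for i in range(3))
            assert pool - env.substrates["N"] == pytest.approx(granted, rel=1e-9)
            assert env.substrates["N"] >= 0.0


class TestGrowthLaws:
    def test_liebig_zero_limiting_factor(self):
        assert growth_coefficient_nc({"A": 10.0, "B": 0.0}, {"A": 1.0, "B": 1.0}) == 0.0

    def test_liebig_minimum(self):
        k = growth_coefficient_nc({"A": 10.0, "B": 5.0}, {"A": 2.0, "B": 1.0}, k_max=10.0)
        assert k == pytest.approx(5.0)

    def test_liebig_single_substrate_caps_at_k_max(self):
        assert growth_coefficient_nc({"A": 50.0}, {"A": 1.0}, k_max=3.0) == 3.0

    def test_rubel_compensation(self):
        # one absent substrate is offset by the abundant one; Liebig gives 0
        alloc, c = {"A": 10.0, "B": 0.0}, {"A": 1.0, "B": 1.0}
        assert growth_coefficient_c(alloc, c) == pytest.approx(5.0)
        assert growth_coefficient_nc(alloc, c) == 0.0

    def test_replacement_point_equals_one_under_both_laws(self):
        alloc = {"A": 2.0, "B": 0.5}
        c = {"A": 2.0, "B": 0.5}
        assert growth_coefficient_nc(alloc, c) == pytest.approx(1.0)
        assert growth_coefficient_c(alloc, c) == pytest.approx(1.0)

    def test_concentrated_weight_reduces_to_liebig_single(self):
        alloc = {"A": 4.0, "B": 100.0}
        c = {"A": 2.0, "B": 1.0}
        k = growth_coefficient_c(alloc, c, w={"A": 1.0, "B": 0.0})
        assert k == pytest.approx(growth_coefficient_nc({"A": 4.0}, {"A": 2.0}))

    def test_compensation_never_hurts_with_uniform_weights(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            subs = [f"S{i}" for i in range(rng.integers(1, 5))]
            alloc = {s: float(rng.uniform(0, 10)) for s in subs}
            c = {s: float(rng.uniform(0.1, 5)) for s in subs}
            k_max = float(rng.uniform(0.5, 10))
            assert (
                growth_coefficient_c(alloc, c, k_max=k_max)
                >= growth_coefficient_nc(alloc, c, k_max=k_max) - 1e-12
            )


class TestInteractionMultiplier:
    def test_no_links_gives_identity(self):
        assert interaction_multiplier({}, {}, 0.0, 0.0) == 1.0

    def test_inhibitor_halves_growth(self):
        assert interaction_multiplier({"S2": 1.0}, {}, 1.0, 0.0) == pytest.approx(0.5)

    def test_monotone_in_sensitivity_and_activation(self):
        grid = np.linspace(0.0, 5.0, 11)
        inh = [interaction_multiplier({"x": 2.0}, {}, s, 0.0) for s in grid]
        act = [interaction_multiplier({}, {"y": 2.0}, 0.0, a) for a in grid]
        assert all(b < a for a, b in zip(inh, inh[1:]))
        assert all(b > a for a, b in zip(act, act[1:]))


class TestReproduce:
    def test_zero_growth_keeps_count(self):
        assert reproduce(100.0, 0.0) == 100.0

    def test_deterministic_growth(self):
        assert reproduce(100.0, 0.1, 1.0) == pytest.approx(110.0)

    def test_death_rate_shrinks_cohort(self):
        assert reproduce(100.0, 0.0, death_rate=0.25) == pytest.approx(75.0)

    def test_stochastic_expectation_matches_deterministic(self):
        rng = np.random.default_rng(9)
        reps = 10_000
        vals = [reproduce(100.0, 0.1, 1.0, stochastic=True, rng=rng) for _ in range(reps)]
        # offspring are Poisson(10): SE of the mean = sqrt(10/reps)
        se = math.sqrt(10.0 / reps)
        assert abs(np.mean(vals) - 110.0) < 3 * se


class TestSynthesis:
    def test_secreted_product_scales_with_count(self):
        struct = simple_structure(produced={"S1": True})
        sec, internal = synthesize_and_secrete(1000.0, struct, {"S1": 0.01})
        assert sec == {"S1": pytest.approx(10.0)}
        assert internal == {}

    def test_zero_yield_produces_nothing(self):
        struct = simple_structure(produced={"S1": True})
        assert synthesize_and_secrete(1000.0, struct, {"S1": 0.0}) == ({}, {})

    def test_non_secreted_product_stays_internal(self):
        struct = simple_structure(produced={"S1": False})
        sec, internal = synthesize_and_secrete(100.0, struct, {"S1": 0.5})
        assert sec == {}
        assert internal == {"S1": pytest.approx(50.0)}


class TestCohortFitness:
    @pytest.mark.parametrize(
        "before,after,expected", [(100, 110, 0.10), (100, 100, 0.0), (50, 40, -0.2)]
    )
    def test_relative_change(self, before, after, expected):
        assert cohort_fitness(before, after) == pytest.approx(expected)

    def test_empty_cohort_is_undefined(self):
        assert math.isnan(cohort_fitness(0.0, 5.0))


class TestNodeStep:
    def test_empty_node_unchanged(self):
        env = PointEnvironment(index=0, substrates={"N": 5.0})
        node_step(env, rng=0)
        assert env.substrates == {"N": 5.0}

    def test_abundant_substrate_growth_at_k_max(self):
        params = ReproductionParams(c={"N": 1.0}, k_max=0.5)
        pop = simple_population(params=params, cohorts={0: {(): 100.0}})
        env = _env({"N": 1e6}, [pop])
        fitness = node_step(env, rng=0)
        assert fitness["sp"][()] == pytest.approx(0.5)
        assert pop.node_count(0) == pytest.approx(150.0)

    def test_substrates_never_negative(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            pop = simple_population(cohorts={0: {(): float(rng.uniform(0, 1000))}})
            env = _env({"N": float(rng.uniform(0, 50))}, [pop])
            node_step(env, rng=0)
            assert all(v >= 0 for v in env.substrates.values())

    def test_secretion_flag_off_leaves_environment_pools_unchanged(self):
        struct = simple_structure(produced={"W": False})
        params = ReproductionParams(c={"N": 1.0}, yields={"W": 1.0})
        pop = Population(structure=struct, params=params, cohorts_by_node={0: {(): 10.0}})
        env = _env({"N": 1e4, "W": 0.0}, [pop])
        node_step(env, rng=0)
        assert env.substrates["W"] == 0.0
        assert env.internal["sp"]["W"] > 0.0

    def test_stage1_is_node_order_independent(self):
        """Processing nodes in any order yields a bit-identical habitat."""
        from evogrid.spatial import Habitat

        def build():
            h = Habitat(dims=(2,), mutation=MutationSettings(rate=0.1, sites_model="infinite"))
            slot = GeneSlot(id="g", role="sensitivity", bounds=(0.0, 1.0))
            pop = simple_population(
                slots=(slot,),
                cohorts={0: {(0.3,): 100.0}, 1: {(0.6,): 50.0}},
            )
            for env in h.nodes:
                env.substrates["N"] = 40.0
            h.register(pop)
            return h

        results = []
        for order in ((0, 1), (1, 0)):
            h = build()
            for i in order:
                rng = np.random.default_rng([1, 0, i])
                node_step(h.nodes[i], rng=rng, mutation=h.mutation)
            results.append(
                (
                    [dict(env.substrates) for env in h.nodes],
                    {
                        (s, i): dict(p.cohorts_by_node[i])
                        for s, p in h.populations.items()
                        for i in (0, 1)
                    },
                )
            )
        assert results[0] == results[1]
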