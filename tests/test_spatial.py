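"""Spatial redistribution operators and the two-stage simulation loop."""

import copy

import numpy as np
import pandas as pd
import pytest

from evogrid.dynamics import ReproductionParams
from evogrid.genome import GeneSlot, Population, TrophicStructure
from evogrid.spatial import (
    EventSchedule,
    Habitat,
    SetInflowEvent,
    attractiveness,
    chemotaxis_step,
    diffusion_step,
    flow_step_perpendicular,
    flow_step_through,
    run,
    simulation_step,
)

from conftest import one_node_habitat, simple_population


def _tube(n, substrates=None, flow_mode="through", **kw):
    h = Habitat(dims=(n,), flow_mode=flow_mode, **kw)
    for i, env in enumerate(h.nodes):
        for sub, values in (substrates or {}).items():
            env.substrates[sub] = values[i]
    return h


class TestFlowThrough:
    def test_zero_rate_is_noop(self):
        h = _tube(3, {"T": [1.0, 2.0, 3.0]}, flow_rate=0.0)
        flow_step_through(h)
        assert [e.substrates["T"] for e in h.nodes] == [1.0, 2.0, 3.0]

    def test_two_percent_advects_downstream(self):
        h = _tube(2, {"T": [100.0, 0.0]}, flow_rate=0.02)
        flow_step_through(h)
        assert h.nodes[0].substrates["T"] == pytest.approx(98.0)
        assert h.nodes[1].substrates["T"] == pytest.approx(2.0)

    def test_hand_propagated_tracer(self):
        """8 units in the first of three nodes, r = 1/2: two steps give (2,4,2)."""
        h = _tube(3, {"T": [8.0, 0.0, 0.0]}, flow_rate=0.5)
        flow_step_through(h)
        flow_step_through(h)
        assert [e.substrates["T"] for e in h.nodes] == pytest.approx(
            [2.0, 4.0, 2.0], abs=1e-9
        )

    def test_mass_balance_with_inflow_and_outflow(self):
        h = _tube(4, {"T": [10.0, 5.0, 0.0, 20.0]}, flow_rate=0.1, inflow={"T": 7.0})
        before = h.total_substrate("T")
        flow_step_through(h)
        outflow = 0.1 * 20.0
        inflow = 0.1 * 7.0
        assert h.total_substrate("T") == pytest.approx(before - outflow + inflow, rel=1e-12)

    def test_cells_advect_like_substrates(self):
        pop = simple_population(cohorts={0: {(): 100.0}, 1: {}})
        h = _tube(2, flow_rate=0.02)
        h.register(pop)
        flow_step_through(h)
        assert pop.node_count(0) == pytest.approx(98.0)
        assert pop.node_count(1) == pytest.approx(2.0)

    def test_uniform_inflow_level_is_fixed_point(self):
        h = _tube(5, {"N": [7.0] * 5}, flow_rate=0.3, inflow={"N": 7.0})
        flow_step_through(h)
        assert [e.substrates["N"] for e in h.nodes] == pytest.approx([7.0] * 5, abs=1e-12)

    def test_converges_to_inflow_level(self):
        h = _tube(4, {"N": [0.0] * 4}, flow_rate=0.5, inflow={"N": 3.0})
        for _ in range(120):
            flow_step_through(h)
        assert [e.substrates["N"] for e in h.nodes] == pytest.approx([3.0] * 4, abs=1e-9)


class TestFlowPerpendicular:
    def test_passive_substrate_fixed_point_is_inflow(self):
        h = _tube(3, {"N": [0.0, 50.0, 400.0]}, flow_mode="perpendicular",
                  flow_rate=0.25, inflow={"N": 12.0})
        for _ in range(120):
            flow_step_perpendicular(h)
        assert [e.substrates["N"] for e in h.nodes] == pytest.approx([12.0] * 3, abs=1e-9)

    def test_cells_decay_geometrically(self):
        pop = simple_population(cohorts={0: {(): 1000.0}})
        h = _tube(1, flow_mode="perpendicular", flow_rate=0.1)
        h.register(pop)
        for t in range(1, 21):
            flow_step_perpendicular(h)
            assert pop.node_count(0) == pytest.approx(1000.0 * 0.9**t, rel=1e-9)


class TestDiffusion:
    def test_uniform_field_is_fixed_point(self):
        h = _tube(4, {"S": [5.0] * 4}, diffusion_rate=0.2)
        diffusion_step(h)
        assert [e.substrates["S"] for e in h.nodes] == pytest.approx([5.0] * 4)

    def test_two_node_stencil(self):
        h = _tube(2, {"S": [10.0, 0.0]}, diffusion_rate=0.1)
        diffusion_step(h)
        assert h.nodes[0].substrates["S"] == pytest.approx(9.0)
        assert h.nodes[1].substrates["S"] == pytest.approx(1.0)

    def test_closed_system_conserves_mass_exactly(self):
        rng = np.random.default_rng(0)
        h = _tube(6, {"S": list(rng.uniform(0, 10, 6))}, diffusion_rate=0.3)
        before = h.total_substrate("S")
        for _ in range(50):
            diffusion_step(h)
        assert h.total_substrate("S") == pytest.approx(before, rel=1e-12)

    def test_variance_is_non_increasing(self):
        rng = np.random.default_rng(1)
        h = _tube(8, {"S": list(rng.uniform(0, 100, 8))}, diffusion_rate=0.4)
        last = np.var([e.substrates["S"] for e in h.nodes])
        for _ in range(30):
            diffusion_step(h)
            var = np.var([e.substrates["S"] for e in h.nodes])
            assert var <= last + 1e-12
            last = var

    def test_cells_do_not_diffuse_by_default(self):
        pop = simple_population(cohorts={0: {(): 100.0}, 1: {}})
        h = _tube(2, diffusion_rate=0.2)
        h.register(pop)
        diffusion_step(h)
        assert pop.node_count(0) == 100.0


class TestAttractiveness:
    def test_empty_environment_scores_zero(self):
        struct = simple_population().structure
        assert attractiveness({}, struct) == 0.0

    def test_richer_node_scores_higher(self):
        struct = simple_population().structure
        assert attractiveness({"N": 10.0}, struct) > attractiveness({"N": 0.0}, struct)

    def test_sensitivity_weighted_toxin_penalty(self):
        struct = TrophicStructure(
            species_id="prey", consumed=frozenset({"N"}), inhibitors=frozenset({"S2"})
        )
        clean = attractiveness({"N": 4.0, "S2": 0.0}, struct, sensitivity=1.0)
        toxic = attractiveness({"N": 4.0, "S2": 5.0}, struct, sensitivity=1.0)
        assert clean - toxic == pytest.approx(5.0)


class TestChemotaxis:
    def _habitat(self, food, c=0.1, cells=1000.0):
        pop = simple_population(cohorts={0: {(): cells}, 1: {}})
        h = _tube(2, {"N": food}, chemotaxis_rate=c)
        h.register(pop)
        return h, pop

    def test_no_movement_when_rate_zero_or_uniform(self):
        for food, c in (([0.0, 10.0], 0.0), ([5.0, 5.0], 0.1)):
            h, pop = self._habitat(food, c=c)
            chemotaxis_step(h)
            assert pop.node_count(0) == 1000.0

    def test_fraction_moves_up_gradient(self):
        h, pop = self._habitat([0.0, 10.0], c=0.1)
        chemotaxis_step(h)
        assert pop.node_count(0) == pytest.approx(900.0)
        assert pop.node_count(1) == pytest.approx(100.0)

    def test_net_movement_down_inhibitor_gradient(self):
        slot = GeneSlot(id="s", role="sensitivity", bounds=(0.0, 5.0), target_substrate="S2")
        struct = TrophicStructure(
            species_id="prey",
            consumed=frozenset({"N"}),
            inhibitors=frozenset({"S2"}),
            gene_slots=(slot,),
        )
        pop = Population(
            structure=struct,
            params=ReproductionParams(c={"N": 1.0}),
            cohorts_by_node={i: {(1.0,): 100.0} for i in range(4)},
        )
        h = _tube(4, {"S2": [9.0, 6.0, 3.0, 0.0]}, chemotaxis_rate=0.2)
        h.register(pop)
        before = [pop.node_count(i) for i in range(4)]
        chemotaxis_step(h)
        after = [pop.node_count(i) for i in range(4)]
        assert sum(after) == pytest.approx(sum(before))
        # center of mass shifts toward the toxin-free end
        com = lambda v: sum(i * x for i, x in enumerate(v)) / sum(v)
        assert com(after) > com(before)


def test_stage2_conserves_closed_system():
    """Flow off: diffusion + chemotaxis conserve substrate and cell totals."""
    from conftest import random_habitat

    rng = np.random.default_rng(123)
    for _ in range(30):
        h = random_habitat(rng)
        subs = h.substrate_ids()
        sub_tot = {s: h.total_substrate(s) for s in subs}
        cell_tot = h.total_cells()
        for _ in range(3):
            flow_step_perpendicular(h)  # r == 0: no-op
            diffusion_step(h)
            chemotaxis_step(h)
        for s in subs:
            assert h.total_substrate(s) == pytest.approx(sub_tot[s], rel=1e-9, abs=1e-9)
        assert h.total_cells() == pytest.approx(cell_tot, rel=1e-9)


class TestSimulationLoop:
    def _scenario(self, **kw):
        from evogrid import scenarios

        spec = scenarios.poisoner_prey(n_nodes=4, generations=30, **kw)
        return scenarios.build_habitat(spec)

    def test_zero_coupling_equals_independent_node_steps(self):
        from evogrid.dynamics import node_step

        h1, _ = self._scenario(flow_rate=0.0)
        h2, _ = self._scenario(flow_rate=0.0)
        simulation_step(h1, seed=5)
        for env in h2.nodes:
            node_step(env, rng=np.random.default_rng([5, 0, env.index]))
        for e1, e2 in zip(h1.nodes, h2.nodes):
            assert e1.substrates == e2.substrates
        for sid in h1.populations:
            assert (
                h1.populations[sid].cohorts_by_node
                == h2.populations[sid].cohorts_by_node
            )

    def test_starvation_and_recovery_events(self):
        h, _ = self._scenario()
        schedule = EventSchedule(
            [
                SetInflowEvent(generation=2, factor=0.01),
                SetInflowEvent(generation=4, composition=dict(h.base_inflow)),
            ]
        )
        base = dict(h.inflow)
        simulation_step(h, schedule, seed=0)
        simulation_step(h, schedule, seed=0)
        simulation_step(h, schedule, seed=0)  # fires at generation 2
        assert h.inflow == {k: pytest.approx(v * 0.01) for k, v in base.items()}
        simulation_step(h, schedule, seed=0)
        simulation_step(h, schedule, seed=0)  # fires at generation 4
        assert h.inflow == base

    def test_run_zero_generations_records_initial_state_only(self):
        h, sched = self._scenario()
        traj = run(h, 0, sched, seed=0)
        assert traj.generations == [0]

    def test_same_seed_gives_bit_identical_trajectory(self):
        results = []
        for _ in range(2):
            h, sched = self._scenario(stochastic=True)
            results.append(run(h, 25, sched, seed=17))
        pd.testing.assert_frame_equal(results[0].counts, results[1].counts)
        pd.testing.assert_frame_equal(results[0].substrates, results[1].substrates)
        pd.testing.assert_frame_equal(results[0].alleles, results[1].alleles)

    def test_uniform_state_stays_uniform_without_gradients(self):
        """Perpendicular flow, chemotaxis on, uniform start: node symmetry holds."""
        h, sched = self._scenario(flow_mode="perpendicular", chemotaxis_rate=0.2)
        for _ in range(20):
            simulation_step(h, sched, seed=0)
        ref = h.species_counts(0)
        for f in range(1, h.n_nodes):
            assert h.species_counts(f) == pytest.approx(ref)
        for env in h.nodes:
            assert env.substrates == pytest.approx(h.nodes[0].substrates)


def test_lattice_dimensionality_consistency():
    """An n-by-1(-by-1) lattice reproduces the 1D run bit-identically."""

    def build(dims):
        h = Habitat(dims=dims, flow_mode="through", flow_rate=0.1,
                    diffusion_rate=0.1, chemotaxis_rate=0.1, inflow={"N": 30.0})
        pop = simple_population(
            cohorts={f: {(): 100.0 + 10.0 * f} for f in range(int(np.prod(dims)))}
        )
        for f, env in enumerate(h.nodes):
            env.substrates["N"] = 10.0 * f
        h.register(pop)
        return h

    states = []
    for dims in [(4,), (4, 1), (4, 1, 1)]:
        h = build(dims)
        for _ in range(10):
            simulation_step(h, seed=3)
        states.append(
            (
                [env.substrates for env in h.nodes],
                [h.species_counts(f) for f in range(4)],
            )
        )
    assert states[0] == states[1] == states[2]
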