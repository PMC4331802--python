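"""Stage-2 spatial redistribution and the two-stage simulation loop.

A habitat is a 1D/2D/3D lattice of point environments coupled by:

* flow — ``through`` mode advects a fraction ``r`` of all cells and substrates
  to the downstream neighbor along the first lattice axis (inflow enters the
  upstream face, outflow leaves the downstream face); ``perpendicular`` mode
  exchanges the same fraction of every node's content with an external flow
  independently (substrate inflow only, never cells);
* diffusion — a synchronous nearest-neighbor stencil on substrate fields
  (cells do not diffuse by default);
* chemotaxis — greedy movement of a fraction ``c`` of each cohort to the
  strictly most attractive neighboring node.

Each simulated generation fires due scheduled events, runs the stage-1 node
update at every node (order-independent), then runs the stage-2 operators in a
fixed, configurable order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import genome
from .dynamics import MutationSettings, PointEnvironment, cohort_traits, node_step
from .errors import ConfigError, ParameterError
from .genome import Combination, Population, TrophicStructure

__all__ = [
    "Habitat",
    "EventSchedule",
    "HorizontalTransferEvent",
    "SetInflowEvent",
    "CustomEvent",
    "flow_step_through",
    "flow_step_perpendicular",
    "diffusion_step",
    "attractiveness",
    "chemotaxis_step",
    "simulation_step",
    "run",
]

STAGE2_OPS = ("flow", "diffusion", "chemotaxis")


# ---------------------------------------------------------------------------
# events


@dataclass
class HorizontalTransferEvent:
    generation: int
    node: int
    donor: str
    acceptor: str
    slot: str
    n_cells: float
    new_species_id: Optional[str] = None


@dataclass
class SetInflowEvent:
    """Replace the inflow composition, or scale it by ``factor``."""

    generation: int
    composition: Optional[Dict[str, float]] = None
    factor: Optional[float] = None


@dataclass
class CustomEvent:
    generation: int
    fn: Callable[["Habitat"], None]


@dataclass
class EventSchedule:
    """Ordered list of (generation, event); generations must be non-decreasing."""

    events: List[object] = field(default_factory=list)

    def __post_init__(self):
        gens = [e.generation for e in self.events]
        if any(b < a for a, b in zip(gens, gens[1:])):
            raise ConfigError("event generations must be non-decreasing")

    def due(self, generation: int) -> List[object]:
        return [e for e in self.events if e.generation == generation]

    @property
    def generations(self) -> List[int]:
        return [e.generation for e in self.events]


# ---------------------------------------------------------------------------
# habitat


class Habitat:
    """Lattice of point environments with flow/diffusion/chemotaxis coupling."""

    def __init__(
        self,
        dims: Sequence[int],
        flow_mode: str = "through",
        flow_rate: float = 0.0,
        diffusion_rate: float = 0.0,
        chemotaxis_rate: float = 0.0,
        inflow: Optional[Dict[str, float]] = None,
        stochastic: bool = False,
        stage2_order: Sequence[str] = STAGE2_OPS,
        substeps: int = 1,
        cell_diffusion: bool = False,
        mutation: Optional[MutationSettings] = None,
    ):
        dims = tuple(int(d) for d in dims)
        if not dims or len(dims) > 3 or any(d < 1 for d in dims):
            raise ConfigError(f"dims must be 1-3 axes of size >= 1, got {dims}")
        if flow_mode not in ("through", "perpendicular"):
            raise ConfigError(f"unknown flow mode {flow_mode!r}")
        if not 0.0 <= flow_rate <= 1.0:
            raise ConfigError(f"flow rate {flow_rate} outside [0, 1]")
        if not 0.0 <= chemotaxis_rate <= 1.0:
            raise ConfigError(f"chemotaxis rate {chemotaxis_rate} outside [0, 1]")
        d_bound = 1.0 / (2.0 * len(dims))
        if not 0.0 <= diffusion_rate <= d_bound + 1e-12:
            raise ConfigError(
                f"diffusion rate {diffusion_rate} outside stability bound "
                f"[0, {d_bound}] for {len(dims)}D"
            )
        if sorted(stage2_order) != sorted(STAGE2_OPS):
            raise ConfigError(f"stage2_order must permute {STAGE2_OPS}")
        if substeps < 1:
            raise ConfigError("substeps must be >= 1")
        self.dims = dims
        self.n_nodes = int(np.prod(dims))
        self.flow_mode = flow_mode
        self.flow_rate = float(flow_rate)
        self.diffusion_rate = float(diffusion_rate)
        self.chemotaxis_rate = float(chemotaxis_rate)
        self.inflow: Dict[str, float] = dict(inflow or {})
        self.base_inflow: Dict[str, float] = dict(self.inflow)
        self.stochastic = bool(stochastic)
        self.stage2_order = tuple(stage2_order)
        self.substeps = int(substeps)
        self.cell_diffusion = bool(cell_diffusion)
        self.mutation = mutation
        self.generation = 0
        self.nodes: List[PointEnvironment] = [
            PointEnvironment(index=f) for f in range(self.n_nodes)
        ]
        self.populations: Dict[str, Population] = {}
        self._neighbors = self._build_neighbors()
        self._axis0_stride = int(np.prod(dims[1:])) if len(dims) > 1 else 1

    # -- construction -----------------------------------------------------

    def _build_neighbors(self) -> List[List[int]]:
        shape = self.dims
        strides = [int(np.prod(shape[i + 1 :])) for i in range(len(shape))]
        out: List[List[int]] = []
        for f in range(self.n_nodes):
            coord = list(np.unravel_index(f, shape))
            nb = []
            for ax in range(len(shape)):
                for step in (-1, 1):
                    c = coord[ax] + step
                    if 0 <= c < shape[ax]:
                        nb.append(f + step * strides[ax])
            out.append(sorted(nb))
        return out

    def register(self, pop: Population):
        """Add a population: every node gains a (possibly empty) cohort map,
        shared between the population and the node's resident entry."""
        if pop.species_id in self.populations:
            raise ConfigError(f"duplicate species id {pop.species_id!r}")
        self.populations[pop.species_id] = pop
        for env in self.nodes:
            env.add_population(pop)

    # -- accounting -------------------------------------------------------

    def substrate_ids(self) -> List[str]:
        ids = set(self.inflow) | set(self.base_inflow)
        for env in self.nodes:
            ids.update(env.substrates)
        for pop in self.populations.values():
            ids |= pop.structure.consumed | set(pop.structure.produced)
            ids |= pop.structure.activators | pop.structure.inhibitors
        return sorted(ids)

    def total_substrate(self, sub: str) -> float:
        return sum(env.substrates.get(sub, 0.0) for env in self.nodes)

    def total_cells(self, species: Optional[str] = None) -> float:
        pops = [self.populations[species]] if species else self.populations.values()
        return sum(p.total_count() for p in pops)

    def species_counts(self, node: int) -> Dict[str, float]:
        return {
            sid: sum(pop.cohorts_by_node.get(node, {}).values())
            for sid, pop in self.populations.items()
        }

    # -- events -----------------------------------------------------------

    def apply_event(self, event, rng=None):
        if isinstance(event, SetInflowEvent):
            if event.composition is not None:
                self.inflow = dict(event.composition)
            elif event.factor is not None:
                self.inflow = {k: v * event.factor for k, v in self.inflow.items()}
            else:
                raise ConfigError("SetInflowEvent needs a composition or a factor")
        elif isinstance(event, HorizontalTransferEvent):
            try:
                donor = self.populations[event.donor]
                acceptor = self.populations[event.acceptor]
            except KeyError as exc:
                raise ConfigError(f"event references unknown population {exc}") from exc
            if not 0 <= event.node < self.n_nodes:
                raise ConfigError(f"event references unknown node {event.node}")
            slot = donor.structure.slot(event.slot)
            new_pop = genome.horizontal_transfer(
                donor,
                acceptor,
                slot,
                event.node,
                event.n_cells,
                new_species_id=event.new_species_id,
                rng=rng,
                stochastic=self.stochastic,
            )
            self.register(new_pop)
        elif isinstance(event, CustomEvent):
            event.fn(self)
        else:
            raise ConfigError(f"unknown event type {type(event).__name__}")


# ---------------------------------------------------------------------------
# stage-2 operators


def _habitat_rng(h: "Habitat") -> np.random.Generator:
    rng = getattr(h, "_stage2_rng", None)
    if rng is None:
        rng = h._stage2_rng = np.random.default_rng(0)
    return rng



def _node_inflow(h: Habitat, env: PointEnvironment) -> Dict[str, float]:
    return env.inflow if env.inflow is not None else h.inflow


def flow_step_through(h: Habitat) -> Habitat:
    """Synchronous downstream advection of cells and substrates along axis 0.

    Every node sends fraction ``r`` of everything to its downstream neighbor;
    upstream-face nodes additionally receive ``r * inflow`` of each inflow
    substrate, and the downstream face's sent fraction leaves the system.
    """
    r = h.flow_rate
    if r == 0.0:
        return h
    stride = h._axis0_stride
    n0 = h.dims[0]
    upstream_face = [f for f in range(h.n_nodes) if (f // stride) % n0 == 0]
    subs = h.substrate_ids()
    old = {sub: [env.substrates.get(sub, 0.0) for env in h.nodes] for sub in subs}
    for f, env in enumerate(h.nodes):
        i0 = (f // stride) % n0
        for sub in subs:
            new = (1.0 - r) * old[sub][f]
            if i0 > 0:
                new += r * old[sub][f - stride]
            else:
                new += r * _node_inflow(h, env).get(sub, 0.0)
            env.substrates[sub] = new
    rng = _habitat_rng(h) if h.stochastic else None
    for pop in h.populations.values():
        moves: List[Tuple[int, Combination, float]] = []
        for f in range(h.n_nodes):
            cohorts = pop.cohorts_by_node.get(f, {})
            for combo, n in list(cohorts.items()):
                if n <= 0:
                    continue
                if h.stochastic:
                    moved = float(rng.binomial(int(n), r))
                else:
                    moved = n * r
                if moved > 0:
                    moves.append((f, combo, moved))
        for f, combo, moved in moves:
            src = pop.cohorts_by_node[f]
            src[combo] = src[combo] - moved
            if src[combo] <= 0:
                del src[combo]
            i0 = (f // stride) % n0
            if i0 < n0 - 1:  # downstream face's share leaves the system
                dst = pop.cohorts_by_node[f + stride]
                dst[combo] = dst.get(combo, 0.0) + moved
    return h


def flow_step_perpendicular(h: Habitat) -> Habitat:
    """Independent per-node exchange with an external flow: every node loses
    fraction ``r`` of cells and substrates and gains ``r * inflow`` of each
    inflow substrate.  No inter-node advection; no cells enter with inflow."""
    r = h.flow_rate
    if r == 0.0:
        return h
    subs = h.substrate_ids()
    for env in h.nodes:
        inflow = _node_inflow(h, env)
        for sub in subs:
            env.substrates[sub] = (1.0 - r) * env.substrates.get(
                sub, 0.0
            ) + r * inflow.get(sub, 0.0)
    rng = _habitat_rng(h) if h.stochastic else None
    for pop in h.populations.values():
        for f in range(h.n_nodes):
            cohorts = pop.cohorts_by_node.get(f, {})
            for combo, n in list(cohorts.items()):
                if n <= 0:
                    continue
                lost = float(rng.binomial(int(n), r)) if h.stochastic else n * r
                cohorts[combo] = n - lost
                if cohorts[combo] <= 0:
                    del cohorts[combo]
    return h


def diffusion_step(h: Habitat) -> Habitat:
    """Synchronous nearest-neighbor substrate diffusion:
    ``dS(x) = d * sum_nb (S(y) - S(x))``.  Exactly conservative in a closed
    system; a uniform field is a fixed point.  Cells diffuse only when the
    habitat's ``cell_diffusion`` toggle is on."""
    d = h.diffusion_rate
    if d == 0.0:
        return h
    subs = h.substrate_ids()
    for sub in subs:
        old = [env.substrates.get(sub, 0.0) for env in h.nodes]
        for f, env in enumerate(h.nodes):
            delta = sum(old[g] - old[f] for g in h._neighbors[f])
            env.substrates[sub] = old[f] + d * delta
    if h.cell_diffusion:
        rng = _habitat_rng(h) if h.stochastic else None
        for pop in h.populations.values():
            moves: List[Tuple[int, int, Combination, float]] = []
            for f in range(h.n_nodes):
                for combo, n in list(pop.cohorts_by_node.get(f, {}).items()):
                    if n <= 0:
                        continue
                    nbs = h._neighbors[f]
                    if h.stochastic:
                        probs = [d] * len(nbs) + [1.0 - d * len(nbs)]
                        parts = rng.multinomial(int(n), probs)
                        for g, part in zip(nbs, parts[:-1]):
                            if part:
                                moves.append((f, g, combo, float(part)))
                    else:
                        for g in nbs:
                            moves.append((f, g, combo, n * d))
            for f, g, combo, amt in moves:
                src = pop.cohorts_by_node[f]
                src[combo] = src.get(combo, 0.0) - amt
                if src[combo] <= 0:
                    del src[combo]
                dst = pop.cohorts_by_node[g]
                dst[combo] = dst.get(combo, 0.0) + amt
    return h


def attractiveness(env, structure: TrophicStructure, sensitivity: float = 0.0) -> float:
    """Favorability score of a node for a cohort: total consumable substrate
    minus sensitivity-weighted inhibitor load.  Deterministic; an empty
    environment scores 0."""
    subs = env.substrates if isinstance(env, PointEnvironment) else env
    score = sum(subs.get(sub, 0.0) for sub in structure.consumed)
    score -= sensitivity * sum(subs.get(sub, 0.0) for sub in structure.inhibitors)
    return score


def chemotaxis_step(h: Habitat, rng=None) -> Habitat:
    """Greedy gradient-following movement from a synchronous snapshot.

    Each cohort evaluates its own attractiveness score (which uses its
    sensitivity allele) at its node and all neighbors; if the best neighbor
    strictly improves on the current node (tolerance 1e-12; ties between
    neighbors broken toward the lowest flat index), fraction ``c`` of the
    cohort moves there.  Total cells are conserved exactly.
    """
    c = h.chemotaxis_rate
    if c == 0.0:
        return h
    if rng is None and h.stochastic:
        rng = _habitat_rng(h)
    snapshot = [dict(env.substrates) for env in h.nodes]
    for pop in h.populations.values():
        struct = pop.structure
        params = pop.params
        moves: List[Tuple[int, int, Combination, float]] = []
        for f in range(h.n_nodes):
            cohorts = pop.cohorts_by_node.get(f, {})
            for combo, n in cohorts.items():
                if n <= 0:
                    continue
                s_eff = cohort_traits(struct, params, combo).s if params else 0.0
                here = attractiveness(snapshot[f], struct, s_eff)
                best_g, best_score = -1, -np.inf
                for g in h._neighbors[f]:  # ascending: ties keep lowest index
                    score = attractiveness(snapshot[g], struct, s_eff)
                    if score > best_score:
                        best_g, best_score = g, score
                if best_g >= 0 and best_score > here + 1e-12:
                    moved = float(rng.binomial(int(n), c)) if h.stochastic else n * c
                    if moved > 0:
                        moves.append((f, best_g, combo, moved))
        for f, g, combo, moved in moves:
            src = pop.cohorts_by_node[f]
            src[combo] = src[combo] - moved
            if src[combo] <= 0:
                del src[combo]
            dst = pop.cohorts_by_node[g]
            dst[combo] = dst.get(combo, 0.0) + moved
    return h


# ---------------------------------------------------------------------------
# simulation loop


def _stage2(h: Habitat, seed: int):
    for sub in range(h.substeps):
        h._stage2_rng = np.random.default_rng(
            [seed & 0x7FFFFFFF, h.generation, 1_000_000 + sub]
        )
        for op in h.stage2_order:
            if op == "flow":
                if h.flow_mode == "through":
                    flow_step_through(h)
                else:
                    flow_step_perpendicular(h)
            elif op == "diffusion":
                diffusion_step(h)
            elif op == "chemotaxis":
                chemotaxis_step(h)


def simulation_step(
    h: Habitat, schedule: Optional[EventSchedule] = None, seed: int = 0
) -> Habitat:
    """One full generation: due events, stage 1 at every node, then stage 2.

    Per-node RNG streams are derived from (seed, generation, node index), so
    the stage-1 result is independent of node processing order even with
    stochastic sampling or infinite-sites mutation draws.
    """
    if schedule is not None:
        ev_rng = np.random.default_rng([seed & 0x7FFFFFFF, h.generation, 2_000_000])
        for event in schedule.due(h.generation):
            h.apply_event(event, rng=ev_rng)
    for env in h.nodes:
        rng = np.random.default_rng([seed & 0x7FFFFFFF, h.generation, env.index])
        node_step(env, rng=rng, stochastic=h.stochastic, mutation=h.mutation)
    _stage2(h, seed)
    h.generation += 1
    return h


def run(
    h: Habitat,
    generations: int,
    schedule: Optional[EventSchedule] = None,
    seed: int = 0,
    recorder=None,
    record_every: int = 1,
    record_alleles: bool = True,
):
    """Iterate the two-stage step, recording per-generation state.

    Returns the recorder's trajectory (a fresh
    :class:`evogrid.trajectory.Recorder` is created when none is given).
    Deterministic given the seed.
    """
    if generations < 0:
        raise ParameterError("generations must be >= 0")
    if recorder is None:
        from .trajectory import Recorder

        recorder = Recorder(record_every=record_every, record_alleles=record_alleles)
    recorder.record(h)
    for _ in range(generations):
        simulation_step(h, schedule, seed)
        recorder.record(h)
    return recorder.trajectory()
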