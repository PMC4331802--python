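"""Programmatic builders for the benchmark communities.

Two communities are shipped:

* ``poisoner_prey`` — a prey species that lives on the inflow-supplied
  non-specific substrate N1 and secretes S1, and a poisoner that consumes both
  N1 and S1 (compensating one with the other), secretes the toxin S2 that
  inhibits the prey, and is activated by S1.  The prey is polymorphic in its
  sensitivity to S2, the poisoner in its S1-utilization efficiency.

* ``two_cycles`` — two trophically disjoint three-species rings P1-P2-P3 and
  P4-P5-P6.  Species Pi utilizes its specific substrate Si plus the
  non-specific inflow substrate N and secretes the next ring member's
  substrate.  All six species breed either non-compensatory (NC-NC, Liebig's
  law) or compensatory (C-C, Rubel's law).  The benchmark schedule transfers
  the S6-utilization gene from P6 into P1 cells at generation 100 (founding
  P7, which joins the two rings), cuts the non-specific inflow 100-fold at
  generation 2000 and restores it at generation 3000.

The numeric defaults (``DEFAULT_POISONER_PREY_PARAMS``,
``DEFAULT_TWO_CYCLES_PARAMS``) are a non-canonical reference parameter set:
free knobs chosen so the deterministic flow-through poisoner-prey run shows
the qualitative pattern of interest (prey confined to proximal nodes, adaptive
alleles fixing faster where selection is stronger).  Every knob can be
overridden through the scenario spec.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from .config import GeneSpec, ScenarioSpec, SpeciesSpec, validate
from .dynamics import MutationSettings, ReproductionParams
from .errors import ConfigError
from .genome import GeneSlot, Population, TrophicStructure
from .spatial import (
    EventSchedule,
    Habitat,
    HorizontalTransferEvent,
    SetInflowEvent,
)

__all__ = [
    "DEFAULT_POISONER_PREY_PARAMS",
    "DEFAULT_TWO_CYCLES_PARAMS",
    "poisoner_prey",
    "two_cycles",
    "schedule_ht_and_starvation",
    "build_habitat",
    "build_poisoner_prey",
    "build_two_cycles",
    "builtin_scenario",
]

#: Non-canonical reference knobs for the poisoner-prey community.
DEFAULT_POISONER_PREY_PARAMS: Dict[str, float] = {
    "n_inflow": 40_000.0,  # non-specific substrate concentration in the inflow
    "n_initial": 500.0,  # initial N1 per node
    "s2_gradient_high": 4.0,  # node-1 toxin level for gradient initialization
    "prey_count": 500.0,
    "poisoner_count": 500.0,
    "prey_yield_s1": 10.0,  # S1 secreted per newborn prey cell
    "poisoner_yield_s2": 2e-4,  # toxin secreted per newborn poisoner cell
    "activator_gain": 1e-4,  # poisoner growth activation per unit S1
    "prey_sensitivity_low": 0.025,  # adaptive (resistant) allele
    "prey_sensitivity_high": 0.25,  # inadaptive (sensitive) allele
    "poisoner_eff_low": 0.2,  # inadaptive S1-utilization allele
    "poisoner_eff_high": 0.8,  # adaptive S1-utilization allele
    "prey_k_max": 2.0,  # prey takes a larger share of fresh N1
    "poisoner_k_max": 1.0,
    "poisoner_c_s1": 3.0,  # S1 units needed per new poisoner cell
    "prey_death": 0.04,  # per-generation resource-independent mortality
    "poisoner_death": 0.01,
}

#: Non-canonical reference knobs for the two-trophic-cycles community.
DEFAULT_TWO_CYCLES_PARAMS: Dict[str, float] = {
    "n_inflow": 50_000.0,
    "n_initial": 2_000.0,
    "s_initial": 500.0,  # bootstrap level of each specific substrate
    "count": 2_000.0,
    "yield_s": 7.0,  # specific substrate secreted per newborn cell
    "utilization_eff": 0.9,
    "k_max": 1.0,
    "c_n": 1.0,  # non-specific substrate units per new cell
    "c_s": 6.0,  # specific substrate units per new cell
    "ht_generation": 100,
    "starvation_generation": 2000,
    "recovery_generation": 3000,
    "starvation_factor": 0.01,
    "ht_n_cells": 100.0,
}


def _merged(defaults: Dict[str, float], overrides: Dict[str, float]) -> Dict[str, float]:
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown parameter knobs: {sorted(unknown)}")
    out = dict(defaults)
    out.update(overrides)
    return out


# ---------------------------------------------------------------------------
# scenario specs


def poisoner_prey(
    n_nodes: int = 10,
    flow_mode: str = "through",
    flow_rate: float = 0.02,
    diffusion_rate: float = 0.0,
    chemotaxis_rate: float = 0.0,
    s2_gradient: bool = False,
    stochastic: bool = False,
    generations: int = 900,
    seeds: Optional[List[int]] = None,
    record_every: int = 1,
    **knobs,
) -> ScenarioSpec:
    """Scenario spec of the poisoner-prey community (defaults mirror the
    flow-through benchmark: 10 nodes, flow rate 0.02, uniform initial state)."""
    p = _merged(DEFAULT_POISONER_PREY_PARAMS, knobs)
    substrates = {
        "N1": {"uniform": p["n_initial"]},
        "S1": {"uniform": 0.0},
        "S2": (
            {"gradient": [p["s2_gradient_high"], 0.0]}
            if s2_gradient
            else {"uniform": 0.0}
        ),
    }
    prey = SpeciesSpec(
        id="prey",
        consumed=["N1"],
        produced={"S1": True},
        inhibitors=["S2"],
        strategy="non-compensatory",
        params={
            "c": {"N1": 1.0},
            "k_max": p["prey_k_max"],
            "e": {"N1": 1.0},
            "yields": {"S1": p["prey_yield_s1"]},
            "death_rate": p["prey_death"],
        },
        genes=[
            GeneSpec(
                id="s_S2",
                role="sensitivity",
                target="S2",
                bounds=[0.0, 10.0],
                support=[p["prey_sensitivity_low"], p["prey_sensitivity_high"]],
                freqs=[0.5, 0.5],
            )
        ],
        initial_count={"uniform": p["prey_count"]},
    )
    poisoner = SpeciesSpec(
        id="poisoner",
        consumed=["N1", "S1"],
        produced={"S2": True},
        activators=["S1"],
        strategy="compensatory",
        params={
            "c": {"N1": 1.0, "S1": p["poisoner_c_s1"]},
            "weights": {"N1": 1.0, "S1": 1.0},
            "k_max": p["poisoner_k_max"],
            "e": {"N1": 1.0},
            "yields": {"S2": p["poisoner_yield_s2"]},
            "a": p["activator_gain"],
            "death_rate": p["poisoner_death"],
        },
        genes=[
            GeneSpec(
                id="e_S1",
                role="utilization-efficiency",
                target="S1",
                bounds=[0.01, 1.0],
                support=[p["poisoner_eff_low"], p["poisoner_eff_high"]],
                freqs=[0.5, 0.5],
            )
        ],
        initial_count={"uniform": p["poisoner_count"]},
    )
    return validate(
        ScenarioSpec(
            name="poisoner_prey",
            dims=[n_nodes],
            flow_mode=flow_mode,
            flow_rate=flow_rate,
            diffusion_rate=diffusion_rate,
            chemotaxis_rate=chemotaxis_rate,
            stochastic=stochastic,
            generations=generations,
            seeds=list(seeds) if seeds is not None else [0],
            record_every=record_every,
            inflow={"N1": p["n_inflow"]},
            substrates=substrates,
            species=[prey, poisoner],
        )
    )


def _ring(first: int) -> List[Tuple[str, str, str]]:
    """(species, utilized substrate, secreted substrate) triples of one cycle."""
    ids = [first, first + 1, first + 2]
    return [
        (f"P{i}", f"S{i}", f"S{ids[(k + 1) % 3]}") for k, i in enumerate(ids)
    ]


def two_cycles(
    strategy: str = "C-C",
    n_nodes: int = 10,
    flow_mode: str = "through",
    flow_rate: float = 0.02,
    diffusion_rate: float = 0.0,
    chemotaxis_rate: float = 0.0,
    ht_node: int = 0,
    stochastic: bool = False,
    cell_diffusion: bool = False,
    generations: int = 3500,
    seeds: Optional[List[int]] = None,
    record_every: int = 1,
    with_schedule: bool = True,
    **knobs,
) -> ScenarioSpec:
    """Scenario spec of the two-trophic-cycles community with the HT +
    starvation schedule.  ``strategy`` is ``"NC-NC"`` (all species Liebig) or
    ``"C-C"`` (all species Rubel)."""
    if strategy not in ("NC-NC", "C-C"):
        raise ConfigError(f"strategy must be 'NC-NC' or 'C-C', got {strategy!r}")
    p = _merged(DEFAULT_TWO_CYCLES_PARAMS, knobs)
    breed = "compensatory" if strategy == "C-C" else "non-compensatory"
    substrates: Dict[str, Dict] = {"N": {"uniform": p["n_initial"]}}
    species: List[SpeciesSpec] = []
    for sid, s_in, s_out in _ring(1) + _ring(4):
        substrates[s_in] = {"uniform": p["s_initial"]}
        species.append(
            SpeciesSpec(
                id=sid,
                consumed=["N", s_in],
                produced={s_out: True},
                strategy=breed,
                params={
                    "c": {"N": p["c_n"], s_in: p["c_s"]},
                    "weights": {"N": 1.0, s_in: 1.0},
                    "k_max": p["k_max"],
                    "e": {"N": 1.0},
                    "yields": {s_out: p["yield_s"]},
                },
                genes=[
                    GeneSpec(
                        id=f"e_{s_in}",
                        role="utilization-efficiency",
                        target=s_in,
                        bounds=[0.01, 1.0],
                        support=[p["utilization_eff"]],
                        freqs=[1.0],
                    )
                ],
                initial_count={"uniform": p["count"]},
            )
        )
    schedule: List[Dict] = []
    if with_schedule:
        schedule = [
            {
                "generation": int(p["ht_generation"]),
                "type": "horizontal_transfer",
                "node": ht_node,
                "donor": "P6",
                "acceptor": "P1",
                "slot": "e_S6",
                "n_cells": p["ht_n_cells"],
                "new_species_id": "P7",
            },
            {
                "generation": int(p["starvation_generation"]),
                "type": "scale_inflow",
                "factor": p["starvation_factor"],
            },
            {
                "generation": int(p["recovery_generation"]),
                "type": "set_inflow",
                "composition": {"N": p["n_inflow"]},
            },
        ]
    return validate(
        ScenarioSpec(
            name=f"two_cycles_{strategy.lower().replace('-', '_')}",
            dims=[n_nodes],
            flow_mode=flow_mode,
            flow_rate=flow_rate,
            diffusion_rate=diffusion_rate,
            chemotaxis_rate=chemotaxis_rate,
            cell_diffusion=cell_diffusion,
            stochastic=stochastic,
            generations=generations,
            seeds=list(seeds) if seeds is not None else [0],
            record_every=record_every,
            inflow={"N": p["n_inflow"]},
            substrates=substrates,
            species=species,
            schedule=schedule,
        )
    )


def schedule_ht_and_starvation(
    node: int,
    inflow: Optional[Dict[str, float]] = None,
    n_cells: float = DEFAULT_TWO_CYCLES_PARAMS["ht_n_cells"],
) -> EventSchedule:
    """The benchmark event schedule: S6-utilization HT from P6 into P1 at the
    given node at generation 100 (founding P7), non-specific inflow cut to
    1/100 at generation 2000, original inflow restored at generation 3000."""
    restore = dict(
        inflow
        if inflow is not None
        else {"N": DEFAULT_TWO_CYCLES_PARAMS["n_inflow"]}
    )
    return EventSchedule(
        [
            HorizontalTransferEvent(
                generation=100,
                node=node,
                donor="P6",
                acceptor="P1",
                slot="e_S6",
                n_cells=n_cells,
                new_species_id="P7",
            ),
            SetInflowEvent(generation=2000, factor=0.01),
            SetInflowEvent(generation=3000, composition=restore),
        ]
    )


# ---------------------------------------------------------------------------
# spec -> simulator objects


def _field_values(init: Dict, dims: List[int]) -> List[float]:
    n_nodes = 1
    for d in dims:
        n_nodes *= d
    if "uniform" in init:
        return [float(init["uniform"])] * n_nodes
    if "values" in init:
        return [float(v) for v in init["values"]]
    first, last = init["gradient"]
    n0 = dims[0]
    stride = n_nodes // n0
    vals = []
    for f in range(n_nodes):
        i0 = (f // stride) % n0
        frac = i0 / (n0 - 1) if n0 > 1 else 0.0
        vals.append(float(first) + (float(last) - float(first)) * frac)
    return vals


def _combinations(genes: List[GeneSpec]) -> List[Tuple[Tuple[float, ...], float]]:
    combos: List[Tuple[Tuple[float, ...], float]] = [((), 1.0)]
    for g in genes:
        combos = [
            (vals + (v,), w * f)
            for vals, w in combos
            for v, f in zip(g.support, g.freqs)
            if f > 0
        ]
    return combos


def build_habitat(spec: ScenarioSpec) -> Tuple[Habitat, EventSchedule]:
    """Instantiate a validated scenario spec as a Habitat plus its schedule."""
    validate(spec)
    mutation = None
    if spec.mutation is not None and spec.mutation.get("rate", 0.0) > 0:
        mutation = MutationSettings(
            rate=spec.mutation["rate"],
            sites_model=spec.mutation.get("sites_model", "finite"),
            beta_a=spec.mutation.get("beta_a", 2.0),
            beta_b=spec.mutation.get("beta_b", 2.0),
        )
    habitat = Habitat(
        dims=spec.dims,
        flow_mode=spec.flow_mode,
        flow_rate=spec.flow_rate,
        diffusion_rate=spec.diffusion_rate,
        chemotaxis_rate=spec.chemotaxis_rate,
        inflow=dict(spec.inflow),
        stochastic=spec.stochastic,
        stage2_order=tuple(spec.stage2_order),
        substeps=spec.substeps,
        cell_diffusion=spec.cell_diffusion,
        mutation=mutation,
    )
    for sub, init in spec.substrates.items():
        for env, value in zip(habitat.nodes, _field_values(init, spec.dims)):
            env.substrates[sub] = value
    for sp in spec.species:
        structure = TrophicStructure(
            species_id=sp.id,
            consumed=frozenset(sp.consumed),
            produced=dict(sp.produced),
            activators=frozenset(sp.activators),
            inhibitors=frozenset(sp.inhibitors),
            reproduction_strategy=sp.strategy,
            gene_slots=tuple(
                GeneSlot(
                    id=g.id,
                    role=g.role,
                    bounds=(float(g.bounds[0]), float(g.bounds[1])),
                    target_substrate=g.target,
                )
                for g in sp.genes
            ),
        )
        params = ReproductionParams(
            c={k: float(v) for k, v in sp.params.get("c", {}).items()},
            k_max=float(sp.params.get("k_max", 1.0)),
            maintenance=float(sp.params.get("maintenance", 0.0)),
            death_rate=float(sp.params.get("death_rate", 0.0)),
            s=float(sp.params.get("s", 0.0)),
            a=float(sp.params.get("a", 0.0)),
            e={k: float(v) for k, v in sp.params.get("e", {}).items()},
            yields={k: float(v) for k, v in sp.params.get("yields", {}).items()},
            weights={k: float(v) for k, v in sp.params.get("weights", {}).items()},
        )
        counts = (
            _field_values(sp.initial_count, spec.dims)
            if sp.initial_count
            else [0.0] * spec.n_nodes
        )
        combos = _combinations(sp.genes)
        cohorts_by_node: Dict[int, Dict[Tuple[float, ...], float]] = {}
        for f, n in enumerate(counts):
            node_cohorts: Dict[Tuple[float, ...], float] = {}
            for combo, w in combos:
                amount = n * w
                if spec.stochastic:
                    amount = float(round(amount))
                if amount > 0:
                    node_cohorts[combo] = amount
            cohorts_by_node[f] = node_cohorts
        pop = Population(
            structure=structure, params=params, cohorts_by_node=cohorts_by_node
        )
        habitat.register(pop)
    events: List[object] = []
    for ev in spec.schedule:
        if ev["type"] == "horizontal_transfer":
            events.append(
                HorizontalTransferEvent(
                    generation=int(ev["generation"]),
                    node=int(ev["node"]),
                    donor=ev["donor"],
                    acceptor=ev["acceptor"],
                    slot=ev["slot"],
                    n_cells=float(ev["n_cells"]),
                    new_species_id=ev.get("new_species_id"),
                )
            )
        elif ev["type"] == "scale_inflow":
            events.append(
                SetInflowEvent(
                    generation=int(ev["generation"]), factor=float(ev["factor"])
                )
            )
        else:
            events.append(
                SetInflowEvent(
                    generation=int(ev["generation"]),
                    composition={
                        k: float(v) for k, v in ev["composition"].items()
                    },
                )
            )
    return habitat, EventSchedule(events)


def build_poisoner_prey(
    spec: Optional[ScenarioSpec] = None, **kwargs
) -> Tuple[Habitat, EventSchedule]:
    if spec is None:
        spec = poisoner_prey(**kwargs)
    return build_habitat(spec)


def build_two_cycles(
    strategy: str = "C-C", spec: Optional[ScenarioSpec] = None, **kwargs
) -> Tuple[Habitat, EventSchedule]:
    if spec is None:
        spec = two_cycles(strategy=strategy, **kwargs)
    return build_habitat(spec)


def builtin_scenario(name: str, **kwargs) -> ScenarioSpec:
    """Look up a built-in scenario spec by name."""
    builders = {
        "poisoner_prey": poisoner_prey,
        "two_cycles_nc_nc": lambda **kw: two_cycles(strategy="NC-NC", **kw),
        "two_cycles_c_c": lambda **kw: two_cycles(strategy="C-C", **kw),
    }
    if name not in builders:
        raise ConfigError(
            f"unknown scenario {name!r}; built-ins: {sorted(builders)}"
        )
    return builders[name](**kwargs)
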