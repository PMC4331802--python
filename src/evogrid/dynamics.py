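"""Stage-1 update of one point environment (one lattice node).

Per discrete generation, each node runs independently of every other node:

1. substrate consumption — each substrate pool is split among the demanding
   cohorts of all resident species proportionally to demand, capped by
   availability;
2. utilization — consumed substrate is converted to usable resource with the
   cohort's utilization efficiency;
3. growth coefficient — non-compensatory strategy applies Liebig's law of the
   minimum (growth set by the scarcest required resource), compensatory
   strategy applies Rubel's law of compensation (abundant resources offset
   scarce ones through a weighted sum);
4. activation/inhibition — environmental substrates multiply growth through a
   bounded hyperbolic factor;
5. reproduction, then substrate synthesis and secretion, then (optionally)
   mutation.

Per-cohort fitness is recorded as (after - before) / before over the
reproduction stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from . import genome
from .errors import ParameterError
from .genome import Combination, Population, TrophicStructure

__all__ = [
    "ReproductionParams",
    "MutationSettings",
    "PointEnvironment",
    "cohort_traits",
    "allocate_consumption",
    "growth_coefficient_nc",
    "growth_coefficient_c",
    "interaction_multiplier",
    "reproduce",
    "synthesize_and_secrete",
    "cohort_fitness",
    "node_step",
]


@dataclass
class ReproductionParams:
    """Species-level numeric parameters of the synthesis/reproduction strategies.

    c
        resource units required per new cell, per consumed substrate.
    k_max
        maximum per-generation growth coefficient (dimensionless).
    e
        utilization efficiency per substrate: fraction of consumed resource
        converted to usable form (default 1; allele-carried when the species
        has a utilization-efficiency gene slot).
    s, a
        inhibitor sensitivity and activator gain (per concentration unit;
        ``s`` is allele-carried when a sensitivity slot exists).
    yields
        units of each produced substrate synthesized per newborn cell:
        synthesis is powered by utilization energy, so secretion scales with
        realized reproduction, not standing population size (a starving
        cohort secretes nothing).
    weights
        compensation weights of the compensatory (Rubel) growth law.
    maintenance
        resource units per cell per generation kept for upkeep (default 0).
    death_rate
        fraction of cells dying per generation independent of resources
        (default 0: cells are lost only through outflow).
    """

    c: Dict[str, float] = field(default_factory=dict)
    k_max: float = 1.0
    maintenance: float = 0.0
    death_rate: float = 0.0
    s: float = 0.0
    a: float = 0.0
    e: Dict[str, float] = field(default_factory=dict)
    yields: Dict[str, float] = field(default_factory=dict)
    weights: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for sub, ci in self.c.items():
            if ci <= 0:
                raise ParameterError(f"c[{sub!r}] must be > 0, got {ci}")
        if self.k_max <= 0:
            raise ParameterError(f"k_max must be > 0, got {self.k_max}")
        if self.s < 0 or self.a < 0:
            raise ParameterError("sensitivity and activator gain must be >= 0")
        if not 0.0 <= self.death_rate <= 1.0:
            raise ParameterError(f"death_rate must be in [0, 1], got {self.death_rate}")
        for sub, ei in self.e.items():
            if not 0 < ei <= 1:
                raise ParameterError(f"e[{sub!r}] must be in (0, 1], got {ei}")


@dataclass
class MutationSettings:
    """Per-generation mutation configuration applied inside node_step."""

    rate: float = 0.0
    sites_model: str = "finite"
    beta_a: float = 2.0
    beta_b: float = 2.0


@dataclass
class Resident:
    """One species' presence at a node; ``cohorts`` is shared with the
    population's ``cohorts_by_node`` entry, so in-place edits are visible to
    both views."""

    population: Population
    cohorts: Dict[Combination, float]


@dataclass
class PointEnvironment:
    """One lattice node: substrate pools plus resident cohorts (a 0D block)."""

    index: int
    substrates: Dict[str, float] = field(default_factory=dict)
    residents: Dict[str, Resident] = field(default_factory=dict)
    inflow: Optional[Dict[str, float]] = None
    internal: Dict[str, Dict[str, float]] = field(default_factory=dict)
    last_fitness: Dict[str, Dict[Combination, float]] = field(default_factory=dict)

    def add_population(self, pop: Population):
        cohorts = pop.cohorts_by_node.setdefault(self.index, {})
        self.residents[pop.species_id] = Resident(pop, cohorts)

    def total_cells(self) -> float:
        return sum(sum(r.cohorts.values()) for r in self.residents.values())


@dataclass
class CohortTraits:
    """Effective per-cohort parameters after applying allele overrides."""

    e: Dict[str, float]
    s: float
    a: float
    k_max: float
    yields: Dict[str, float]


def cohort_traits(
    structure: TrophicStructure, params: ReproductionParams, combo: Combination
) -> CohortTraits:
    """Species defaults overridden by the cohort's allele values, slot by slot."""
    e = {sub: params.e.get(sub, 1.0) for sub in structure.consumed}
    yields = dict(params.yields)
    s, a, k_max = params.s, params.a, params.k_max
    for slot, value in zip(structure.gene_slots, combo):
        if slot.role == "utilization-efficiency" and slot.target_substrate:
            e[slot.target_substrate] = value
        elif slot.role == "sensitivity":
            s = value
        elif slot.role == "synthesis-efficiency" and slot.target_substrate:
            yields[slot.target_substrate] = value
        elif slot.role == "reproduction-parameter":
            k_max = value
    return CohortTraits(e=e, s=s, a=a, k_max=k_max, yields=yields)


def allocate_consumption(
    env: PointEnvironment,
) -> Dict[str, Dict[Combination, Dict[str, float]]]:
    """Split each substrate pool among demanding cohorts, proportionally to demand.

    A cohort of ``n`` cells demands ``n * k_max * c_i`` raw units of each
    consumed substrate (its ingestion need at full growth; utilization
    efficiency acts downstream, converting the raw share into usable resource,
    so efficient alleles extract more from the same share).  When a pool
    cannot cover total demand every demand is scaled by the same availability
    factor, so shares stay demand-proportional.  Pools are decremented by
    exactly the allocated totals and never go negative.  Species-internal
    (non-secreted) product pools are drawn down first.
    """
    demands: Dict[str, List[Tuple[str, Combination, float]]] = {}
    traits_cache: Dict[str, Dict[Combination, CohortTraits]] = {}
    for sid, res in env.residents.items():
        struct = res.population.structure
        params = res.population.params
        traits_cache[sid] = {}
        for combo, n in res.cohorts.items():
            if n <= 0:
                continue
            tr = cohort_traits(struct, params, combo)
            traits_cache[sid][combo] = tr
            for sub in struct.consumed:
                ci = params.c.get(sub)
                if ci is None:
                    continue
                demand = n * tr.k_max * ci
                if demand > 0:
                    demands.setdefault(sub, []).append((sid, combo, demand))

    alloc: Dict[str, Dict[Combination, Dict[str, float]]] = {
        sid: {combo: {} for combo in traits_cache[sid]} for sid in traits_cache
    }
    for sub, entries in demands.items():
        # internal pools first, species by species
        remaining = {i: d for i, (_, _, d) in enumerate(entries)}
        for sid in env.internal:
            pool = env.internal[sid].get(sub, 0.0)
            if pool <= 0:
                continue
            own = [i for i, (s2, _, _) in enumerate(entries) if s2 == sid]
            tot = sum(remaining[i] for i in own)
            if tot <= 0:
                continue
            factor = min(1.0, pool / tot)
            for i in own:
                take = remaining[i] * factor
                sid_i, combo_i, _ = entries[i]
                alloc[sid_i][combo_i][sub] = alloc[sid_i][combo_i].get(sub, 0.0) + take
                remaining[i] -= take
            env.internal[sid][sub] = max(0.0, pool - tot * factor)
        pool = env.substrates.get(sub, 0.0)
        total = sum(remaining.values())
        if total <= 0 or pool <= 0:
            for i, (sid_i, combo_i, _) in enumerate(entries):
                alloc[sid_i][combo_i].setdefault(sub, 0.0)
            continue
        factor = min(1.0, pool / total)
        granted = 0.0
        for i, (sid_i, combo_i, _) in enumerate(entries):
            take = remaining[i] * factor
            alloc[sid_i][combo_i][sub] = alloc[sid_i][combo_i].get(sub, 0.0) + take
            granted += take
        env.substrates[sub] = max(0.0, pool - granted)
    env._last_traits = traits_cache  # stashed for node_step
    return alloc


def growth_coefficient_nc(
    allocated: Mapping[str, float], c: Mapping[str, float], k_max: float = math.inf
) -> float:
    """Liebig's law of the minimum: growth is set by the scarcest required
    resource.  ``allocated`` is usable resource per cell; returns 0 if any
    required substrate got nothing."""
    k = k_max
    for sub, ci in c.items():
        if ci <= 0:
            raise ParameterError(f"c[{sub!r}] must be > 0")
        k = min(k, allocated.get(sub, 0.0) / ci)
    return max(0.0, k)


def growth_coefficient_c(
    allocated: Mapping[str, float],
    c: Mapping[str, float],
    w: Optional[Mapping[str, float]] = None,
    k_max: float = math.inf,
) -> float:
    """Rubel's law of compensation: abundant resources offset scarce ones.

    ``k = min(k_max, sum_i w_i * allocated_i / sum_i w_i * c_i)`` — strictly
    positive whenever any positively weighted substrate was allocated.
    """
    if w is None:
        w = {sub: 1.0 for sub in c}
    num = 0.0
    den = 0.0
    for sub, ci in c.items():
        if ci <= 0:
            raise ParameterError(f"c[{sub!r}] must be > 0")
        wi = w.get(sub, 0.0)
        if wi < 0:
            raise ParameterError(f"weight w[{sub!r}] must be >= 0")
        num += wi * allocated.get(sub, 0.0)
        den += wi * ci
    if den <= 0:
        raise ParameterError("compensation weights must not all be zero")
    return max(0.0, min(k_max, num / den))


def interaction_multiplier(inhibitors, activators, s: float, a: float) -> float:
    """Bounded hyperbolic activation/inhibition factor on growth.

    ``(1 + a * sum(activator conc)) / (1 + s * sum(inhibitor conc))`` — equal
    to 1 with no links, strictly decreasing in inhibitor load, increasing in
    activator load.
    """
    if s < 0 or a < 0:
        raise ParameterError("s and a must be >= 0")
    inh = sum(inhibitors.values()) if isinstance(inhibitors, Mapping) else inhibitors
    act = sum(activators.values()) if isinstance(activators, Mapping) else activators
    return (1.0 + a * act) / (1.0 + s * inh)


def reproduce(
    count: float,
    k: float,
    m: float = 1.0,
    death_rate: float = 0.0,
    stochastic: bool = False,
    rng=None,
) -> float:
    """New cohort size after reproduction: ``count * (1 + k*m - death_rate)``
    (floored at zero) in deterministic mode; Poisson births and binomial
    deaths with the same expectation in stochastic mode."""
    if k < 0 or m < 0:
        raise ParameterError("k and m must be >= 0")
    if not 0.0 <= death_rate <= 1.0:
        raise ParameterError("death_rate must be in [0, 1]")
    if count <= 0:
        return count
    if stochastic:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        births = gen.poisson(count * k * m)
        deaths = gen.binomial(int(count), death_rate) if death_rate > 0 else 0
        return float(max(0, int(count) + births - deaths))
    return count * max(0.0, 1.0 + k * m - death_rate)


def synthesize_and_secrete(
    count: float,
    structure: TrophicStructure,
    yields: Mapping[str, float],
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Substrate increments produced by ``count`` cells in one generation.

    Returns ``(secreted, internal)``: secreted products go to the environment
    pool, non-secreted products stay with the producing species for its own
    consumption next step.
    """
    secreted: Dict[str, float] = {}
    internal: Dict[str, float] = {}
    for sub, flag in structure.produced.items():
        y = yields.get(sub, 0.0)
        if y < 0:
            raise ParameterError(f"yield for {sub!r} must be >= 0")
        amount = count * y
        if amount == 0:
            continue
        (secreted if flag else internal)[sub] = amount
    return secreted, internal


def cohort_fitness(before: float, after: float) -> float:
    """Per-generation fitness of an allelic combination: (after-before)/before.

    Undefined (NaN sentinel) when the cohort started empty.
    """
    if before <= 0:
        return math.nan
    return (after - before) / before


def node_step(
    env: PointEnvironment,
    rng=None,
    stochastic: bool = False,
    mutation: Optional[MutationSettings] = None,
) -> Dict[str, Dict[Combination, float]]:
    """One stage-1 generation of a single point environment, in place.

    Applies consumption -> growth coefficients -> interaction multipliers ->
    reproduction -> synthesis/secretion -> mutation, and records per-cohort
    fitness in ``env.last_fitness``.  Touches no other node, so processing
    order across nodes is irrelevant.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    snapshot = dict(env.substrates)  # interaction terms read pre-consumption state
    alloc = allocate_consumption(env)
    traits_cache = env._last_traits
    fitness: Dict[str, Dict[Combination, float]] = {}
    for sid, res in env.residents.items():
        struct = res.population.structure
        params = res.population.params
        fitness[sid] = {}
        new_cohorts: Dict[Combination, float] = {}
        total_secreted: Dict[str, float] = {}
        total_internal: Dict[str, float] = {}
        for combo, n in res.cohorts.items():
            if n <= 0:
                continue
            tr = traits_cache[sid][combo]
            per_cell = {
                sub: alloc[sid][combo].get(sub, 0.0) * tr.e[sub] / n
                for sub in struct.consumed
            }
            c = {sub: params.c[sub] for sub in struct.consumed if sub in params.c}
            if struct.reproduction_strategy == "compensatory":
                k = growth_coefficient_c(per_cell, c, params.weights or None, tr.k_max)
            else:
                k = growth_coefficient_nc(per_cell, c, tr.k_max)
            m = interaction_multiplier(
                {sub: snapshot.get(sub, 0.0) for sub in struct.inhibitors},
                {sub: snapshot.get(sub, 0.0) for sub in struct.activators},
                tr.s,
                tr.a,
            )
            if stochastic:
                births = float(gen.poisson(n * k * m))
                deaths = (
                    float(gen.binomial(int(n), params.death_rate))
                    if params.death_rate > 0
                    else 0.0
                )
                after = max(0.0, float(int(n)) + births - deaths)
            else:
                births = n * k * m
                after = n * max(0.0, 1.0 + k * m - params.death_rate)
            fitness[sid][combo] = cohort_fitness(n, after)
            if after > 0:
                new_cohorts[combo] = after
            # synthesis is fuelled by utilization energy: secretion per newborn
            sec, internal = synthesize_and_secrete(births, struct, tr.yields)
            for sub, amt in sec.items():
                total_secreted[sub] = total_secreted.get(sub, 0.0) + amt
            for sub, amt in internal.items():
                total_internal[sub] = total_internal.get(sub, 0.0) + amt
        res.cohorts.clear()
        res.cohorts.update(new_cohorts)
        for sub, amt in total_secreted.items():
            env.substrates[sub] = env.substrates.get(sub, 0.0) + amt
        if total_internal:
            pool = env.internal.setdefault(sid, {})
            for sub, amt in total_internal.items():
                pool[sub] = pool.get(sub, 0.0) + amt
        if mutation is not None and mutation.rate > 0 and res.cohorts:
            genome.apply_mutations(
                res.population,
                env.index,
                mutation.rate,
                mutation.sites_model,
                rng=gen,
                stochastic=stochastic,
                beta_a=mutation.beta_a,
                beta_b=mutation.beta_b,
            )
    env.last_fitness = fitness
    return fitness
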