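"""Heritable state of species: gene-network structures and generalized genomes.

A species is identified with the *structure* of its gene networks: which
substrates it consumes and secretes, which environmental substances activate or
inhibit its growth, its reproduction strategy, and an ordered list of numeric
"gene slots" whose values are the heritable alleles.  A polymorphic population
is stored as explicit cohorts over full allelic combinations (one allele per
slot); the per-gene allele distributions of the generalized genome are marginal
views over those cohorts.

Cell counts are real-valued in deterministic mode and integer in stochastic
mode; every cell-moving operation (mutation, horizontal transfer, gene loss)
conserves total cell count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    DomainError,
    InsufficientCellsError,
    ParameterError,
    StructureError,
)

__all__ = [
    "ROLES",
    "GeneSlot",
    "TrophicStructure",
    "AlleleDistribution",
    "Cohort",
    "Population",
    "mutate_allele",
    "apply_mutations",
    "horizontal_transfer",
    "gene_loss",
    "species_identity",
    "marginal_allele_frequencies",
]

#: Admissible gene-slot roles: which model parameter an allele value overrides.
ROLES = (
    "utilization-efficiency",
    "sensitivity",
    "synthesis-efficiency",
    "reproduction-parameter",
)

Combination = Tuple[float, ...]
CohortMap = Dict[Combination, float]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class GeneSlot:
    """One heritable numeric parameter of a gene network.

    ``role`` states which model parameter the allele value carries
    (see :data:`ROLES`); ``target_substrate`` names the substrate the role
    applies to (utilization/synthesis efficiency, inhibitor sensitivity),
    or ``None`` for substrate-free roles.
    """

    id: str
    role: str
    bounds: Tuple[float, float]
    target_substrate: Optional[str] = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise StructureError(f"unknown gene-slot role {self.role!r}")
        lo, hi = self.bounds
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
            raise StructureError(f"gene slot {self.id!r}: empty bounds {self.bounds}")

    def contains(self, value: float) -> bool:
        lo, hi = self.bounds
        return lo <= value <= hi


@dataclass
class TrophicStructure:
    """Gene-network structure of one species (its trophic identity).

    Two populations belong to the same species iff their structures are equal
    up to the species label — same slots, trophic links and strategies —
    regardless of allele values or frequencies.
    """

    species_id: str
    consumed: frozenset = frozenset()
    produced: Dict[str, bool] = field(default_factory=dict)  # substrate -> secreted?
    activators: frozenset = frozenset()
    inhibitors: frozenset = frozenset()
    reproduction_strategy: str = "non-compensatory"
    gene_slots: Tuple[GeneSlot, ...] = ()

    def __post_init__(self):
        self.consumed = frozenset(self.consumed)
        self.activators = frozenset(self.activators)
        self.inhibitors = frozenset(self.inhibitors)
        self.gene_slots = tuple(self.gene_slots)
        if self.reproduction_strategy not in ("compensatory", "non-compensatory"):
            raise StructureError(
                f"{self.species_id}: unknown reproduction strategy "
                f"{self.reproduction_strategy!r}"
            )
        if self.activators & self.inhibitors:
            raise StructureError(
                f"{self.species_id}: activators and inhibitors overlap: "
                f"{sorted(self.activators & self.inhibitors)}"
            )
        ids = [s.id for s in self.gene_slots]
        if len(ids) != len(set(ids)):
            raise StructureError(f"{self.species_id}: duplicate gene-slot ids")
        known = self.consumed | set(self.produced) | self.activators | self.inhibitors
        for slot in self.gene_slots:
            if slot.target_substrate is not None and slot.target_substrate not in known:
                raise StructureError(
                    f"{self.species_id}: slot {slot.id!r} targets unknown substrate "
                    f"{slot.target_substrate!r}"
                )

    @property
    def signature(self) -> tuple:
        """Structure identity, excluding the species label and allele state."""
        return (
            tuple(sorted(self.consumed)),
            tuple(sorted(self.produced.items())),
            tuple(sorted(self.activators)),
            tuple(sorted(self.inhibitors)),
            self.reproduction_strategy,
            tuple(
                (s.id, s.role, s.target_substrate, s.bounds) for s in self.gene_slots
            ),
        )

    def slot_index(self, slot) -> int:
        sid = slot.id if isinstance(slot, GeneSlot) else slot
        for i, s in enumerate(self.gene_slots):
            if s.id == sid:
                return i
        raise StructureError(f"{self.species_id}: no gene slot {sid!r}")

    def slot(self, slot_id: str) -> GeneSlot:
        return self.gene_slots[self.slot_index(slot_id)]


@dataclass
class AlleleDistribution:
    """Finite per-gene allele distribution (one marginal of the generalized genome)."""

    gene_slot: str
    support: List[float] = field(default_factory=list)
    weights: List[float] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.support

    def as_dict(self) -> Dict[float, float]:
        return dict(zip(self.support, self.weights))

    def modal_value(self) -> float:
        """Most frequent allele; ties broken toward the smaller value."""
        if self.empty:
            raise DomainError(f"empty allele distribution for {self.gene_slot!r}")
        best = max(zip(self.support, self.weights), key=lambda vw: (vw[1], -vw[0]))
        return best[0]


@dataclass
class Cohort:
    """Cells of one allelic combination at one node: the unit of selection."""

    combination: Combination
    count: float

    def __post_init__(self):
        if self.count < 0:
            raise DomainError(f"negative cohort count {self.count}")


@dataclass
class Population:
    """A polymorphic population: structure + per-node cohorts over combinations.

    ``cohorts_by_node`` maps a flat node index to ``{combination: count}``.
    ``params`` holds the species-level reproduction parameters
    (:class:`evogrid.dynamics.ReproductionParams`); it is optional for purely
    genomic manipulation.
    """

    structure: TrophicStructure
    params: object = None
    cohorts_by_node: Dict[int, CohortMap] = field(default_factory=dict)

    @property
    def species_id(self) -> str:
        return self.structure.species_id

    def node_count(self, node: int) -> float:
        return sum(self.cohorts_by_node.get(node, {}).values())

    def total_count(self) -> float:
        return sum(sum(c.values()) for c in self.cohorts_by_node.values())

    def cohorts(self, node: int) -> List[Cohort]:
        return [
            Cohort(combo, n) for combo, n in self.cohorts_by_node.get(node, {}).items()
        ]


# ---------------------------------------------------------------------------
# operations


def mutate_allele(
    value: float,
    slot: GeneSlot,
    beta_a: float = 2.0,
    beta_b: float = 2.0,
    rng=None,
) -> float:
    """Draw a mutated allele value on the slot's bounds via a Beta distribution.

    Returns ``lo + X * (hi - lo)`` with ``X ~ Beta(beta_a, beta_b)``; the draw
    is independent of the current value (the current value only has to be a
    legal allele).  Deterministic given the RNG state/seed.
    """
    if not slot.contains(value):
        raise DomainError(
            f"allele {value} outside bounds {slot.bounds} of slot {slot.id!r}"
        )
    if beta_a <= 0 or beta_b <= 0:
        raise ParameterError(f"beta shapes must be positive, got ({beta_a}, {beta_b})")
    lo, hi = slot.bounds
    x = _as_rng(rng).beta(beta_a, beta_b)
    return lo + x * (hi - lo)


def marginal_allele_frequencies(
    pop: Population, slot, node: Optional[int] = None
) -> AlleleDistribution:
    """Cohort-count-weighted marginal allele distribution of one gene slot.

    ``node=None`` aggregates over the whole habitat.  An empty population
    yields the empty-distribution sentinel (no support points).
    """
    idx = pop.structure.slot_index(slot)
    slot_id = pop.structure.gene_slots[idx].id
    acc: Dict[float, float] = {}
    nodes = pop.cohorts_by_node.keys() if node is None else [node]
    for n in nodes:
        for combo, count in pop.cohorts_by_node.get(n, {}).items():
            if count > 0:
                acc[combo[idx]] = acc.get(combo[idx], 0.0) + count
    total = sum(acc.values())
    if total <= 0:
        return AlleleDistribution(gene_slot=slot_id)
    support = sorted(acc)
    return AlleleDistribution(
        gene_slot=slot_id,
        support=support,
        weights=[acc[v] / total for v in support],
    )


def species_identity(a: Population, b: Population) -> bool:
    """True iff the two populations have equal gene-network structures.

    Allele values, frequencies and the species label are ignored: genetic
    polymorphism never separates species; a structural change (extra/missing
    slot or trophic link, different strategy) always does.
    """
    return a.structure.signature == b.structure.signature


def _replace(combo: Combination, idx: int, value: float) -> Combination:
    return combo[:idx] + (value,) + combo[idx + 1 :]


def apply_mutations(
    pop: Population,
    node: int,
    rate: float,
    sites_model: str = "finite",
    rng=None,
    stochastic: bool = False,
    beta_a: float = 2.0,
    beta_b: float = 2.0,
) -> Population:
    """Mutate a fraction ``rate`` of the cells at one node, in place.

    Each mutating cell picks one gene slot uniformly.  Under the finite-sites
    model the new value is drawn from the slot's current marginal distribution
    at the node (the local gene pool), so the support never grows; under the
    infinite-sites model a fresh value is drawn from the Beta law on the slot
    bounds, adding a new support point.  Total cell count at the node is
    conserved exactly.
    """
    if not 0.0 <= rate <= 1.0:
        raise ParameterError(f"mutation rate {rate} outside [0, 1]")
    if sites_model not in ("finite", "infinite"):
        raise ParameterError(f"unknown sites model {sites_model!r}")
    if node not in pop.cohorts_by_node:
        raise IndexError(f"population {pop.species_id} has no node {node}")
    slots = pop.structure.gene_slots
    if rate == 0.0 or not slots:
        return pop
    gen = _as_rng(rng)
    cohorts = pop.cohorts_by_node[node]
    marginals = [marginal_allele_frequencies(pop, s, node) for s in slots]
    moves: CohortMap = {}
    removed: Dict[Combination, float] = {}
    for combo, count in cohorts.items():
        if count <= 0:
            continue
        if stochastic:
            n_mut = int(gen.binomial(int(count), rate))
            if n_mut == 0:
                continue
            per_slot = gen.multinomial(n_mut, [1.0 / len(slots)] * len(slots))
        else:
            n_mut = count * rate
            per_slot = [n_mut / len(slots)] * len(slots)
        removed[combo] = removed.get(combo, 0.0) + float(n_mut)
        for si, m_s in enumerate(per_slot):
            if m_s <= 0:
                continue
            if sites_model == "finite":
                dist = marginals[si]
                if dist.empty:
                    continue
                if stochastic:
                    draws = gen.multinomial(int(m_s), dist.weights)
                    for v, d in zip(dist.support, draws):
                        if d:
                            key = _replace(combo, si, v)
                            moves[key] = moves.get(key, 0.0) + float(d)
                else:
                    for v, w in zip(dist.support, dist.weights):
                        key = _replace(combo, si, v)
                        moves[key] = moves.get(key, 0.0) + m_s * w
            else:  # infinite sites: fresh support points
                n_draws = int(m_s) if stochastic else 1
                for _ in range(n_draws):
                    v = mutate_allele(combo[si], slots[si], beta_a, beta_b, gen)
                    key = _replace(combo, si, v)
                    mass = 1.0 if stochastic else m_s
                    moves[key] = moves.get(key, 0.0) + mass
    for combo, lost in removed.items():
        cohorts[combo] = cohorts[combo] - lost
        if cohorts[combo] <= 0:
            del cohorts[combo]
    for combo, gained in moves.items():
        cohorts[combo] = cohorts.get(combo, 0.0) + gained
    return pop


def _proportional_take(
    cohorts: CohortMap, n_cells: float, stochastic: bool, rng
) -> Dict[Combination, float]:
    """Remove ``n_cells`` from a cohort map proportionally; return what was taken."""
    total = sum(cohorts.values())
    taken: Dict[Combination, float] = {}
    if stochastic:
        combos = [c for c, n in cohorts.items() if n > 0]
        counts = np.array([int(cohorts[c]) for c in combos])
        draw = _as_rng(rng).multivariate_hypergeometric(counts, int(n_cells))
        for combo, d in zip(combos, draw):
            if d:
                taken[combo] = float(d)
    else:
        frac = n_cells / total
        for combo, n in cohorts.items():
            if n > 0:
                taken[combo] = n * frac
    for combo, t in taken.items():
        cohorts[combo] -= t
        if cohorts[combo] <= 0:
            del cohorts[combo]
    return taken


def merge_params_for_transfer(acceptor_params, donor_params, slot: GeneSlot):
    """Extend the acceptor's reproduction parameters with the transferred
    substrate's requirement/weight copied from the donor (the allele itself
    carries the efficiency)."""
    if acceptor_params is None:
        return None
    import copy

    params = copy.deepcopy(acceptor_params)
    target = slot.target_substrate
    if donor_params is not None and target is not None:
        if target in getattr(donor_params, "c", {}):
            params.c[target] = donor_params.c[target]
        if target in getattr(donor_params, "weights", {}):
            params.weights[target] = donor_params.weights[target]
    return params


def horizontal_transfer(
    donor: Population,
    acceptor: Population,
    slot: GeneSlot,
    node: int,
    n_cells: float,
    new_species_id: Optional[str] = None,
    allele_mode: str = "modal",
    rng=None,
    stochastic: bool = False,
) -> Population:
    """Horizontal transfer of one gene slot from donor into acceptor cells.

    ``n_cells`` acceptor cells at ``node`` acquire the donor's slot (appended
    after the acceptor's slots) and leave the acceptor to found a new species
    whose structure is the acceptor's extended with the slot; a
    utilization-efficiency slot also extends the consumed-substrate set.  The
    transferred allele value is the donor's current modal allele at the node
    (``allele_mode="draw"`` samples the donor's marginal instead).  Global cell
    count is conserved: the acceptor loses exactly ``n_cells``.
    """
    d_idx = donor.structure.slot_index(slot)  # raises if absent from donor
    if any(s.id == slot.id for s in acceptor.structure.gene_slots):
        raise StructureError(
            f"slot {slot.id!r} already present in {acceptor.species_id}"
        )
    if n_cells <= 0:
        raise ParameterError(f"n_cells must be positive, got {n_cells}")
    avail = acceptor.node_count(node)
    if n_cells > avail + 1e-9:
        raise InsufficientCellsError(
            f"{acceptor.species_id} holds {avail} cells at node {node}, "
            f"cannot transfer {n_cells}"
        )
    donor_dist = marginal_allele_frequencies(donor, slot, node)
    if donor_dist.empty:
        donor_dist = marginal_allele_frequencies(donor, slot, None)
    if donor_dist.empty:
        raise InsufficientCellsError(
            f"donor {donor.species_id} has no cells carrying slot {slot.id!r}"
        )
    gen = _as_rng(rng)
    if allele_mode == "modal":
        allele = donor_dist.modal_value()
    elif allele_mode == "draw":
        allele = float(gen.choice(donor_dist.support, p=donor_dist.weights))
    else:
        raise ParameterError(f"unknown allele mode {allele_mode!r}")

    consumed = set(acceptor.structure.consumed)
    if slot.role == "utilization-efficiency" and slot.target_substrate:
        consumed.add(slot.target_substrate)
    struct = TrophicStructure(
        species_id=new_species_id or f"{acceptor.species_id}+{slot.id}",
        consumed=frozenset(consumed),
        produced=dict(acceptor.structure.produced),
        activators=acceptor.structure.activators,
        inhibitors=acceptor.structure.inhibitors,
        reproduction_strategy=acceptor.structure.reproduction_strategy,
        gene_slots=acceptor.structure.gene_slots + (slot,),
    )
    taken = _proportional_take(acceptor.cohorts_by_node[node], n_cells, stochastic, gen)
    new_cohorts: CohortMap = {}
    for combo, n in taken.items():
        key = combo + (allele,)
        new_cohorts[key] = new_cohorts.get(key, 0.0) + n
    return Population(
        structure=struct,
        params=merge_params_for_transfer(acceptor.params, donor.params, slot),
        cohorts_by_node={node: new_cohorts},
    )


def gene_loss(
    pop: Population,
    slot,
    node: int,
    n_cells: float,
    new_species_id: Optional[str] = None,
    rng=None,
    stochastic: bool = False,
) -> Population:
    """Loss of one gene slot in ``n_cells`` cells at a node, founding a new species.

    The slot (and the consumed-substrate link that only it served) is removed
    from the structure; removal that would leave no consumable substrate is a
    structure error.  Cell bookkeeping mirrors :func:`horizontal_transfer`.
    """
    idx = pop.structure.slot_index(slot)
    lost_slot = pop.structure.gene_slots[idx]
    if n_cells <= 0:
        raise ParameterError(f"n_cells must be positive, got {n_cells}")
    avail = pop.node_count(node)
    if n_cells > avail + 1e-9:
        raise InsufficientCellsError(
            f"{pop.species_id} holds {avail} cells at node {node}, "
            f"cannot remove {n_cells}"
        )
    consumed = set(pop.structure.consumed)
    remaining = [s for i, s in enumerate(pop.structure.gene_slots) if i != idx]
    if (
        lost_slot.role == "utilization-efficiency"
        and lost_slot.target_substrate in consumed
        and not any(
            s.role == "utilization-efficiency"
            and s.target_substrate == lost_slot.target_substrate
            for s in remaining
        )
    ):
        consumed.discard(lost_slot.target_substrate)
    if not consumed:
        raise StructureError(
            f"removing slot {lost_slot.id!r} would leave {pop.species_id} "
            "with no consumable substrate"
        )
    struct = TrophicStructure(
        species_id=new_species_id or f"{pop.species_id}-{lost_slot.id}",
        consumed=frozenset(consumed),
        produced=dict(pop.structure.produced),
        activators=pop.structure.activators,
        inhibitors=pop.structure.inhibitors,
        reproduction_strategy=pop.structure.reproduction_strategy,
        gene_slots=tuple(remaining),
    )
    taken = _proportional_take(
        pop.cohorts_by_node[node], n_cells, stochastic, _as_rng(rng)
    )
    new_cohorts: CohortMap = {}
    for combo, n in taken.items():
        key = combo[:idx] + combo[idx + 1 :]
        new_cohorts[key] = new_cohorts.get(key, 0.0) + n
    import copy

    params = copy.deepcopy(pop.params) if pop.params is not None else None
    if (
        params is not None
        and lost_slot.target_substrate is not None
        and lost_slot.target_substrate not in consumed
    ):
        params.c.pop(lost_slot.target_substrate, None)
        params.weights.pop(lost_slot.target_substrate, None)
    return Population(
        structure=struct, params=params, cohorts_by_node={node: new_cohorts}
    )
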