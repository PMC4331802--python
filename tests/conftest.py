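import numpy as np
import pytest

from evogrid.dynamics import ReproductionParams
from evogrid.genome import GeneSlot, Population, TrophicStructure
from evogrid.spatial import Habitat


@pytest.fixture
def slot01():
    return GeneSlot(id="g", role="sensitivity", bounds=(0.0, 1.0), target_substrate=None)


def simple_structure(species_id="sp", consumed=("N",), slots=(), **kw):
    return TrophicStructure(
        species_id=species_id,
        consumed=frozenset(consumed),
        gene_slots=tuple(slots),
        **kw,
    )


def simple_population(species_id="sp", consumed=("N",), slots=(), cohorts=None, params=None, **kw):
    struct = simple_structure(species_id, consumed, slots, **kw)
    if params is None:
        params = ReproductionParams(c={s: 1.0 for s in consumed})
    return Population(structure=struct, params=params, cohorts_by_node=cohorts or {})


def one_node_habitat(populations, substrates=None, **kw):
    h = Habitat(dims=(1,), **kw)
    for sub, v in (substrates or {}).items():
        h.nodes[0].substrates[sub] = v
    for pop in populations:
        h.register(pop)
    return h


def random_habitat(rng, stochastic=False):
    """A random small 1D/2D/3D habitat with random cohorts and substrate fields."""
    ndim = rng.integers(1, 4)
    dims = tuple(int(rng.integers(2, 5)) for _ in range(ndim))
    h = Habitat(
        dims=dims,
        flow_mode="perpendicular",
        flow_rate=0.0,
        diffusion_rate=float(rng.uniform(0, 1.0 / (2 * ndim))),
        chemotaxis_rate=float(rng.uniform(0, 1)),
        stochastic=stochastic,
        cell_diffusion=bool(rng.integers(0, 2)),
    )
    subs = [f"S{i}" for i in range(rng.integers(1, 4))]
    for env in h.nodes:
        for s in subs:
            env.substrates[s] = float(rng.uniform(0, 100))
    slot = GeneSlot(id="g", role="sensitivity", bounds=(0.0, 2.0), target_substrate=subs[0])
    struct = TrophicStructure(
        species_id="sp",
        consumed=frozenset(subs[:1]),
        inhibitors=frozenset(subs[1:2]),
        gene_slots=(slot,),
    )
    params = ReproductionParams(c={subs[0]: 1.0})
    cohorts = {}
    for f in range(h.n_nodes):
        node = {}
        for allele in (0.5, 1.5):
            if rng.random() < 0.8:
                count = rng.integers(0, 500) if stochastic else rng.uniform(0, 500)
                if count > 0:
                    node[(float(allele),)] = float(count)
        cohorts[f] = node
    h.register(Population(structure=struct, params=params, cohorts_by_node=cohorts))
    return h
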