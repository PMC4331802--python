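"""Scenario configuration: a versioned, human-readable YAML dialect.

A scenario file fully describes a runnable experiment: lattice geometry,
flow/diffusion/chemotaxis rates, initial substrate fields, species (trophic
links, strategies, gene slots with allele supports and initial frequencies),
mutation settings and the event schedule.  ``read_config(write_config(spec))``
is an identity, field for field.  Validation reports the key path of the first
offending field.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import yaml

from .errors import ConfigError

FORMAT_VERSION = 1

_ROLES = (
    "utilization-efficiency",
    "sensitivity",
    "synthesis-efficiency",
    "reproduction-parameter",
)
_EVENT_TYPES = ("horizontal_transfer", "scale_inflow", "set_inflow")


@dataclass
class GeneSpec:
    """One polymorphic gene: slot definition plus initial allele distribution."""

    id: str
    role: str
    bounds: List[float]
    target: Optional[str] = None
    support: List[float] = field(default_factory=list)
    freqs: List[float] = field(default_factory=list)


@dataclass
class SpeciesSpec:
    id: str
    consumed: List[str] = field(default_factory=list)
    produced: Dict[str, bool] = field(default_factory=dict)
    activators: List[str] = field(default_factory=list)
    inhibitors: List[str] = field(default_factory=list)
    strategy: str = "non-compensatory"
    params: Dict = field(default_factory=dict)
    genes: List[GeneSpec] = field(default_factory=list)
    initial_count: Dict = field(default_factory=dict)  # {"uniform": x} | {"values": [...]}


@dataclass
class ScenarioSpec:
    name: str
    dims: List[int] = field(default_factory=lambda: [10])
    flow_mode: str = "through"
    flow_rate: float = 0.02
    diffusion_rate: float = 0.0
    chemotaxis_rate: float = 0.0
    substeps: int = 1
    stage2_order: List[str] = field(
        default_factory=lambda: ["flow", "diffusion", "chemotaxis"]
    )
    cell_diffusion: bool = False
    stochastic: bool = False
    generations: int = 100
    seeds: List[int] = field(default_factory=lambda: [0])
    record_every: int = 1
    inflow: Dict[str, float] = field(default_factory=dict)
    substrates: Dict[str, Dict] = field(default_factory=dict)
    mutation: Optional[Dict] = None
    species: List[SpeciesSpec] = field(default_factory=list)
    schedule: List[Dict] = field(default_factory=list)
    format_version: int = FORMAT_VERSION

    @property
    def n_nodes(self) -> int:
        n = 1
        for d in self.dims:
            n *= d
        return n


# ---------------------------------------------------------------------------
# validation


def _require(cond: bool, path: str, message: str):
    if not cond:
        raise ConfigError(f"{path}: {message}")


def _check_field_init(path: str, spec: Dict, n_nodes: int):
    _require(isinstance(spec, dict), path, "must be a mapping")
    keys = set(spec)
    _require(
        len(keys & {"uniform", "gradient", "values"}) == 1,
        path,
        "needs exactly one of 'uniform', 'gradient', 'values'",
    )
    if "uniform" in spec:
        _require(float(spec["uniform"]) >= 0, path + ".uniform", "must be >= 0")
    if "gradient" in spec:
        g = spec["gradient"]
        _require(
            isinstance(g, list) and len(g) == 2,
            path + ".gradient",
            "must be [first-node value, last-node value]",
        )
        _require(min(g) >= 0, path + ".gradient", "values must be >= 0")
    if "values" in spec:
        v = spec["values"]
        _require(
            isinstance(v, list) and len(v) == n_nodes,
            path + ".values",
            f"must list one value per node ({n_nodes})",
        )
        _require(min(v) >= 0, path + ".values", "values must be >= 0")


def validate(spec: ScenarioSpec) -> ScenarioSpec:
    """Validate a scenario; raises ConfigError naming the offending key path."""
    _require(
        spec.format_version == FORMAT_VERSION,
        "format_version",
        f"unsupported version {spec.format_version} (expected {FORMAT_VERSION})",
    )
    _require(
        1 <= len(spec.dims) <= 3 and all(d >= 1 for d in spec.dims),
        "dims",
        "must be 1-3 axes of size >= 1",
    )
    _require(
        spec.flow_mode in ("through", "perpendicular"),
        "flow_mode",
        f"unknown mode {spec.flow_mode!r}",
    )
    _require(0.0 <= spec.flow_rate <= 1.0, "flow_rate", "must be in [0, 1]")
    _require(
        0.0 <= spec.chemotaxis_rate <= 1.0, "chemotaxis_rate", "must be in [0, 1]"
    )
    bound = 1.0 / (2.0 * len(spec.dims))
    _require(
        0.0 <= spec.diffusion_rate <= bound,
        "diffusion_rate",
        f"must be in [0, {bound}] for {len(spec.dims)}D",
    )
    _require(spec.generations >= 0, "generations", "must be >= 0")
    _require(spec.substeps >= 1, "substeps", "must be >= 1")
    _require(bool(spec.seeds), "seeds", "must list at least one seed")
    for sub, v in spec.inflow.items():
        _require(v >= 0, f"inflow.{sub}", "must be >= 0")
    for sub, init in spec.substrates.items():
        _check_field_init(f"substrates.{sub}", init, spec.n_nodes)
    if spec.mutation is not None:
        _require(
            0.0 <= spec.mutation.get("rate", 0.0) <= 1.0,
            "mutation.rate",
            "must be in [0, 1]",
        )
        _require(
            spec.mutation.get("sites_model", "finite") in ("finite", "infinite"),
            "mutation.sites_model",
            "must be 'finite' or 'infinite'",
        )

    known_substrates = set(spec.substrates) | set(spec.inflow)
    for sp in spec.species:
        known_substrates |= set(sp.produced)
    seen_ids = set()
    for i, sp in enumerate(spec.species):
        path = f"species[{i}]"
        _require(sp.id not in seen_ids, path + ".id", f"duplicate id {sp.id!r}")
        seen_ids.add(sp.id)
        _require(
            sp.strategy in ("compensatory", "non-compensatory"),
            path + ".strategy",
            f"unknown strategy {sp.strategy!r}",
        )
        _require(bool(sp.consumed), path + ".consumed", "must not be empty")
        for sub in sp.consumed + sp.activators + sp.inhibitors:
            _require(
                sub in known_substrates,
                path,
                f"references unknown substrate {sub!r}",
            )
        _require(
            not set(sp.activators) & set(sp.inhibitors),
            path,
            "activators and inhibitors overlap",
        )
        slot_targets = known_substrates | set(sp.consumed)
        gene_ids = set()
        for j, g in enumerate(sp.genes):
            gpath = f"{path}.genes[{j}]"
            _require(g.id not in gene_ids, gpath + ".id", f"duplicate id {g.id!r}")
            gene_ids.add(g.id)
            _require(g.role in _ROLES, gpath + ".role", f"unknown role {g.role!r}")
            _require(
                isinstance(g.bounds, list) and len(g.bounds) == 2
                and g.bounds[0] <= g.bounds[1],
                gpath + ".bounds",
                "must be [lo, hi] with lo <= hi",
            )
            if g.target is not None:
                _require(
                    g.target in slot_targets,
                    gpath + ".target",
                    f"unknown substrate {g.target!r}",
                )
            _require(bool(g.support), gpath + ".support", "must not be empty")
            _require(
                all(g.bounds[0] <= v <= g.bounds[1] for v in g.support),
                gpath + ".support",
                "values must lie within bounds",
            )
            _require(
                len(g.freqs) == len(g.support),
                gpath + ".freqs",
                "must match support length",
            )
            _require(
                abs(sum(g.freqs) - 1.0) < 1e-9 and min(g.freqs) >= 0,
                gpath + ".freqs",
                "must be non-negative and sum to 1",
            )
        if sp.initial_count:
            _check_field_init(path + ".initial_count", sp.initial_count, spec.n_nodes)
    for k, ev in enumerate(spec.schedule):
        path = f"schedule[{k}]"
        _require(isinstance(ev, dict), path, "must be a mapping")
        _require("generation" in ev, path + ".generation", "is required")
        _require(ev["generation"] >= 0, path + ".generation", "must be >= 0")
        etype = ev.get("type")
        _require(etype in _EVENT_TYPES, path + ".type", f"must be one of {_EVENT_TYPES}")
        if etype == "horizontal_transfer":
            for key in ("node", "donor", "acceptor", "slot", "n_cells"):
                _require(key in ev, f"{path}.{key}", "is required")
            _require(
                0 <= ev["node"] < spec.n_nodes, path + ".node", "outside the lattice"
            )
            _require(
                ev["donor"] in seen_ids, path + ".donor", f"unknown species {ev['donor']!r}"
            )
            _require(
                ev["acceptor"] in seen_ids,
                path + ".acceptor",
                f"unknown species {ev['acceptor']!r}",
            )
        elif etype == "scale_inflow":
            _require("factor" in ev, path + ".factor", "is required")
            _require(ev["factor"] >= 0, path + ".factor", "must be >= 0")
        elif etype == "set_inflow":
            _require("composition" in ev, path + ".composition", "is required")
    gens = [ev["generation"] for ev in spec.schedule]
    _require(
        all(b >= a for a, b in zip(gens, gens[1:])),
        "schedule",
        "event generations must be non-decreasing",
    )
    return spec


# ---------------------------------------------------------------------------
# (de)serialization


def spec_to_dict(spec: ScenarioSpec) -> Dict:
    return asdict(spec)


def spec_from_dict(data: Dict) -> ScenarioSpec:
    if not isinstance(data, dict):
        raise ConfigError("document root: must be a mapping")
    data = dict(data)
    species_raw = data.pop("species", [])
    species = []
    for i, sp in enumerate(species_raw):
        if not isinstance(sp, dict):
            raise ConfigError(f"species[{i}]: must be a mapping")
        sp = dict(sp)
        genes = [GeneSpec(**g) for g in sp.pop("genes", [])]
        try:
            species.append(SpeciesSpec(genes=genes, **sp))
        except TypeError as exc:
            raise ConfigError(f"species[{i}]: {exc}") from exc
    try:
        spec = ScenarioSpec(species=species, **data)
    except TypeError as exc:
        raise ConfigError(f"document root: {exc}") from exc
    return validate(spec)


def write_config(spec: ScenarioSpec, path: str):
    validate(spec)
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def read_config(path: str) -> ScenarioSpec:
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    return spec_from_dict(data)
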