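"""Long-format trajectory records and their tab-separated persistence.

Three tables, one row per observation:

* counts:     (generation, node, species, count)
* substrates: (generation, node, substrate, concentration)
* alleles:    (generation, node, species, gene, allele, frequency)

Floats are written with 12 significant digits; readers round-trip the tables
bit-exactly at that precision.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from . import genome

COUNT_COLS = ["generation", "node", "species", "count"]
SUBSTRATE_COLS = ["generation", "node", "substrate", "concentration"]
ALLELE_COLS = ["generation", "node", "species", "gene", "allele", "frequency"]

_TABLES = {
    "counts": COUNT_COLS,
    "substrates": SUBSTRATE_COLS,
    "alleles": ALLELE_COLS,
}


@dataclass
class Trajectory:
    """Recorded simulation output as three long-format DataFrames."""

    counts: pd.DataFrame
    substrates: pd.DataFrame
    alleles: pd.DataFrame

    def write(self, prefix: str):
        """Write ``<prefix>.counts.tsv`` etc. (three TSV tables)."""
        os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
        for name in _TABLES:
            getattr(self, name).to_csv(
                f"{prefix}.{name}.tsv", sep="\t", index=False, float_format="%.12g"
            )

    @classmethod
    def read(cls, prefix: str) -> "Trajectory":
        frames = {}
        for name, cols in _TABLES.items():
            path = f"{prefix}.{name}.tsv"
            df = pd.read_csv(path, sep="\t")
            frames[name] = df[cols] if len(df) else pd.DataFrame(columns=cols)
        return cls(**frames)

    @property
    def generations(self) -> List[int]:
        return sorted(self.counts["generation"].unique())


class Recorder:
    """Accumulates per-generation rows from a habitat into a Trajectory."""

    def __init__(self, record_every: int = 1, record_alleles: bool = True):
        self.record_every = max(1, int(record_every))
        self.record_alleles = record_alleles
        self._counts: List[tuple] = []
        self._subs: List[tuple] = []
        self._alleles: List[tuple] = []

    def record(self, habitat):
        g = habitat.generation
        if g % self.record_every != 0:
            return
        subs = habitat.substrate_ids()
        for f, env in enumerate(habitat.nodes):
            for sub in subs:
                self._subs.append((g, f, sub, env.substrates.get(sub, 0.0)))
        for sid, pop in habitat.populations.items():
            for f in range(habitat.n_nodes):
                count = sum(pop.cohorts_by_node.get(f, {}).values())
                self._counts.append((g, f, sid, count))
                if not self.record_alleles or count <= 0:
                    continue
                for slot in pop.structure.gene_slots:
                    dist = genome.marginal_allele_frequencies(pop, slot, f)
                    for v, w in zip(dist.support, dist.weights):
                        self._alleles.append((g, f, sid, slot.id, v, w))

    def trajectory(self) -> Trajectory:
        return Trajectory(
            counts=pd.DataFrame(self._counts, columns=COUNT_COLS),
            substrates=pd.DataFrame(self._subs, columns=SUBSTRATE_COLS),
            alleles=pd.DataFrame(self._alleles, columns=ALLELE_COLS),
        )
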