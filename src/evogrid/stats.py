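"""Summary statistics over recorded trajectories.

All statistics are pure functions of the trajectory tables: the same input
always yields the same output.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import pandas as pd

from .trajectory import Trajectory

__all__ = ["diversity_loss_time", "pmax_pmin_ratio", "oscillation_amplitude"]

#: Allele-frequency threshold below which an allele counts as extinct in
#: deterministic runs (stochastic runs hit exact zero).
DETERMINISTIC_EXTINCTION_THRESHOLD = 1e-9


def diversity_loss_time(
    traj: Trajectory,
    species: str,
    node: Optional[int] = None,
    threshold: float = DETERMINISTIC_EXTINCTION_THRESHOLD,
) -> Optional[int]:
    """First generation from which the population stays monomorphic.

    Diversity is lost at a node once, for every polymorphic gene, all allele
    frequencies except one have fallen to (effectively) zero — and remain so
    for the rest of the record; a node where the population is extinct holds
    no diversity by definition.  ``node=None`` aggregates counts and allele
    masses over the whole habitat.  Returns ``None`` (not-lost sentinel) if
    polymorphism persists to the end of the trajectory.
    """
    counts = traj.counts[traj.counts["species"] == species]
    if counts.empty:
        raise KeyError(f"species {species!r} not present in trajectory")
    alleles = traj.alleles[traj.alleles["species"] == species]
    if node is not None:
        counts = counts[counts["node"] == node]
        alleles = alleles[alleles["node"] == node]
        if counts.empty:
            raise KeyError(f"species {species!r} has no records at node {node}")
    gens = sorted(counts["generation"].unique())
    totals = counts.groupby("generation")["count"].sum()
    if alleles.empty:
        return gens[0]
    surviving = {}
    if node is None and len(traj.counts["node"].unique()) > 1:
        # habitat-wide marginal: combine per-node frequencies weighted by counts
        node_counts = counts.set_index(["generation", "node"])["count"]
        mass = alleles.assign(
            mass=alleles["frequency"].values
            * node_counts.reindex(
                pd.MultiIndex.from_frame(alleles[["generation", "node"]])
            ).values
        )
        grouped = mass.groupby(["generation", "gene", "allele"])["mass"].sum()
        freq = grouped / grouped.groupby(["generation", "gene"]).transform("sum")
        per_gen = (
            (freq > threshold)
            .groupby(["generation", "gene"])
            .sum()
            .groupby("generation")
            .max()
        )
    else:
        per_gen = (
            (alleles["frequency"] > threshold)
            .groupby([alleles["generation"], alleles["gene"]])
            .sum()
            .groupby("generation")
            .max()
        )
    loss = None
    for g in reversed(gens):
        extinct = totals.get(g, 0.0) <= 0
        mono = per_gen.get(g, 0) <= 1
        if extinct or mono:
            loss = int(g)
        else:
            break
    return loss


def pmax_pmin_ratio(
    traj: Trajectory,
    window: Tuple[int, int],
    scope: Optional[int] = None,
    species: Optional[list] = None,
) -> float:
    """Ratio of the largest to the smallest species total at the window end.

    Species sizes are habitat-summed (or taken at one node when ``scope`` is a
    node index) at the last recorded generation inside ``window``; ``species``
    optionally restricts the comparison to a subset of the community.  A
    species of size zero yields the infinite-ratio sentinel.  The result is
    >= 1 by construction.
    """
    lo, hi = window
    counts = traj.counts
    if scope is not None:
        counts = counts[counts["node"] == scope]
    if species is not None:
        counts = counts[counts["species"].isin(species)]
    sel = counts[(counts["generation"] >= lo) & (counts["generation"] <= hi)]
    if sel.empty:
        raise ValueError(f"window {window} contains no recorded generations")
    g_end = sel["generation"].max()
    sizes = sel[sel["generation"] == g_end].groupby("species")["count"].sum()
    if (sizes <= 0).any():
        return math.inf
    return float(sizes.max() / sizes.min())


def oscillation_amplitude(
    traj: Trajectory, species: str, node: int, window: Tuple[int, int]
) -> float:
    """Max minus min of a species' count series at one node over a window."""
    lo, hi = window
    counts = traj.counts
    sel = counts[
        (counts["species"] == species)
        & (counts["node"] == node)
        & (counts["generation"] >= lo)
        & (counts["generation"] <= hi)
    ]
    if sel.empty:
        raise ValueError(
            f"window {window} holds no records for {species!r} at node {node}"
        )
    return float(sel["count"].max() - sel["count"].min())
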