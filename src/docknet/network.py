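"""Build the z-thresholded interaction network and summarize its topology."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .docking import DEFAULT_Z_THRESHOLD, DockZ
from .errors import EmptyInputError
from .io_formats import canonical_pair
from .model_qc import percent

__all__ = [
    "InteractionNetwork",
    "DegreeStats",
    "build_network",
    "degree_stats",
    "overlap_with",
]


@dataclass
class InteractionNetwork:
    graph: nx.Graph
    threshold: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> set[tuple[str, str]]:
        return {canonical_pair(u, v) for u, v in self.graph.edges()}


@dataclass
class DegreeStats:
    degrees: dict[str, int]
    mean_degree: float
    mean_degree_reported: int  # rounded to nearest integer, as summarized
    histogram: dict[tuple[int, int], int]  # [lo, hi) bins
    frac_10_30: float  # fraction of nodes with degree in [10, 30] closed


def build_network(
    zscores: Iterable[DockZ],
    threshold: float = DEFAULT_Z_THRESHOLD,
    keep_isolated: bool = False,
) -> InteractionNetwork:
    """Edge for every pair with z >= threshold; no self-loops, no duplicate
    edges. Nodes without a surviving edge are dropped unless
    ``keep_isolated``. Duplicate pair entries with conflicting z raise."""
    seen: dict[tuple[str, str], float] = {}
    g = nx.Graph()
    for rec in zscores:
        if rec.pair is None:
            raise ValueError("DockZ record lacks a pair id")
        pair = canonical_pair(*rec.pair)
        if pair[0] == pair[1]:
            raise ValueError(f"self-pair {pair[0]!r} is not allowed in the network")
        if pair in seen:
            if seen[pair] != rec.z:
                raise ValueError(f"conflicting z for pair {pair}: {seen[pair]} vs {rec.z}")
            continue
        seen[pair] = rec.z
        if keep_isolated:
            g.add_node(pair[0])
            g.add_node(pair[1])
        if rec.z >= threshold:
            g.add_edge(pair[0], pair[1], z=rec.z)
    return InteractionNetwork(graph=g, threshold=threshold)


def degree_stats(net: InteractionNetwork, bin_width: int = 10) -> DegreeStats:
    """Mean degree 2E/N and a [lo, hi) degree histogram.

    The headline '10-30 connections' fraction uses the closed interval
    [10, 30].
    """
    if net.n_nodes == 0:
        raise EmptyInputError("cannot summarize an empty network")
    degrees = {n: d for n, d in net.graph.degree()}
    vals = list(degrees.values())
    assert sum(vals) == 2 * net.n_edges
    mean = 2.0 * net.n_edges / net.n_nodes
    hist: dict[tuple[int, int], int] = {}
    for d in vals:
        lo = (d // bin_width) * bin_width
        key = (lo, lo + bin_width)
        hist[key] = hist.get(key, 0) + 1
    frac = sum(1 for d in vals if 10 <= d <= 30) / len(vals)
    return DegreeStats(
        degrees=degrees,
        mean_degree=mean,
        mean_degree_reported=int(math.floor(mean + 0.5)),
        histogram=dict(sorted(hist.items())),
        frac_10_30=frac,
    )


def overlap_with(
    net: InteractionNetwork,
    other_edge_sets: Mapping[str, Iterable[tuple[str, str]]],
):
    """Overlap of network edges with named external edge sets.

    Returns per-set counts, the union count, and the union fraction of
    network edges as a one-decimal percent.
    """
    own = net.edges()
    per_set: dict[str, int] = {}
    union: set[tuple[str, str]] = set()
    for name, pairs in other_edge_sets.items():
        canon = {canonical_pair(*p) for p in pairs}
        per_set[name] = len(own & canon)
        union |= own & canon
    frac_pct = percent(len(union), len(own)) if own else 0.0
    return {"per_set": per_set, "union_count": len(union), "union_percent": frac_pct}
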