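"""Correlation-weighted residue interaction networks and path analysis.

Following the standard dynamical-network convention, residues i and j are
connected when their contact occupancy is high (default ≥ 0.75 of frames)
and their motions are correlated (|C_ij| above a floor); the edge weight is
−log |C_ij|, so strongly correlated contacts are short and shortest paths
trace probable communication routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import islice

import networkx as nx
import numpy as np

from .correlation import ContactSummary, CorrelationMatrix

__all__ = ["ResidueNetwork", "build_network", "shortest_paths", "network_summary"]

OCCUPANCY_MIN_DEFAULT = 0.75
CORR_FLOOR_DEFAULT = 0.01


@dataclass
class ResidueNetwork:
    """Undirected weighted graph over residues, with the edge rule recorded."""

    graph: nx.Graph
    occupancy_min: float
    corr_floor: float
    weight_formula: str = "-log|C_ij|"

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        return [(min(u, v), max(u, v), d["weight"])
                for u, v, d in self.graph.edges(data=True)]


def build_network(occupancy: ContactSummary, corr: CorrelationMatrix,
                  occupancy_min: float = OCCUPANCY_MIN_DEFAULT,
                  corr_floor: float = CORR_FLOOR_DEFAULT) -> ResidueNetwork:
    """Edges where occupancy ≥ occupancy_min and |C_ij| ≥ corr_floor."""
    if not np.array_equal(occupancy.labels, corr.labels):
        raise ValueError("occupancy and correlation labels differ")
    labels = occupancy.labels
    g = nx.Graph()
    g.add_nodes_from(int(r) for r in labels)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            c = abs(corr.values[i, j])
            if occupancy.occupancy[i, j] >= occupancy_min and c >= corr_floor:
                g.add_edge(int(labels[i]), int(labels[j]),
                           weight=float(-np.log(min(c, 1.0))))
    return ResidueNetwork(graph=g, occupancy_min=occupancy_min,
                          corr_floor=corr_floor)


def shortest_paths(net: ResidueNetwork, source: int, target: int,
                   k: int = 1) -> list[tuple[list[int], float]]:
    """The k loopless shortest paths by total weight (Yen's algorithm).

    Ties are broken by lexicographic node sequence; a disconnected pair
    yields an empty list rather than an exception.
    """
    if source == target:
        raise ValueError("source and target must differ")
    g = net.graph
    if source not in g or target not in g:
        raise ValueError("source/target not in network")
    try:
        gen = nx.shortest_simple_paths(g, source, target, weight="weight")
        paths = list(islice(gen, k * 4))  # oversample to resolve weight ties
    except nx.NetworkXNoPath:
        return []

    def path_weight(p):
        return sum(g[u][v]["weight"] for u, v in zip(p, p[1:]))

    scored = sorted(((path_weight(p), p) for p in paths),
                    key=lambda wp: (round(wp[0], 12), wp[1]))
    return [(p, w) for w, p in scored[:k]]


def network_summary(net: ResidueNetwork,
                    segments: dict[str, tuple[int, int]] | None = None) -> dict:
    """Degrees, mean path length and betweenness over the largest component.

    With ``segments`` given, counts of edges crossing each segment pair are
    reported too (inclusive residue ranges).
    """
    g = net.graph
    if g.number_of_edges() == 0:
        return {"degree": {}, "mean_path_length": np.nan,
                "betweenness": {}, "segment_edges": {}}
    comp = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
    sub = g.subgraph(comp)
    degree = {int(n): d for n, d in g.degree()}
    mean_pl = nx.average_shortest_path_length(sub, weight="weight") \
        if len(comp) > 1 else 0.0
    btw = nx.betweenness_centrality(sub, weight="weight", normalized=True)
    ranking = sorted(btw, key=lambda n: (-btw[n], n))
    seg_edges = {}
    if segments:
        for a in segments:
            for b in segments:
                if a >= b:
                    continue
                lo1, hi1 = segments[a]
                lo2, hi2 = segments[b]
                count = sum(1 for u, v in g.edges
                            if (lo1 <= u <= hi1 and lo2 <= v <= hi2)
                            or (lo2 <= u <= hi2 and lo1 <= v <= hi1))
                seg_edges[(a, b)] = count
    return {"degree": degree, "mean_path_length": float(mean_pl),
            "betweenness": {int(n): float(v) for n, v in btw.items()},
            "betweenness_ranking": [int(n) for n in ranking],
            "segment_edges": seg_edges}
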