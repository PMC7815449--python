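"""Descriptive statistics of a recommendation network.

Conventions: crawled networks can be disconnected after cleaning, so the
diameter is taken over the largest connected component; nodes of degree < 2
contribute a local clustering coefficient of 0 to the average (the common
implementation convention), with a flag to restrict the average to degree
>= 2 nodes instead.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import networkx as nx

from .graph_core import RecNetwork

__all__ = [
    "GlobalStats",
    "average_degree",
    "diameter",
    "average_clustering",
    "compute_global_stats",
]


@dataclass(frozen=True)
class GlobalStats:
    n_nodes: int
    n_edges: int
    average_degree: float
    diameter: int
    average_clustering: float

    def to_dict(self) -> dict:
        return asdict(self)


def average_degree(network: RecNetwork) -> float:
    """Mean degree 2E/N of a simple undirected graph, unrounded."""
    n = network.n_nodes
    if n == 0:
        raise ValueError("average degree undefined for an empty network")
    return 2.0 * network.n_edges / n


def diameter(network: RecNetwork) -> int:
    """Maximum finite shortest-path length (largest component if disconnected).

    0 for edgeless graphs and single nodes.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("diameter undefined for an empty network")
    if g.number_of_edges() == 0:
        return 0
    giant = max(nx.connected_components(g), key=len)
    return int(nx.diameter(g.subgraph(giant)))


def average_clustering(network: RecNetwork, *, count_low_degree: bool = True) -> float:
    """Mean local clustering coefficient.

    With ``count_low_degree`` (default), nodes of degree < 2 contribute 0;
    otherwise the mean runs over degree >= 2 nodes only.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(g, count_zeros=count_low_degree))


def compute_global_stats(network: RecNetwork) -> GlobalStats:
    return GlobalStats(
        n_nodes=network.n_nodes,
        n_edges=network.n_edges,
        average_degree=average_degree(network),
        diameter=diameter(network),
        average_clustering=average_clustering(network),
    )
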