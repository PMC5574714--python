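"""Protein-interaction network connectivity and essentiality enrichment.

Degree centrality (number of interaction partners) quantifies how embedded a
protein such as EF-Tu is in the cellular interaction network; the first-
neighbor subnetwork and a one-sided hypergeometric test then ask whether its
interaction partners are enriched in essential proteins relative to the whole
interactome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from scipy import stats

__all__ = [
    "NetworkError",
    "Interactome",
    "CentralityReport",
    "EnrichmentResult",
    "degree_centrality",
    "neighbor_subnetwork",
    "essentiality_enrichment",
]


class NetworkError(ValueError):
    """Raised for invalid interactome input or queries."""


@dataclass
class Interactome:
    """Simple undirected protein graph with per-node essentiality flags.

    Duplicate edges and self-loops in the input are dropped (counted in
    ``n_dropped``): interactions are treated as an unweighted simple graph.
    """

    graph: nx.Graph
    n_dropped: int = 0

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str]],
        essential: dict[str, bool] | None = None,
        extra_nodes: list[str] | None = None,
    ) -> "Interactome":
        g = nx.Graph()
        dropped = 0
        for u, v in edges:
            if u == v or g.has_edge(u, v):
                dropped += 1
                continue
            g.add_edge(u, v)
        for node in extra_nodes or []:
            g.add_node(node)
        essential = essential or {}
        for node in g.nodes:
            g.nodes[node]["essential"] = bool(essential.get(node, False))
        return cls(graph=g, n_dropped=dropped)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def is_essential(self, node: str) -> bool:
        return bool(self.graph.nodes[node].get("essential", False))

    def essential_nodes(self) -> set[str]:
        return {n for n in self.graph.nodes if self.is_essential(n)}


@dataclass
class CentralityReport:
    degree: dict[str, int]
    mean_degree: float
    ranking: list[str] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    p_value: float
    overlap: int          # essential nodes in the sample
    sample_size: int
    category_size: int    # essential nodes in the universe
    universe_size: int


def degree_centrality(net: Interactome) -> CentralityReport:
    """Exact degree of every node, the network mean, and a deterministic ranking.

    Ranking is by degree descending, ties broken lexicographically by node id.
    """
    if net.graph.number_of_nodes() == 0:
        raise NetworkError("empty network")
    degree = {n: int(d) for n, d in net.graph.degree()}
    mean = sum(degree.values()) / len(degree)
    ranking = sorted(degree, key=lambda n: (-degree[n], n))
    return CentralityReport(degree=degree, mean_degree=mean, ranking=ranking)


def neighbor_subnetwork(net: Interactome, node: str) -> Interactome:
    """Induced subgraph on a node plus its first neighbors, flags preserved."""
    if node not in net.graph:
        raise NetworkError(f"node {node!r} not in network")
    keep = set(net.graph.neighbors(node)) | {node}
    sub = net.graph.subgraph(keep).copy()
    return Interactome(graph=sub)


def essentiality_enrichment(sample_nodes: list[str] | set[str], net: Interactome) -> EnrichmentResult:
    """One-sided hypergeometric (Fisher upper-tail) enrichment of essential proteins.

    P(X >= overlap) when drawing ``len(sample_nodes)`` proteins without
    replacement from the whole interactome, of which ``category_size`` are
    essential.  The survival function is evaluated in log space internally by
    scipy, so P-values at the 1e-21 scale are representable.
    """
    sample = set(sample_nodes)
    if not sample:
        raise NetworkError("empty sample")
    universe = set(net.graph.nodes)
    missing = sample - universe
    if missing:
        raise NetworkError(f"sample nodes not in network: {sorted(missing)[:5]}")
    essential = net.essential_nodes()
    overlap = len(sample & essential)
    M, n, N = len(universe), len(essential), len(sample)
    # upper tail including the observed overlap
    p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(
        p_value=p,
        overlap=overlap,
        sample_size=N,
        category_size=n,
        universe_size=M,
    )
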