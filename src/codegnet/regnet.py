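"""Upstream-regulator network inference (Expression2Kinases-style).

Starting from a differential signature: (1) transcription factors are ranked
by combined enrichment score of their target sets; (2) the top TFs are
connected through a background PPI by adding every protein lying on a
shortest path of length <= ``max_path_length`` between two TFs
(Genes2Networks expansion); (3) kinases whose substrate sets are enriched in
the resulting subnetwork are attached with phosphorylation edges. Hubs are
the nodes with the highest k-core, ties broken by betweenness then degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .data_io import GeneSetLibrary, PPINetwork
from .enrichment import EnrichmentRow, NullRankModel, enrich

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryNetwork",
    "top_regulators",
    "g2n_expand",
    "kinase_enrich_and_attach",
    "betweenness",
    "kcore",
    "compute_hub_table",
    "select_hubs",
    "write_network_sif",
    "write_network_graphml",
]

ROLE_TF = "tf"
ROLE_INTERMEDIATE = "intermediate"
ROLE_KINASE = "kinase"
EDGE_PPI = "ppi"
EDGE_PHOSPHO = "phosphorylation"


@dataclass
class RegulatoryNetwork:
    """Typed graph of TFs, intermediate proteins and kinases.

    ``nodes`` maps each symbol to its role; ``edge_kinds`` maps each
    unordered pair (stored with a < b) to ``ppi`` or ``phosphorylation``.
    The graph is simple; edge kinds are ignored for centrality metrics.
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edge_kinds: dict[tuple[str, str], str] = field(default_factory=dict)
    provenance: str = ""

    @property
    def edges(self) -> set[tuple[str, str, str]]:
        return {(a, b, kind) for (a, b), kind in self.edge_kinds.items()}

    def add_edge(self, a: str, b: str, kind: str) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        self.edge_kinds.setdefault(key, kind)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in sorted(self.nodes):
            g.add_node(node, role=self.nodes[node])
        for (a, b) in sorted(self.edge_kinds):
            g.add_edge(a, b, kind=self.edge_kinds[(a, b)])
        return g

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(dict(self.nodes), dict(self.edge_kinds), self.provenance)


def top_regulators(enrichment: list[EnrichmentRow], n: int = 10) -> list[str]:
    """First ``n`` term symbols by combined score descending, ties by symbol."""
    if n < 1:
        raise ValueError(f"n must be >=1, got {n}")
    ordered = sorted(enrichment, key=lambda r: (-r.combined_score, r.term_id))
    return [r.term_id for r in ordered[:n]]


def g2n_expand(
    seeds: list[str], ppi: PPINetwork, max_path_length: int = 2, provenance: str = ""
) -> RegulatoryNetwork:
    """Genes2Networks expansion of seed TFs through a background PPI.

    The subnetwork consists of the seeds plus every non-seed protein lying on
    any shortest path of length <= ``max_path_length`` between two distinct
    seeds; edges are those of the PPI induced on the selected nodes. Seeds
    absent from the PPI are kept as isolated TF nodes.
    """
    if not seeds:
        raise ValueError("seeds must be non-empty")
    if max_path_length not in (1, 2, 3):
        raise ValueError(f"max_path_length must be 1, 2 or 3, got {max_path_length}")
    seed_set = {s.upper() for s in seeds}
    g = ppi.to_networkx()
    selected = set(seed_set)
    present = [s for s in sorted(seed_set) if s in g]
    for s, t in combinations(present, 2):
        try:
            length = nx.shortest_path_length(g, s, t)
        except nx.NetworkXNoPath:
            continue
        if length <= max_path_length:
            for path in nx.all_shortest_paths(g, s, t):
                selected.update(path)

    net = RegulatoryNetwork(provenance=provenance)
    for node in sorted(selected):
        net.nodes[node] = ROLE_TF if node in seed_set else ROLE_INTERMEDIATE
    sub = g.subgraph(selected & set(g.nodes))
    for a, b in sorted(sub.edges):
        net.add_edge(a, b, EDGE_PPI)
    return net


def kinase_enrich_and_attach(
    network: RegulatoryNetwork,
    kinase_library: GeneSetLibrary,
    universe: set[str] | frozenset[str],
    null_model: NullRankModel | None = None,
    n: int = 10,
) -> tuple[RegulatoryNetwork, list[EnrichmentRow]]:
    """Kinase enrichment over the network's proteins, top kinases attached.

    The network node symbols form the query; the top ``n`` kinases by
    combined score are added as kinase nodes with phosphorylation edges to
    their substrates already present in the network. Returns the augmented
    network (a copy) and the full kinase enrichment table.
    """
    if not network.nodes:
        raise ValueError("network has no nodes")
    if len(kinase_library) == 0:
        raise ValueError("kinase library is empty")
    query = set(network.nodes)
    uni = frozenset(universe) | query  # network proteins are part of the measured space
    rows = enrich(query, kinase_library, uni, null_model)
    if not rows:
        logger.warning("no kinase substrate set overlaps the network; network unchanged")
        return network.copy(), []

    out = network.copy()
    substrates_pool = set(network.nodes)
    for kin in top_regulators(rows, n):
        out.nodes[kin] = ROLE_KINASE  # upgrades role if the kinase was already a node
        for sub in sorted(kinase_library.terms[kin] & substrates_pool - {kin}):
            out.add_edge(kin, sub, EDGE_PHOSPHO)
    return out, rows


def betweenness(network: RegulatoryNetwork | nx.Graph) -> dict[str, float]:
    """Unnormalised betweenness: for each node N, the sum over unordered node
    pairs (excluding N) of the fraction of shortest paths through N.
    Disconnected pairs contribute zero; edge kinds are ignored."""
    g = network.to_networkx() if isinstance(network, RegulatoryNetwork) else network
    return {n: float(v) for n, v in nx.betweenness_centrality(g, normalized=False).items()}


def kcore(network: RegulatoryNetwork | nx.Graph) -> dict[str, int]:
    """Core number per node: the largest k such that the node belongs to a
    maximal subgraph of minimum degree k."""
    g = network.to_networkx() if isinstance(network, RegulatoryNetwork) else network
    return {n: int(v) for n, v in nx.core_number(g).items()}


def compute_hub_table(network: RegulatoryNetwork) -> pd.DataFrame:
    """Per-node degree, betweenness, core number; ``is_hub`` initialised False."""
    g = network.to_networkx()
    btw = betweenness(g)
    cores = kcore(g)
    rows = [
        {
            "node": n,
            "role": network.nodes[n],
            "degree": g.degree[n],
            "betweenness": btw[n],
            "kcore": cores[n],
            "is_hub": False,
        }
        for n in sorted(network.nodes)
    ]
    return pd.DataFrame(rows, columns=["node", "role", "degree", "betweenness", "kcore", "is_hub"])


def select_hubs(hub_table: pd.DataFrame, top_k: int) -> list[str]:
    """Mark and return the ``top_k`` hubs.

    Ranking: k-core descending, then betweenness descending, then degree
    descending, then symbol ascending. ``is_hub`` is set in place.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >=1, got {top_k}")
    order = hub_table.sort_values(
        ["kcore", "betweenness", "degree", "node"],
        ascending=[False, False, False, True],
        kind="mergesort",
    )
    hubs = list(order["node"].head(top_k))
    hub_table["is_hub"] = hub_table["node"].isin(hubs)
    return hubs


def write_network_sif(network: RegulatoryNetwork, path) -> None:
    with open(path, "w") as fh:
        covered = set()
        for (a, b) in sorted(network.edge_kinds):
            rel = "pp" if network.edge_kinds[(a, b)] == EDGE_PPI else "ph"
            fh.write(f"{a}\t{rel}\t{b}\n")
            covered.update((a, b))
        for n in sorted(set(network.nodes) - covered):
            fh.write(f"{n}\n")


def write_network_graphml(network: RegulatoryNetwork, path) -> None:
    nx.write_graphml(network.to_networkx(), path)
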