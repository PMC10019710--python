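"""Seed-plus-first-neighbor PPI subnetworks and hub-gene ranking.

Builds an undirected simple graph from a reference interactome edge list,
extracts the induced subgraph on a seed gene set plus its first neighbors,
computes degree and unnormalized betweenness centrality (Brandes), and ranks
hub genes by degree then betweenness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

SEED = "seed"
CONNECTOR = "connector"


@dataclass
class PPINetwork:
    """Undirected gene graph with node roles and centrality scores."""

    graph: nx.Graph
    roles: dict[str, str] = field(default_factory=dict)     # node -> seed|connector
    degree: dict[str, int] = field(default_factory=dict)
    betweenness: dict[str, float] = field(default_factory=dict)

    @property
    def n_seeds(self) -> int:
        return sum(1 for r in self.roles.values() if r == SEED)

    @property
    def n_connectors(self) -> int:
        return sum(1 for r in self.roles.values() if r == CONNECTOR)

    def node_table(self) -> pd.DataFrame:
        nodes = sorted(self.graph.nodes)
        return pd.DataFrame(
            {
                "gene": nodes,
                "role": [self.roles.get(n, CONNECTOR) for n in nodes],
                "degree": [self.degree.get(n, self.graph.degree(n)) for n in nodes],
                "betweenness": [self.betweenness.get(n, float("nan")) for n in nodes],
            }
        )


def load_interactome(edge_list_path: str | Path) -> nx.Graph:
    """Read a reference interactome from a two-column TSV of gene symbols.

    Self-loops and duplicate edges are dropped (counts logged); symbols are
    upper-cased and stripped.
    """
    path = Path(edge_list_path)
    if not path.exists():
        raise FileNotFoundError(path)
    graph = nx.Graph()
    n_self = n_dup = 0
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                continue
            a, b = parts[0].strip().upper(), parts[1].strip().upper()
            if a == b:
                n_self += 1
                continue
            if graph.has_edge(a, b):
                n_dup += 1
                continue
            graph.add_edge(a, b)
    if graph.number_of_edges() == 0:
        raise ValueError(f"{path}: no usable edges")
    if n_self or n_dup:
        logger.info("%s: dropped %d self-loop(s), %d duplicate edge(s)",
                    path.name, n_self, n_dup)
    return graph


def seed_subnetwork(reference: nx.Graph, seeds: list[str]) -> PPINetwork:
    """Induced subgraph on the seeds plus their first neighbors.

    Seeds absent from the reference, or with no interactions, are excluded
    and logged; with no seed found at all a ValueError lists the misses.
    """
    seeds = [s.strip().upper() for s in seeds]
    present = [s for s in seeds if s in reference and reference.degree(s) > 0]
    missing = sorted(set(seeds) - set(present))
    if not present:
        raise ValueError(f"no seed found in the reference interactome: {missing}")
    if missing:
        logger.info("seeds absent or isolated in reference: %s", missing)
    nodes = set(present)
    for s in present:
        nodes.update(reference.neighbors(s))
    sub = reference.subgraph(nodes).copy()
    roles = {n: (SEED if n in set(present) else CONNECTOR) for n in sub.nodes}
    return PPINetwork(graph=sub, roles=roles)


def centrality(network: PPINetwork, normalized: bool = False) -> PPINetwork:
    """Fill degree and betweenness (Brandes) for every node.

    Betweenness is unnormalized by default: the sum over unordered node pairs
    (excluding the endpoints) of the fraction of shortest paths through the
    node — matching the raw counts conventionally reported for PPI hubs.
    """
    network.degree = {n: int(d) for n, d in network.graph.degree()}
    network.betweenness = nx.betweenness_centrality(
        network.graph, normalized=normalized
    )
    return network


def rank_hubs(
    network: PPINetwork, top_k: int = 10, seeds_only: bool = False
) -> pd.DataFrame:
    """Top hub genes by degree desc, ties by betweenness desc, then name.

    ``seeds_only`` restricts the ranking to seed nodes.  Requesting more hubs
    than there are nodes returns all of them (logged).
    """
    if not network.degree or not network.betweenness:
        network = centrality(network)
    nodes = [
        n for n in network.graph.nodes
        if not seeds_only or network.roles.get(n) == SEED
    ]
    ranked = sorted(
        nodes,
        key=lambda n: (-network.degree[n], -network.betweenness[n], n),
    )
    if top_k > len(ranked):
        logger.info("top_k=%d exceeds %d node(s); returning all", top_k, len(ranked))
    ranked = ranked[:top_k]
    return pd.DataFrame(
        {
            "gene": ranked,
            "role": [network.roles.get(n, CONNECTOR) for n in ranked],
            "degree": [network.degree[n] for n in ranked],
            "betweenness": [network.betweenness[n] for n in ranked],
        }
    )


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")
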