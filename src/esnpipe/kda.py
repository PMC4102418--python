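"""Key-driver analysis on directed gene networks.

A key driver of a gene set is a network gene whose neighborhood contains
significantly more set members than expected for a random gene (one-sided
Fisher exact test, Bonferroni-corrected over the genes tested in that
network). Drivers found across several networks are ranked by
(N - 0.99) * mean(-log10 p), which strongly favors genes replicating in at
least two networks. A separate utility scores the enrichment of an
arbitrary query gene list among the depth-limited network neighbors of a
seed gene list (used for perturbation-experiment validation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

KDA_ALPHA = 0.05
DEPTH_DEFAULT = 1
DIRECTION_DEFAULT = "undirected"
ENRICH_DEPTH_DEFAULT = 2


def load_network(edges: pd.DataFrame, network_id: str = "net",
                 require_dag: bool = False) -> nx.DiGraph:
    """Build a DiGraph from a (source, target) edge table.

    Self-loops are dropped and duplicate edges collapse. With
    ``require_dag=True`` (Bayesian-network imports) a cycle is an error.
    """
    graph = nx.DiGraph(network_id=network_id)
    for s, t in zip(edges["source"], edges["target"]):
        if s != t:
            graph.add_edge(s, t)
    if require_dag and not nx.is_directed_acyclic_graph(graph):
        raise ValueError(f"network {network_id!r} is not acyclic")
    return graph


def neighborhood(network: nx.DiGraph, gene: str, depth: int = DEPTH_DEFAULT,
                 direction: str = DIRECTION_DEFAULT) -> set[str]:
    """Genes reachable within ``depth`` edges of ``gene`` (seed excluded)."""
    if gene not in network:
        raise KeyError(f"gene {gene!r} is not in the network")
    if direction == "out":
        graph = network
    elif direction == "in":
        graph = network.reverse(copy=False)
    elif direction == "undirected":
        graph = network.to_undirected(as_view=True)
    else:
        raise ValueError(f"direction must be out/in/undirected, got {direction!r}")
    reached = nx.single_source_shortest_path_length(graph, gene, cutoff=depth)
    return set(reached) - {gene}


def key_driver_test(network: nx.DiGraph, superset_genes, candidate: str,
                    depth: int = DEPTH_DEFAULT,
                    direction: str = DIRECTION_DEFAULT) -> tuple[int, int, float]:
    """(n_neighbors, n_hits, Fisher p) for one candidate gene.

    One-sided hypergeometric upper-tail p for the superset-member count in
    the candidate's neighborhood, with the universe being all other network
    nodes. An empty neighborhood returns p = 1 with a warning.
    """
    nbrs = neighborhood(network, candidate, depth=depth, direction=direction)
    if not nbrs:
        warnings.warn(f"{candidate!r} has an empty neighborhood; p set to 1",
                      stacklevel=2)
        return 0, 0, 1.0
    universe = set(network.nodes) - {candidate}
    in_set = set(superset_genes) & universe
    hits = len(nbrs & in_set)
    p = float(stats.hypergeom.sf(hits - 1, len(universe), len(in_set), len(nbrs)))
    return len(nbrs), hits, p


def find_key_drivers(network: nx.DiGraph, superset_genes,
                     depth: int = DEPTH_DEFAULT,
                     direction: str = DIRECTION_DEFAULT,
                     alpha: float = KDA_ALPHA) -> pd.DataFrame:
    """Test every network gene; Bonferroni over the number of genes tested.

    Returns one row per gene: gene, network, n_neighbors, n_hits, p,
    is_key_driver.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    superset_genes = set(superset_genes)
    network_id = network.graph.get("network_id", "net")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # isolated nodes are expected
        for gene in sorted(network.nodes):
            n_nbrs, hits, p = key_driver_test(
                network, superset_genes, gene, depth=depth, direction=direction)
            rows.append((gene, network_id, n_nbrs, hits, p))
    df = pd.DataFrame(rows, columns=["gene", "network", "n_neighbors", "n_hits", "p"])
    df["is_key_driver"] = df["p"] < alpha / len(df)
    return df


def rank_across_networks(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Cross-network ranking of key drivers.

    For every gene flagged as a key driver in at least one network:
    N = number of such networks, consistency = N - 0.99,
    significance = mean(-log10 p) over those networks, and
    rank_score = consistency * significance. Sorted by descending
    rank_score (gene id breaks ties); invariant to network input order.
    """
    if not results:
        raise ValueError("rank_across_networks needs at least one result table")
    drivers = pd.concat(results, ignore_index=True)
    drivers = drivers[drivers["is_key_driver"]]
    if drivers.empty:
        return pd.DataFrame(columns=["gene", "n_networks", "consistency",
                                     "significance", "rank_score"])
    logp = -np.log10(np.maximum(drivers["p"].to_numpy(dtype=float), 1e-300))
    drivers = drivers.assign(neg_log_p=logp)
    grouped = drivers.groupby("gene").agg(
        n_networks=("network", "nunique"),
        significance=("neg_log_p", "mean"),
    ).reset_index()
    grouped["consistency"] = grouped["n_networks"] - 0.99
    grouped["rank_score"] = grouped["consistency"] * grouped["significance"]
    grouped = grouped.sort_values(["rank_score", "gene"],
                                  ascending=[False, True], kind="stable")
    cols = ["gene", "n_networks", "consistency", "significance", "rank_score"]
    return grouped[cols].reset_index(drop=True)


@dataclass(frozen=True)
class NeighborEnrichment:
    n_neighbors: int
    observed: int
    expected: float
    fold: float
    p: float


def neighbor_set_enrichment(
    networks: list[nx.DiGraph],
    seed_genes,
    query_genes,
    universe_size: int,
    depth: int = ENRICH_DEPTH_DEFAULT,
    direction: str = DIRECTION_DEFAULT,
    min_networks: int = 1,
) -> NeighborEnrichment:
    """Enrichment of ``query_genes`` among the seeds' pooled network neighbors.

    The neighbor pool is the union over networks of the depth-limited
    neighborhoods of all seed genes (a gene must appear in the neighbor set
    of at least ``min_networks`` networks), seeds excluded. Then
    observed = |pool ∩ query|, expected = |pool| * |query| / universe,
    fold = observed / expected, and p is the one-sided hypergeometric
    upper-tail probability.
    """
    seeds = set(seed_genes)
    query = set(query_genes)
    per_network: list[set[str]] = []
    seeds_found = False
    for net in networks:
        present = seeds & set(net.nodes)
        if not present:
            continue
        seeds_found = True
        nbrs: set[str] = set()
        for s in present:
            nbrs |= neighborhood(net, s, depth=depth, direction=direction)
        per_network.append(nbrs - seeds)
    if not seeds_found:
        raise ValueError("no seed gene is present in any network")
    counts: dict[str, int] = {}
    for nbrs in per_network:
        for g in nbrs:
            counts[g] = counts.get(g, 0) + 1
    pool = {g for g, c in counts.items() if c >= min_networks}
    if universe_size < len(pool | query):
        raise ValueError("universe smaller than the union of pool and query")
    observed = len(pool & query)
    expected = len(pool) * len(query) / universe_size
    fold = observed / expected if expected > 0 else 0.0
    p = float(stats.hypergeom.sf(observed - 1, universe_size, len(query), len(pool)))
    return NeighborEnrichment(len(pool), observed, expected, fold, p)


def consensus_edges(networks: list[nx.DiGraph], min_fraction: float = 0.3,
                    min_count: int | None = None) -> set[tuple[str, str]]:
    """Edges present in at least ``min_count`` networks (default: >30%).

    Optional cross-network filter for consensus-network construction or
    visualization; not part of the per-network key-driver statistic.
    """
    if min_count is None:
        min_count = int(np.floor(min_fraction * len(networks))) + 1
    counts: dict[tuple[str, str], int] = {}
    for net in networks:
        for e in net.edges:
            counts[e] = counts.get(e, 0) + 1
    return {e for e, c in counts.items() if c >= min_count}
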