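"""Protein–protein interaction subgraph tests.

Asks whether the proteins coded by a gene set interact with each other more
than expected by chance: the observed edge count of the induced subgraph is
compared with edge counts of random node sets of equal size drawn from the
graph universe (size-matched only; a degree-preserving alternative is
available).  Hub proteins are ranked by induced-subgraph degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from srmtx.exceptions import DegenerateInputError, InvalidConfigError

log = logging.getLogger(__name__)


def load_ppi(edges: pd.DataFrame, universe=None) -> nx.Graph:
    """Build a simple undirected graph from a two-column edge table.

    Self-loops and duplicate edges are removed; when ``universe`` is given,
    genes outside it are dropped and isolated universe genes become
    degree-zero nodes.
    """
    graph = nx.Graph()
    if universe is not None:
        graph.add_nodes_from(universe)
    for a, b in edges.iloc[:, :2].itertuples(index=False):
        if a == b:
            continue
        if universe is not None and (a not in graph or b not in graph):
            continue
        graph.add_edge(a, b)
    return graph


@dataclass
class SubgraphTestResult:
    name: str
    n_input: int
    n_mapped: int
    observed_edges: int
    null_mean: float
    null_sd: float
    p: float
    n_perm: int
    degrees: pd.DataFrame  # gene, degree within induced subgraph


def _induced_degrees(graph: nx.Graph, genes: list[str]) -> pd.DataFrame:
    sub = graph.subgraph(genes)
    rows = sorted(sub.degree, key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["gene", "degree"])


def induced_edge_test(
    graph: nx.Graph,
    gene_set,
    n_perm: int = 10000,
    seed: int = 0,
    universe=None,
    degree_preserving: bool = False,
    name: str = "geneset",
) -> SubgraphTestResult:
    """Edge-count permutation test for the induced subgraph of ``gene_set``.

    Genes absent from the node universe are logged and dropped before size
    matching, so null sets are drawn at the mapped size.  With
    ``degree_preserving`` the null instead bins nodes by degree decile and
    samples within bins.
    """
    nodes = sorted(universe) if universe is not None else sorted(graph.nodes)
    if len(nodes) < 2:
        raise DegenerateInputError("graph universe has fewer than 2 nodes")
    gene_set = sorted(set(gene_set))
    mapped = [g for g in gene_set if g in set(nodes)]
    missing = len(gene_set) - len(mapped)
    if missing:
        log.info("%d genes absent from the PPI universe were dropped", missing)
    if len(mapped) < 2:
        raise DegenerateInputError("fewer than 2 genes map to the PPI universe")

    node_index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in graph.edges:
        ia, ib = node_index.get(a), node_index.get(b)
        if ia is None or ib is None:
            continue
        adj[ia, ib] = adj[ib, ia] = True

    set_idx = np.fromiter((node_index[g] for g in mapped), dtype=np.int64)
    observed = int(adj[np.ix_(set_idx, set_idx)].sum() // 2)

    rng = np.random.default_rng(seed)
    k = len(set_idx)
    null = np.empty(n_perm, dtype=np.int64)
    if degree_preserving:
        degrees = adj.sum(axis=1)
        # decile bins of the degree distribution
        edges_q = np.quantile(degrees, np.linspace(0, 1, 11))
        bins = np.clip(np.searchsorted(edges_q, degrees, side="right") - 1, 0, 9)
        pools = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
        set_bins, set_counts = np.unique(bins[set_idx], return_counts=True)
        for t in range(n_perm):
            pick = np.concatenate(
                [
                    rng.choice(pools[b], size=c, replace=False)
                    for b, c in zip(set_bins, set_counts)
                ]
            )
            null[t] = adj[np.ix_(pick, pick)].sum() // 2
    else:
        for t in range(n_perm):
            pick = rng.choice(n, size=k, replace=False)
            null[t] = adj[np.ix_(pick, pick)].sum() // 2
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return SubgraphTestResult(
        name=name,
        n_input=len(gene_set),
        n_mapped=len(mapped),
        observed_edges=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p=float(p),
        n_perm=n_perm,
        degrees=_induced_degrees(graph, mapped),
    )


def hub_ranking(graph: nx.Graph, gene_set, k: int) -> pd.DataFrame:
    """Top-``k`` genes of the induced subgraph by degree ("hubness").

    Sorted by degree descending, ties broken lexicographically.
    """
    if k < 1:
        raise InvalidConfigError("k must be >= 1")
    genes = sorted(set(gene_set) & set(graph.nodes))
    if not genes:
        raise DegenerateInputError("no genes of the set are present in the graph")
    return _induced_degrees(graph, genes).head(k).reset_index(drop=True)


def connected_component_sizes(graph: nx.Graph, gene_set) -> list[int]:
    """Descriptive only: sizes of induced-subgraph connected components."""
    sub = graph.subgraph(set(gene_set) & set(graph.nodes))
    return sorted((len(c) for c in nx.connected_components(sub)), reverse=True)
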