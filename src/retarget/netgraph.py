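"""Weighted undirected gene-interaction graph: merging, weight imputation
and subgraph induction.

Graphs are :class:`networkx.Graph` objects whose edges carry a
``weight`` attribute; ``None`` marks an edge emitted without a weight
(to be imputed with the mean weight of the subgraph). Merging keeps the
maximum weight for duplicate pairs — union semantics for
high-confidence interactions.
"""

from __future__ import annotations

import networkx as nx

__all__ = ["merge_networks", "impute_unweighted_edges", "induce_subgraph",
           "neighborhood"]


def merge_networks(sources) -> nx.Graph:
    """Union of edge lists / graphs; duplicate pairs keep the max weight.

    Each source is an ``nx.Graph`` or an iterable of (u, v, weight)
    triples (weight may be None). Self-loops are dropped; negative
    weights are an error.
    """
    g = nx.Graph()
    for src in sources:
        if isinstance(src, nx.Graph):
            items = ((u, v, d.get("weight")) for u, v, d in src.edges(data=True))
        else:
            items = src
        for u, v, w in items:
            if u == v:
                continue
            if w is not None and w < 0:
                raise ValueError(f"negative edge weight on ({u}, {v}): {w}")
            if g.has_edge(u, v):
                old = g[u][v]["weight"]
                if w is not None and (old is None or w > old):
                    g[u][v]["weight"] = w
            else:
                g.add_edge(u, v, weight=w)
    return g


def impute_unweighted_edges(g: nx.Graph) -> nx.Graph:
    """Assign every weightless edge the mean of the weighted edges.

    If no edge carries a weight, all weights become 1. Operates on a
    copy; idempotent.
    """
    out = g.copy()
    weights = [d["weight"] for _, _, d in out.edges(data=True)
               if d.get("weight") is not None]
    fill = float(sum(weights) / len(weights)) if weights else 1.0
    for u, v, d in out.edges(data=True):
        if d.get("weight") is None:
            d["weight"] = fill
    return out


def induce_subgraph(g: nx.Graph, genes, include_neighbors: bool = False) -> nx.Graph:
    """Subgraph on ``genes`` (optionally plus their first-hop neighbours).

    Genes absent from ``g`` become isolated nodes of the result.
    """
    genes = set(genes)
    nodes = set(genes)
    if include_neighbors:
        for gn in genes & set(g.nodes):
            nodes.update(g.neighbors(gn))
    sub = nx.Graph()
    sub.add_nodes_from(sorted(nodes, key=str))  # deterministic node order
    present = nodes & set(g.nodes)
    sub.add_edges_from((u, v, d) for u, v, d in g.subgraph(present).edges(data=True))
    return sub


def neighborhood(g: nx.Graph, genes, include_neighbors: bool = True) -> set:
    """The node set: genes present in ``g`` plus (optionally) first neighbours."""
    genes = set(genes) & set(g.nodes)
    out = set(genes)
    if include_neighbors:
        for gn in genes:
            out.update(g.neighbors(gn))
    return out
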