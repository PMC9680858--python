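"""MR-thresholded co-expression graphs and bait-centered functional networks.

A co-expression graph has one node per gene and an undirected edge between
every pair whose Mutual Rank falls strictly below the chosen cutoff
(``mr < cutoff``), mirroring the "MR < 30" style of threshold used for drawn
networks. Two traversals are provided:

* :func:`neighborhood` — genes reachable within a small number of edges of a
  query set (the distance-≤3 single-gene network view),
* :func:`functional_network` — the wider (distance ≤ 10) union neighborhood
  of several bait genes, optionally keyword-filtered on annotation text.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import CoexpressionScores

__all__ = [
    "Neighborhood",
    "build_graph",
    "annotation_text",
    "neighborhood",
    "functional_network",
    "export_graph",
    "import_graph",
]


@dataclasses.dataclass
class Neighborhood:
    """Induced subgraph around a query set with per-node integer distances.

    ``distance[node]`` is the shortest-path edge count from the nearest
    query gene (0 for queries themselves).
    """

    graph: nx.Graph
    distance: dict[str, int]
    query_genes: list[str]


def build_graph(
    scores: CoexpressionScores,
    edge_cutoff: float = 30.0,
    annotations: pd.DataFrame | None = None,
) -> nx.Graph:
    """Build the co-expression graph: edge (A, B) iff MR(A, B) < edge_cutoff.

    Isolated genes are kept as nodes. When an annotation table is given,
    nodes carry a curated ``name`` and a ``kog_category`` (used downstream
    as the node shape class) plus the concatenated annotation text used for
    keyword filtering. Edges store ``mr`` weights.
    """
    if edge_cutoff <= 0:
        raise ValueError("edge_cutoff must be positive")
    g = nx.Graph(edge_cutoff=float(edge_cutoff))
    names: dict[str, str] = {}
    kog: dict[str, str] = {}
    text: dict[str, str] = {}
    if annotations is not None:
        names = (annotations[annotations["namespace"] == "NAME"]
                 .groupby("gene_id")["description"].apply("; ".join).to_dict())
        kog_sub = annotations[annotations["namespace"] == "KOG"]
        kog = kog_sub.groupby("gene_id")["term_id"].first().to_dict()
        text = annotation_text(annotations)
    for gene in scores.gene_ids:
        g.add_node(gene, name=names.get(gene, ""), kog_category=kog.get(gene, ""),
                   annotation_text=text.get(gene, ""))
    mr = scores.mr
    ii, jj = np.nonzero(np.triu(mr < edge_cutoff, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(scores.gene_ids[i], scores.gene_ids[j], mr=float(mr[i, j]))
    return g


def annotation_text(annotations: pd.DataFrame) -> dict[str, str]:
    """Per-gene concatenation of name and all description fields (lowercased)."""
    joined = annotations.groupby("gene_id")["description"].apply(" ".join)
    return {g: t.lower() for g, t in joined.items()}


def neighborhood(g: nx.Graph, query_genes: list[str] | str, max_distance: int = 3) -> Neighborhood:
    """Breadth-first neighborhood of a query set within ``max_distance`` edges.

    The induced subgraph keeps every edge among retained nodes (including
    edges between two nodes at the maximum distance).
    """
    if isinstance(query_genes, str):
        query_genes = [query_genes]
    if max_distance < 0:
        raise ValueError("max_distance must be ≥ 0")
    unknown = [q for q in query_genes if q not in g]
    if unknown:
        raise KeyError(f"query genes absent from graph: {unknown[:5]}")
    if not query_genes:
        raise ValueError("need at least one query gene")
    dist = nx.multi_source_dijkstra_path_length(g, set(query_genes), cutoff=max_distance, weight=None)
    dist = {node: int(d) for node, d in dist.items()}
    sub = g.subgraph(dist).copy()
    return Neighborhood(sub, dist, list(query_genes))


def functional_network(
    g: nx.Graph,
    bait_genes: list[str],
    max_distance: int = 10,
    keywords: list[str] | str | None = None,
    annotations: pd.DataFrame | None = None,
) -> Neighborhood:
    """Union neighborhood of several baits, keyword-filtered on annotations.

    Traversal first, filtering second: distances are computed on the full
    thresholded graph, then non-bait nodes whose annotation text lacks a
    case-insensitive substring match for any keyword are dropped (baits are
    always kept). Multiple keywords combine as OR. Filtering never re-routes
    distances.
    """
    if not bait_genes:
        raise ValueError("need at least one bait gene")
    nb = neighborhood(g, list(bait_genes), max_distance)
    if keywords is None:
        return nb
    if isinstance(keywords, str):
        keywords = [keywords]
    kws = [k.lower() for k in keywords]
    text = annotation_text(annotations) if annotations is not None else {
        n: d.get("annotation_text", "") for n, d in nb.graph.nodes(data=True)
    }
    baits = set(bait_genes)
    keep = [
        node for node in nb.graph.nodes
        if node in baits or any(kw in text.get(node, "") for kw in kws)
    ]
    sub = nb.graph.subgraph(keep).copy()
    dist = {node: nb.distance[node] for node in keep}
    return Neighborhood(sub, dist, list(bait_genes))


def _edge_records(nb: Neighborhood) -> list[dict]:
    return [
        {"gene_a": a, "gene_b": b, "mr": data.get("mr")}
        for a, b, data in sorted(nb.graph.edges(data=True))
    ]


def export_graph(nb: Neighborhood, path, format: str = "graphml") -> None:
    """Write a neighborhood to GraphML, a TSV edge list, or node-link JSON.

    All formats carry node names, KOG category (shape class), distances and
    edge MR weights; GraphML and JSON round-trip losslessly through
    :func:`import_graph`.
    """
    path = Path(path)
    g = nb.graph.copy()
    for node in g.nodes:
        g.nodes[node]["distance"] = int(nb.distance[node])
        g.nodes[node]["is_query"] = node in set(nb.query_genes)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        pd.DataFrame(_edge_records(nb)).to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = nx.node_link_data(g, edges="edges")
        payload["query_genes"] = list(nb.query_genes)
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {format!r} (graphml, edge_tsv or json)")


def import_graph(path, format: str = "graphml") -> Neighborhood:
    """Read a neighborhood written by :func:`export_graph` (graphml or json)."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
        queries = [n for n, d in g.nodes(data=True) if d.get("is_query")]
    elif format == "json":
        payload = json.loads(path.read_text())
        queries = payload.pop("query_genes", [])
        g = nx.node_link_graph(payload, edges="edges")
    else:
        raise ValueError(f"unknown format {format!r} (graphml or json round-trip only)")
    dist = {n: int(d["distance"]) for n, d in g.nodes(data=True)}
    for n in g.nodes:
        g.nodes[n].pop("distance", None)
        g.nodes[n].pop("is_query", None)
    return Neighborhood(g, dist, queries)
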