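"""Thresholded similarity networks, score distributions and subnetworks.

A similarity matrix over input terms (or entities) becomes an association
network by keeping exactly the pairs whose score is *strictly greater*
than an edge threshold; raising the threshold can only remove edges.
Histograms of the off-diagonal scores summarize the distribution a user
would consult to pick a threshold, and subnetwork selection restricts the
network to a picked node set, optionally closed under direct neighbors.
Exports target generic viewers: GraphML and a cytoscape.js-compatible
elements JSON, with node metadata (label, IC, degree) embedded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .ontology import ICTable, OntologyGraph
from .term_similarity import SimilarityMatrix

__all__ = [
    "AssociationNetwork",
    "threshold_network",
    "score_distribution",
    "select_subnetwork",
    "write_graphml",
    "read_graphml",
    "write_cytoscape_json",
    "read_cytoscape_json",
    "write_histogram_tsv",
]


@dataclass
class AssociationNetwork:
    """Score-weighted undirected graph with a strict edge threshold."""

    graph: nx.Graph
    threshold: float
    selected: frozenset[str] = frozenset()
    locked: frozenset[str] = frozenset()

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        """Sorted (a, b, score) records with a < b."""
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = (u, v) if u < v else (v, u)
            out.append((a, b, float(data["score"])))
        return sorted(out)


def threshold_network(
    m: SimilarityMatrix,
    threshold: float,
    g: OntologyGraph | None = None,
    ic: ICTable | None = None,
) -> AssociationNetwork:
    """Keep every unordered pair with score strictly above ``threshold``.

    All matrix terms stay as nodes even when isolated.  When an ontology
    and IC table are supplied, node metadata (label, ic, degree) is
    embedded for downstream viewers.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    graph = nx.Graph()
    graph.add_nodes_from(m.terms)
    for a, b, score in sorted(m.iter_pairs()):
        if score > threshold:
            graph.add_edge(a, b, score=score)
    for node in graph.nodes:
        if g is not None and node in g.terms:
            graph.nodes[node]["label"] = g.terms[node].name
        if ic is not None and node in ic.ic:
            graph.nodes[node]["ic"] = ic.ic[node]
        graph.nodes[node]["degree"] = graph.degree(node)
    return AssociationNetwork(graph=graph, threshold=threshold)


def score_distribution(
    m: SimilarityMatrix, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of the off-diagonal scores.

    Each unordered pair counts exactly once; returns (bin_edges, counts).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(m.terms) < 2:
        raise ValueError("need at least 2 terms for a score distribution")
    values = np.array([s for _, _, s in m.iter_pairs()])
    counts, edges = np.histogram(values, bins=n_bins)
    return edges, counts


def select_subnetwork(
    net: AssociationNetwork, picked: set[str], include_neighbors: bool = False
) -> AssociationNetwork:
    """Induced subgraph on ``picked`` (plus direct neighbors if asked)."""
    unknown = sorted(set(picked) - set(net.graph.nodes))
    if unknown:
        raise KeyError(f"unknown node ids: {', '.join(unknown)}")
    keep = set(picked)
    if include_neighbors:
        for node in picked:
            keep |= set(net.graph.neighbors(node))
    sub = net.graph.subgraph(sorted(keep)).copy()
    return AssociationNetwork(
        graph=sub,
        threshold=net.threshold,
        selected=frozenset(picked),
        locked=net.locked & frozenset(keep),
    )


# ---------------------------------------------------------------------------
# Writers / readers
# ---------------------------------------------------------------------------

def write_graphml(net: AssociationNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def read_graphml(path, threshold: float = float("-inf")) -> AssociationNetwork:
    return AssociationNetwork(graph=nx.read_graphml(path), threshold=threshold)


def write_cytoscape_json(net: AssociationNetwork, path) -> None:
    """cytoscape.js elements schema: nodes[{data:{id,label,...}}], edges[...]."""
    elements = {
        "nodes": [
            {
                "data": {
                    "id": node,
                    "label": net.graph.nodes[node].get("label", node),
                    **{
                        k: net.graph.nodes[node][k]
                        for k in ("ic", "degree")
                        if k in net.graph.nodes[node]
                    },
                }
            }
            for node in sorted(net.graph.nodes)
        ],
        "edges": [
            {"data": {"source": a, "target": b, "weight": score}}
            for a, b, score in net.edges()
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"elements": elements, "threshold": net.threshold}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_cytoscape_json(path) -> AssociationNetwork:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    graph = nx.Graph()
    for node in payload["elements"]["nodes"]:
        data = dict(node["data"])
        graph.add_node(data.pop("id"), **data)
    for edge in payload["elements"]["edges"]:
        data = dict(edge["data"])
        graph.add_edge(data.pop("source"), data.pop("target"), score=data.get("weight"))
    return AssociationNetwork(graph=graph, threshold=payload.get("threshold", float("-inf")))


def write_histogram_tsv(edges: np.ndarray, counts: np.ndarray, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("bin_left\tbin_right\tcount\n")
        for left, right, count in zip(edges[:-1], edges[1:], counts):
            fh.write(f"{float(left)!r}\t{float(right)!r}\t{int(count)}\n")
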