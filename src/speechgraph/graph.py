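"""Directed speech multigraph built from an element sequence.

Each distinct lexeme becomes a node; every consecutive element pair
(i, i+1) contributes one directed edge in utterance order, so a
transcript with k elements yields exactly k-1 edges.  Self-loops (an
element repeated back-to-back) and parallel edges (a transition uttered
more than once) are preserved: recurrence is precisely what the
downstream measures quantify.

An edge is flagged as a topic deviation when its endpoints touch a
deviation span.  The convention is configurable because the boundary
edge — the transition that leaves the anchor topic — can defensibly be
attributed to either side:

``either`` (default)
    flagged if at least one endpoint element is a deviation; the edge
    that exits the anchor topic is itself the flight-of-thought event.
``source`` / ``target``
    flagged only by the corresponding endpoint element.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import networkx as nx
import numpy as np

from .transcript import Segment, Transcript

__all__ = [
    "Edge",
    "NodeSegments",
    "SpeechGraph",
    "build_graph",
    "adjacency_matrix",
    "simplify",
    "to_networkx",
    "write_graphml",
    "write_edgelist_csv",
]

DeviationConvention = Literal["either", "source", "target"]


@dataclass(frozen=True)
class Edge:
    """One directed transition, numbered 1..E in utterance order."""

    source: str
    target: str
    sequence: int
    deviation: bool


@dataclass(frozen=True)
class NodeSegments:
    appears_in_anchor: bool
    appears_in_deviation: bool


@dataclass
class SpeechGraph:
    """Directed multigraph over lexemes, edges in sequence order.

    ``nodes`` is kept in first-appearance order; this order also indexes
    the adjacency matrix, making every downstream quantity deterministic
    for a given transcript.
    """

    nodes: list[str]
    edges: list[Edge]
    node_segments: dict[str, NodeSegments]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_graph(
    t: Transcript, deviation_convention: DeviationConvention = "either"
) -> SpeechGraph:
    """Build the speech multigraph of one transcript.

    A single-element transcript yields the degenerate but valid graph
    with one node and no edges.
    """
    nodes: list[str] = []
    seen: set[str] = set()
    anchor_flag: dict[str, bool] = {}
    deviation_flag: dict[str, bool] = {}
    for el in t.elements:
        if el.lexeme not in seen:
            seen.add(el.lexeme)
            nodes.append(el.lexeme)
            anchor_flag[el.lexeme] = False
            deviation_flag[el.lexeme] = False
        if el.segment is Segment.DEVIATION:
            deviation_flag[el.lexeme] = True
        else:
            anchor_flag[el.lexeme] = True

    edges: list[Edge] = []
    for i in range(len(t.elements) - 1):
        src, dst = t.elements[i], t.elements[i + 1]
        src_dev = src.segment is Segment.DEVIATION
        dst_dev = dst.segment is Segment.DEVIATION
        if deviation_convention == "either":
            dev = src_dev or dst_dev
        elif deviation_convention == "source":
            dev = src_dev
        elif deviation_convention == "target":
            dev = dst_dev
        else:
            raise ValueError(f"unknown deviation convention: {deviation_convention!r}")
        edges.append(Edge(src.lexeme, dst.lexeme, sequence=i + 1, deviation=dev))

    segments = {
        w: NodeSegments(anchor_flag[w], deviation_flag[w]) for w in nodes
    }
    return SpeechGraph(nodes=nodes, edges=edges, node_segments=segments)


def adjacency_matrix(g: SpeechGraph) -> np.ndarray:
    """Integer multiplicity matrix A with A[i, j] = number of edges i->j.

    Rows/columns are indexed by ``g.nodes`` (first-appearance order).
    The sum of all entries equals E.
    """
    index = {w: i for i, w in enumerate(g.nodes)}
    a = np.zeros((g.n_nodes, g.n_nodes), dtype=np.int64)
    for e in g.edges:
        a[index[e.source], index[e.target]] += 1
    return a


def simplify(g: SpeechGraph, directed: bool) -> nx.Graph | nx.DiGraph:
    """Simple-graph view: self-loops dropped, parallel edges collapsed.

    With ``directed=False`` the reciprocal pairs (i, j)/(j, i) merge into
    one undirected edge.  Nodes without surviving edges remain as
    isolated nodes.
    """
    simple: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
    simple.add_nodes_from(g.nodes)
    for e in g.edges:
        if e.source != e.target:
            simple.add_edge(e.source, e.target)
    return simple


def to_networkx(g: SpeechGraph) -> nx.MultiDiGraph:
    """Full-fidelity multigraph view with sequence and deviation attributes."""
    mg = nx.MultiDiGraph()
    for w in g.nodes:
        seg = g.node_segments[w]
        mg.add_node(
            w,
            lexeme=w,
            appears_in_anchor=seg.appears_in_anchor,
            appears_in_deviation=seg.appears_in_deviation,
        )
    for e in g.edges:
        mg.add_edge(e.source, e.target, sequence=e.sequence, deviation=e.deviation)
    return mg


def write_graphml(g: SpeechGraph, path: str | Path) -> None:
    nx.write_graphml(to_networkx(g), str(path))


def write_edgelist_csv(g: SpeechGraph, path: str | Path) -> None:
    """Edge list as CSV with columns source, target, sequence, deviation."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "sequence", "deviation"])
        for e in g.edges:
            writer.writerow([e.source, e.target, e.sequence, int(e.deviation)])
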