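"""The fourteen speech-graph measures, word-normalized variants and ratios.

Local measures
    N, E            number of nodes (distinct lexemes) and edges
    ATD             average total degree, mean of in+out degree = 2E/N
    LCC, LSC        nodes in the largest connected component of the
                    undirected simple view / largest strongly connected
                    component of the directed simple view
    PE              parallel edges: excess multiplicity per ordered node
                    pair beyond the first edge (self-loops excluded)
    L1, L2, L3      closed walks of length 1..3 = trace of A^k on the
                    integer multiplicity adjacency matrix
    WN, WE          nodes / edges touching topic-deviation speech

Global measures
    D               density (E - L1 - PE) / N^2, i.e. simple directed
                    edge count over N^2, hence in [0, 1]
    DI, ASP         diameter and average shortest path of the undirected
                    simple view, over finite-distance pairs only

Each measure also comes word-normalized (divided by the raw word count
of the report), which discounts verbosity differences between speakers.
Undefined quantities (DI/ASP on a single node or with no finite pairs,
WE/E on an edgeless graph) are reported as NaN, never imputed as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidWordCountError
from .graph import DeviationConvention, SpeechGraph, adjacency_matrix, build_graph, simplify
from .transcript import SubjectRecord, Transcript

__all__ = [
    "MeasureVector",
    "RAW_MEASURES",
    "average_total_degree",
    "largest_connected_component",
    "largest_strongly_connected_component",
    "parallel_edges",
    "loops",
    "waking_counts",
    "density",
    "diameter_asp",
    "compute_from_graph",
    "compute_all",
    "measures_table",
]

#: canonical column order of the measure table
RAW_MEASURES = [
    "N", "E", "ATD", "LCC", "LSC", "PE", "L1", "L2", "L3", "WN", "WE",
    "D", "DI", "ASP",
]


def average_total_degree(g: SpeechGraph) -> float:
    """Mean over nodes of in-degree + out-degree (multiplicities counted).

    By the multigraph handshake lemma this equals 2E/N exactly.
    """
    return 2.0 * g.n_edges / g.n_nodes


def largest_connected_component(g: SpeechGraph) -> int:
    """Node count of the largest component of the undirected simple view."""
    und = simplify(g, directed=False)
    return max(len(c) for c in nx.connected_components(und))


def largest_strongly_connected_component(g: SpeechGraph) -> int:
    """Node count of the largest SCC of the directed simple view."""
    dir_simple = simplify(g, directed=True)
    return max(len(c) for c in nx.strongly_connected_components(dir_simple))


def parallel_edges(g: SpeechGraph) -> int:
    """Excess edge multiplicity summed over ordered node pairs i != j.

    Self-loop multiplicities are excluded — repeated self-transitions
    belong to L1.  With this convention E - L1 - PE is exactly the edge
    count of the directed simple view, which pins density into [0, 1].
    """
    a = adjacency_matrix(g)
    off = a - np.diag(np.diag(a))
    return int(np.sum(np.maximum(off - 1, 0)[off > 0]))


def loops(g: SpeechGraph, k: int) -> int:
    """Closed walks of length k (k in 1..3) as the trace of A^k.

    A carries integer multiplicities, so parallel edges multiply walk
    counts — the trace formula is applied literally.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    a = adjacency_matrix(g)
    return int(np.trace(np.linalg.matrix_power(a, k)))


def waking_counts(g: SpeechGraph) -> tuple[int, int]:
    """(WN, WE): nodes appearing in deviation speech, deviation-flagged edges."""
    wn = sum(1 for w in g.nodes if g.node_segments[w].appears_in_deviation)
    we = sum(1 for e in g.edges if e.deviation)
    return wn, we


def density(g: SpeechGraph) -> float:
    """D = E'/N^2 with E' = E - (L1 + PE), the simple directed edge count."""
    e_prime = g.n_edges - loops(g, 1) - parallel_edges(g)
    return e_prime / g.n_nodes**2


def diameter_asp(
    g: SpeechGraph, scope: Literal["finite_pairs", "largest_component"] = "finite_pairs"
) -> tuple[float, float]:
    """Diameter and average shortest path of the undirected simple view.

    All-pairs BFS; pairs in different components carry no finite distance
    and are excluded from both statistics (``scope="largest_component"``
    instead restricts the graph to its largest component first, which on
    connected graphs is identical).  Returns (nan, nan) when no pair has
    a finite distance (N = 1, or no non-loop edges).
    """
    und = simplify(g, directed=False)
    if scope == "largest_component":
        comp = max(nx.connected_components(und), key=len)
        und = und.subgraph(comp)
    distances: list[int] = []
    for source, lengths in nx.all_pairs_shortest_path_length(und):
        for target, d in lengths.items():
            if source < target:  # each unordered pair once
                distances.append(d)
    if not distances:
        return math.nan, math.nan
    return float(max(distances)), float(np.mean(distances))


@dataclass
class MeasureVector:
    """All measures for one transcript; NaN marks undefined values."""

    subject_id: str
    group: str
    word_count: int
    raw: dict[str, float]

    @property
    def normalized(self) -> dict[str, float]:
        """Each raw measure divided by the raw word count of the report."""
        return {f"{k}_per_word": v / self.word_count for k, v in self.raw.items()}

    @property
    def wn_ratio(self) -> float:
        return self.raw["WN"] / self.raw["N"]

    @property
    def we_ratio(self) -> float:
        return self.raw["WE"] / self.raw["E"] if self.raw["E"] > 0 else math.nan

    def to_dict(self) -> dict[str, float | int | str]:
        row: dict[str, float | int | str] = {
            "subject_id": self.subject_id,
            "group": self.group,
            "word_count": self.word_count,
        }
        row.update({k: self.raw[k] for k in RAW_MEASURES})
        row.update(self.normalized)
        row["wn_ratio"] = self.wn_ratio
        row["we_ratio"] = self.we_ratio
        return row


def compute_from_graph(
    g: SpeechGraph,
    word_count: int,
    subject_id: str = "",
    group: str = "unlabeled",
    asp_scope: Literal["finite_pairs", "largest_component"] = "finite_pairs",
) -> MeasureVector:
    if word_count < 1:
        raise InvalidWordCountError(f"word_count must be >= 1, got {word_count}")
    wn, we = waking_counts(g)
    di, asp = diameter_asp(g, scope=asp_scope)
    raw = {
        "N": float(g.n_nodes),
        "E": float(g.n_edges),
        "ATD": average_total_degree(g),
        "LCC": float(largest_connected_component(g)),
        "LSC": float(largest_strongly_connected_component(g)),
        "PE": float(parallel_edges(g)),
        "L1": float(loops(g, 1)),
        "L2": float(loops(g, 2)),
        "L3": float(loops(g, 3)),
        "WN": float(wn),
        "WE": float(we),
        "D": density(g),
        "DI": di,
        "ASP": asp,
    }
    return MeasureVector(
        subject_id=subject_id, group=group, word_count=word_count, raw=raw
    )


def compute_all(
    t: Transcript,
    deviation_convention: DeviationConvention = "either",
    asp_scope: Literal["finite_pairs", "largest_component"] = "finite_pairs",
) -> MeasureVector:
    """Transcript -> full measure vector (raw, normalized, ratios)."""
    g = build_graph(t, deviation_convention=deviation_convention)
    return compute_from_graph(
        g,
        word_count=t.word_count,
        subject_id=t.subject_id,
        group=t.group.value,
        asp_scope=asp_scope,
    )


def measures_table(
    corpus: Iterable[tuple[Transcript, Optional[SubjectRecord]]] | Sequence[Transcript],
    deviation_convention: DeviationConvention = "either",
) -> pd.DataFrame:
    """One measure-vector row per subject, in corpus order.

    Accepts either a plain transcript sequence or the (transcript,
    metadata) pairs returned by :func:`speechgraph.transcript.load_corpus`;
    when metadata carries BPRS/PANSS totals they are appended as columns.
    """
    rows = []
    for item in corpus:
        if isinstance(item, Transcript):
            t, rec = item, None
        else:
            t, rec = item
        vec = compute_all(t, deviation_convention=deviation_convention)
        row = vec.to_dict()
        if rec is not None:
            row["bprs"] = rec.bprs_total if rec.bprs_total is not None else math.nan
            row["panss"] = rec.panss_total if rec.panss_total is not None else math.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    # scale columns only when some subject actually has a total
    for scale in ("bprs", "panss"):
        if scale in table.columns and table[scale].isna().all():
            table = table.drop(columns=scale)
    return table
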