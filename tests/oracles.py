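"""Independent brute-force oracles used to check the measure pipeline.

Everything here works directly on the edge list by exhaustive
enumeration or hand-rolled BFS — deliberately avoiding the adjacency
matrix, trace formulas and networkx calls used by the implementation.
Only usable at toy sizes.
"""

from __future__ import annotations

from collections import Counter, deque
from itertools import combinations


def closed_walks(edges: list[tuple[str, str]], k: int) -> int:
    """Count closed k-walks by enumerating edge sequences."""
    count = 0

    def extend(walk: list[tuple[str, str]]) -> None:
        nonlocal count
        if len(walk) == k:
            if walk[-1][1] == walk[0][0]:
                count += 1
            return
        last = walk[-1][1]
        for e in edges:
            if e[0] == last:
                extend(walk + [e])

    for e in edges:
        extend([e])
    return count


def parallel_edge_excess(edges: list[tuple[str, str]]) -> int:
    """Excess multiplicity over ordered non-loop pairs."""
    mult = Counter(e for e in edges if e[0] != e[1])
    return sum(m - 1 for m in mult.values())


def undirected_adjacency(
    nodes: list[str], edges: list[tuple[str, str]]
) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def _bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def largest_component(nodes: list[str], edges: list[tuple[str, str]]) -> int:
    adj = undirected_adjacency(nodes, edges)
    best = 0
    remaining = set(nodes)
    while remaining:
        src = next(iter(remaining))
        comp = set(_bfs_distances(adj, src))
        best = max(best, len(comp))
        remaining -= comp
    return best


def largest_scc(nodes: list[str], edges: list[tuple[str, str]]) -> int:
    """Largest strongly connected component by pairwise reachability."""
    succ: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        if a != b:
            succ[a].add(b)

    def reachable(src: str) -> set[str]:
        seen = {src}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in succ[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        return seen

    reach = {n: reachable(n) for n in nodes}
    best = 1 if nodes else 0
    for n in nodes:
        scc = {m for m in reach[n] if n in reach[m]}
        best = max(best, len(scc))
    return best


def diameter_and_asp(
    nodes: list[str], edges: list[tuple[str, str]]
) -> tuple[float, float]:
    """Max and mean finite shortest-path distance over unordered pairs."""
    adj = undirected_adjacency(nodes, edges)
    dists = []
    for a, b in combinations(nodes, 2):
        d = _bfs_distances(adj, a)
        if b in d:
            dists.append(d[b])
    if not dists:
        return float("nan"), float("nan")
    return float(max(dists)), sum(dists) / len(dists)


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the pairwise-win fraction over all (positive, negative) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
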