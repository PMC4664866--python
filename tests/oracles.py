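"""Independent brute-force oracles used by the tests.

These deliberately avoid the library code paths they check: shortest paths
are enumerated exhaustively, modularity maxima by iterating over all set
partitions, and rankings by a plain stable sort.
"""

from __future__ import annotations

import itertools
from collections import deque


def all_shortest_paths(g, s, t):
    """Every shortest s-t path as a list of node sequences (BFS + DFS on the
    predecessor structure). Empty list if t is unreachable."""
    if s == t:
        return []
    dist = {s: 0}
    preds = {s: []}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for w in g[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                preds[w] = [u]
                queue.append(w)
            elif dist[w] == dist[u] + 1:
                preds[w].append(u)
    if t not in dist:
        return []
    paths = []

    def walk(node, tail):
        if node == s:
            paths.append([s] + tail)
            return
        for p in preds[node]:
            walk(p, [node] + tail)

    walk(t, [])
    return paths


def brute_edge_betweenness(g):
    """Ordered-pair edge betweenness by exhaustive path enumeration."""
    bet = {tuple(sorted(e, key=str)): 0.0 for e in g.edges()}
    for s in g.nodes:
        for t in g.nodes:
            if s == t:
                continue
            paths = all_shortest_paths(g, s, t)
            if not paths:
                continue
            share = 1.0 / len(paths)
            for path in paths:
                for u, v in zip(path, path[1:]):
                    bet[tuple(sorted((u, v), key=str))] += share
    return bet


def brute_node_betweenness(g, v):
    """Ordered-pair node betweenness of v (endpoints excluded)."""
    total = 0.0
    for s in g.nodes:
        for t in g.nodes:
            if len({s, t, v}) < 3:
                continue
            paths = all_shortest_paths(g, s, t)
            if not paths:
                continue
            total += sum(1 for p in paths if v in p[1:-1]) / len(paths)
    return total


def total_ordered_distance(g):
    """Sum of d(s, t) over ordered connected pairs."""
    total = 0
    for s in g.nodes:
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in g[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        total += sum(d for d in dist.values() if d > 0)
    return total


def set_partitions(items):
    """All set partitions of `items` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1 :]
        yield smaller + [[first]]


def brute_modularity(g, groups):
    """Textbook Q = sum_r (e_rr - a_r^2) computed straight from the sets."""
    m = g.number_of_edges()
    label = {n: i for i, grp in enumerate(groups) for n in grp}
    q = 0.0
    for i, grp in enumerate(groups):
        within = sum(1 for u, v in g.edges() if label[u] == i and label[v] == i)
        ends = sum(1 for u, v in g.edges() for n in (u, v) if label[n] == i)
        q += within / m - (ends / (2 * m)) ** 2
    return q


def brute_max_modularity(g):
    """Maximum modularity over every partition (small graphs only)."""
    return max(
        brute_modularity(g, groups) for groups in set_partitions(list(g.nodes))
    )


def stable_sort_ranking(scored):
    """Reference ranking: stable sort by descending score, then pair name."""
    return [
        sp.pair
        for sp in sorted(
            scored, key=lambda sp: (-sp.score, str(sp.pair[0]), str(sp.pair[1]))
        )
    ]
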