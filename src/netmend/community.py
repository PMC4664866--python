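"""Modularity and extremal-optimization (EO) community detection.

The detector follows the recursive-bipartitioning EO heuristic: starting from
the connected components, each community is repeatedly split in two by
tau-EO dynamics — the node with (close to) the worst per-degree modularity
contribution is relocated across the split, with rank r chosen with
probability proportional to r^-tau — while the best split seen is tracked.
A split is committed only if it raises the global modularity, and splitting
recurses until no community can be profitably divided.

The detector is pluggable: anything with the (graph, seed) -> Partition
contract can replace :func:`detect_communities` in the higher-level methods;
only the partition quality matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._util import derive_rng

__all__ = ["Partition", "modularity", "detect_communities", "classify_pair"]


@dataclass
class Partition:
    """A node -> community-label assignment."""

    assignment: dict = field(default_factory=dict)

    def __getitem__(self, node):
        return self.assignment[node]

    def __contains__(self, node):
        return node in self.assignment

    def __len__(self):
        return len(self.assignment)

    def labels(self) -> set:
        return set(self.assignment.values())

    def communities(self) -> dict:
        """Label -> set of member nodes."""
        out: dict = {}
        for node, lab in self.assignment.items():
            out.setdefault(lab, set()).add(node)
        return out

    def n_communities(self) -> int:
        return len(self.labels())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node\tlabel\n")
            for node in sorted(self.assignment, key=str):
                fh.write(f"{node}\t{self.assignment[node]}\n")

    @classmethod
    def from_communities(cls, groups) -> "Partition":
        return cls({node: i for i, grp in enumerate(groups) for node in grp})


def modularity(g: nx.Graph, p: Partition) -> float:
    """Newman modularity Q = sum_r (e_rr - a_r^2).

    e_rr is the fraction of edges with both endpoints in community r and a_r
    the fraction of edge ends attached to r. Requires at least one edge and a
    label for every node of ``g``.
    """
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    missing = [n for n in g.nodes if n not in p]
    if missing:
        raise KeyError(f"partition misses {len(missing)} node(s), e.g. {missing[0]!r}")
    e_rr: dict = {}
    ends: dict = {}
    for u, v in g.edges():
        cu, cv = p[u], p[v]
        if cu == cv:
            e_rr[cu] = e_rr.get(cu, 0) + 1
        ends[cu] = ends.get(cu, 0) + 1
        ends[cv] = ends.get(cv, 0) + 1
    q = 0.0
    for lab in set(ends) | set(e_rr):
        q += e_rr.get(lab, 0) / m - (ends.get(lab, 0) / (2 * m)) ** 2
    return q


def _eo_bisect(g, members, total_m, rng, tau, stall_limit):
    """Try to split community `members` into two, maximizing the global
    modularity gain. Returns (group_a, group_b, delta_q)."""
    nodes = list(members)
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    deg = np.array([g.degree(node) for node in nodes], dtype=float)
    nbrs = [
        np.array([idx[w] for w in g[node] if w in idx], dtype=np.int64)
        for node in nodes
    ]
    if tau is None:
        tau = 1.0 + 1.0 / np.log(n) if n > 2 else 1.4
    if stall_limit is None:
        stall_limit = n * n

    side = np.zeros(n, dtype=bool)
    side[rng.permutation(n)[: n // 2]] = True

    # links from each node to its own / the other side, within the community
    kappa_same = np.zeros(n)
    for i in range(n):
        kappa_same[i] = np.count_nonzero(side[nbrs[i]] == side[i])
    cut = float(sum(len(nbrs[i]) - kappa_same[i] for i in range(n))) / 2.0

    k_total = deg.sum()
    k_a = deg[side].sum()
    two_m = 2.0 * total_m

    def delta_q():
        # gain over the unsplit community: fewer within-links (the cut) vs
        # the degree-product term released by separating the two halves
        k_b = k_total - k_a
        return -cut / total_m + 2.0 * k_a * k_b / (two_m * two_m)

    weights = np.arange(1, n + 1, dtype=float) ** (-tau)
    cum = np.cumsum(weights / weights.sum())

    best_dq = delta_q()
    best_side = side.copy()
    stall = 0
    while stall < stall_limit:
        # fitness: per-degree modularity contribution of each node
        group_k = np.where(side, k_a, k_total - k_a)
        fitness = kappa_same / (two_m * deg) - group_k / (two_m * two_m)
        order = np.argsort(fitness, kind="stable")  # worst first
        rank = int(np.searchsorted(cum, rng.random()))
        i = int(order[min(rank, n - 1)])

        # flip node i across the split
        new_side = not side[i]
        cut += kappa_same[i] - (len(nbrs[i]) - kappa_same[i])
        kappa_same[i] = len(nbrs[i]) - kappa_same[i]
        for j in nbrs[i]:
            if side[j] == new_side:
                kappa_same[j] += 1
            else:
                kappa_same[j] -= 1
        k_a += deg[i] if new_side else -deg[i]
        side[i] = new_side

        dq = delta_q()
        if dq > best_dq + 1e-14:
            best_dq = dq
            best_side = side.copy()
            stall = 0
        else:
            stall += 1

    group_a = {nodes[i] for i in range(n) if best_side[i]}
    group_b = {nodes[i] for i in range(n) if not best_side[i]}
    return group_a, group_b, best_dq


def detect_communities(
    g: nx.Graph,
    seed=None,
    tau: float | None = None,
    stall_limit: int | None = None,
) -> Partition:
    """Modularity-maximizing partition via recursive tau-EO bipartitioning.

    Parameters
    ----------
    seed : int, optional
        Seeds the EO dynamics; the result is reproducible given a seed.
    tau : float, optional
        Rank-selection exponent; default 1 + 1/ln(n) per community size n.
    stall_limit : int, optional
        Consecutive non-improving relocations before a bipartition attempt
        stops; default n^2 for a community of n nodes.
    """
    if g.number_of_edges() == 0:
        raise ValueError("community detection undefined for an edgeless graph")
    rng = derive_rng(seed)
    total_m = g.number_of_edges()

    final = []
    stack = [set(c) for c in nx.connected_components(g)]
    while stack:
        comm = stack.pop()
        if len(comm) < 2:
            final.append(comm)
            continue
        a, b, dq = _eo_bisect(g, comm, total_m, rng, tau, stall_limit)
        if dq > 1e-12 and a and b:
            stack.append(a)
            stack.append(b)
        else:
            final.append(comm)
    return Partition.from_communities(final)


def classify_pair(p: Partition, x, y) -> str:
    """Classify a node pair as ``"intra"`` (same community) or ``"inter"``."""
    for n in (x, y):
        if n not in p:
            raise KeyError(f"node {n!r} has no community label")
    return "intra" if p[x] == p[y] else "inter"
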