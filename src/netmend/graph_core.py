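"""Graph I/O and structural indices.

Graphs are plain :class:`networkx.Graph` objects: undirected, simple, no
self-loops. Betweenness quantities follow the ordered-pair convention — every
unordered source/target pair is counted in both directions — which is the
convention under which the bundled Zachary karate club network has a maximum
node betweenness (congestibility) of 462.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources

import networkx as nx
import numpy as np

from ._util import canon_pair

logger = logging.getLogger(__name__)

__all__ = [
    "IndexReport",
    "read_edge_list",
    "write_edge_list",
    "load_karate_club",
    "edge_betweenness",
    "max_node_betweenness",
    "laplacian_eigenratio",
    "average_shortest_path",
    "structural_summary",
]


@dataclass
class IndexReport:
    """Structural/dynamical indices of a network.

    Attributes
    ----------
    avg_shortest_path : float
        Mean hop distance over *connected* unordered node pairs (disconnected
        pairs are excluded, so the index is defined for fragmented graphs).
    clustering : float
        Mean local clustering coefficient; nodes of degree < 2 contribute 0.
    assortativity : float or None
        Degree Pearson correlation over edges; ``None`` when undefined
        (zero degree variance, e.g. regular graphs).
    congestibility : float
        Maximum node betweenness, ordered-pair count.
    synchronizability : float
        Laplacian eigenratio lambda_max / lambda_2 of the largest connected
        component (>= 1; smaller means easier to synchronize).
    spreading_ability : float or None
        Mean SIR outbreak size (in nodes); ``None`` if not computed.
    """

    avg_shortest_path: float
    clustering: float
    assortativity: float | None
    congestibility: float
    synchronizability: float
    spreading_ability: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def read_edge_list(path) -> nx.Graph:
    """Read a whitespace-delimited edge list into an undirected simple graph.

    One edge per line: two (or more; extras ignored) whitespace-separated
    node identifiers, kept as opaque strings. ``#`` starts a comment.
    Duplicate edges are collapsed with a logged warning; a self-loop is an
    error naming the offending line.
    """
    g = nx.Graph()
    n_dupes = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 tokens, got {line!r}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u!r}-{v!r}")
            if g.has_edge(u, v):
                n_dupes += 1
            g.add_edge(u, v)
    if g.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges found")
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate edge line(s)", path, n_dupes)
    return g


def write_edge_list(g: nx.Graph, path, header: str | None = None) -> None:
    """Write ``g`` as a two-column whitespace edge list."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for u, v in sorted((canon_pair(u, v) for u, v in g.edges()),
                           key=lambda p: (str(p[0]), str(p[1]))):
            fh.write(f"{u} {v}\n")


def load_karate_club() -> nx.Graph:
    """The bundled Zachary karate club network (34 nodes, 78 edges)."""
    ref = resources.files("netmend.data") / "zachary_karate.edgelist"
    with resources.as_file(ref) as path:
        return read_edge_list(path)


def edge_betweenness(g: nx.Graph) -> dict:
    """Edge betweenness B_e, ordered-pair convention.

    B_e = sum over ordered node pairs (i, j), i != j, of sigma_ij(e)/sigma_ij
    where sigma_ij counts shortest i-j paths and sigma_ij(e) those traversing
    e. Pairs in different components contribute 0. Keys are canonical pairs.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    eb = nx.edge_betweenness_centrality(g, normalized=False)
    # networkx counts each unordered pair once for undirected graphs
    return {canon_pair(u, v): 2.0 * b for (u, v), b in eb.items()}


def max_node_betweenness(g: nx.Graph) -> float:
    """Congestibility: the maximum node betweenness (ordered-pair count)."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    bc = nx.betweenness_centrality(g, normalized=False)
    return 2.0 * max(bc.values())


def laplacian_eigenratio(g: nx.Graph) -> float:
    """Synchronizability index lambda_max / lambda_2 of the combinatorial
    Laplacian of the largest connected component (1.0 for complete graphs)."""
    lcc = max(nx.connected_components(g), key=len)
    sub = g.subgraph(lcc)
    if sub.number_of_nodes() < 2:
        raise ValueError("largest component has fewer than 2 nodes")
    lap = nx.laplacian_matrix(sub, weight=None).toarray().astype(float)
    ev = np.sort(np.linalg.eigvalsh(lap))
    return float(ev[-1] / ev[1])


def average_shortest_path(g: nx.Graph) -> float:
    """Mean shortest-path length over connected unordered node pairs only."""
    total = 0
    n_pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                n_pairs += 1
    if n_pairs == 0:
        raise ValueError("graph has no connected pairs")
    return total / n_pairs  # ordered pairs; ratio equals the unordered mean


def _assortativity(g: nx.Graph) -> float | None:
    degrees = [d for _, d in g.degree()]
    if len(set(degrees)) <= 1:
        return None  # zero degree variance: coefficient undefined
    r = nx.degree_assortativity_coefficient(g)
    if np.isnan(r):
        return None
    return float(r)


def structural_summary(
    g: nx.Graph,
    sir_params: dict | None = None,
    seed=None,
    include_spreading: bool = True,
) -> IndexReport:
    """Compute the six-index structural/dynamical profile of ``g``.

    ``sir_params`` are forwarded to
    :func:`netmend.reconstruction.spreading_ability` (keys ``transmission``,
    ``reps``); set ``include_spreading=False`` to skip the Monte-Carlo index.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    spreading = None
    if include_spreading:
        from .reconstruction import spreading_ability  # deferred: avoids cycle

        spreading = spreading_ability(g, seed=seed, **(sir_params or {}))
    return IndexReport(
        avg_shortest_path=average_shortest_path(g),
        clustering=float(nx.average_clustering(g)),
        assortativity=_assortativity(g),
        congestibility=max_node_betweenness(g),
        synchronizability=laplacian_eigenratio(g),
        spreading_ability=spreading,
    )
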