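"""Local similarity scores for unconnected node pairs.

Two classic indices are provided: common neighbours (CN), the size of the
shared neighbourhood, and resource allocation (RA), which down-weights each
common neighbour z by 1/k_z so that hub-mediated similarity counts less.
Scores are raw (unnormalised); ranking uses the values as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from ._util import Pair, canon_pair

__all__ = ["ScoredPair", "cn_score", "ra_score", "score_candidates", "METHODS"]

#: base similarity methods by name (case-insensitive in public entry points)
METHODS = ("CN", "RA")


@dataclass(frozen=True)
class ScoredPair:
    pair: Pair
    score: float


def _check_nodes(g: nx.Graph, x, y):
    if x == y:
        raise ValueError(f"pair must be two distinct nodes, got {x!r} twice")
    for n in (x, y):
        if n not in g:
            raise KeyError(f"node {n!r} not in graph")


def cn_score(g: nx.Graph, x, y) -> float:
    """Number of common neighbours of x and y."""
    _check_nodes(g, x, y)
    return float(len(set(g[x]) & set(g[y])))


def ra_score(g: nx.Graph, x, y) -> float:
    """Resource-allocation index: sum of 1/k_z over common neighbours z."""
    _check_nodes(g, x, y)
    return float(sum(1.0 / g.degree(z) for z in set(g[x]) & set(g[y])))


_SCORERS = {"CN": cn_score, "RA": ra_score}


def score_candidates(g: nx.Graph, method: str = "CN") -> list[ScoredPair]:
    """Score every non-adjacent unordered node pair of ``g``.

    The candidate universe is all C(N,2) - M non-edges, including pairs
    involving isolated nodes. Returns one :class:`ScoredPair` per candidate.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    key = method.upper()
    if key not in _SCORERS:
        raise ValueError(f"unknown similarity method {method!r}; use CN or RA")
    scorer = _SCORERS[key]
    return [
        ScoredPair(canon_pair(u, v), scorer(g, u, v)) for u, v in nx.non_edges(g)
    ]
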