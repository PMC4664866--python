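"""Prediction rankings: descending score order and beta-interleaving.

The community-based methods (CBCN, CBRA) rank intra- and inter-community
candidates separately and then merge the two lists: at each step the head of
the intra list is taken with probability beta, else the head of the inter
list; an exhausted list is drained from the other. beta = 1 puts all
intra-community candidates first, beta = 0 all inter-community ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from ._util import Pair, derive_rng, pair_sort_key
from .community import Partition, classify_pair, detect_communities
from .similarity import ScoredPair, score_candidates

__all__ = [
    "RankedList",
    "rank_descending",
    "interleave",
    "split_by_community",
    "predict_top_L",
    "PREDICTORS",
]

#: prediction methods by name: plain local similarity and community-based
PREDICTORS = ("CN", "RA", "CBCN", "CBRA")


@dataclass
class RankedList:
    """An ordered sequence of node pairs, rank 1 = most likely missing link.

    ``scores`` is a parallel list of similarity values when the order came
    from a single score (pure lists); it is ``None`` for interleaved lists,
    whose two source scores are not mutually comparable.
    """

    pairs: list = field(default_factory=list)
    scores: list | None = None

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]

    def top(self, L: int) -> "RankedList":
        return RankedList(
            self.pairs[:L], None if self.scores is None else self.scores[:L]
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tu\tv\n")
            for r, (u, v) in enumerate(self.pairs, start=1):
                fh.write(f"{r}\t{u}\t{v}\n")


def rank_descending(scored) -> RankedList:
    """Sort scored pairs by score descending; ties break lexicographically on
    the canonical pair identifiers, so the order is deterministic."""
    ordered = sorted(scored, key=lambda sp: (-sp.score, pair_sort_key(sp.pair)))
    return RankedList([sp.pair for sp in ordered], [sp.score for sp in ordered])


def interleave(
    r_intra: RankedList, r_inter: RankedList, beta: float, seed=None
) -> RankedList:
    """Merge two ranked lists by beta-interleaving.

    Repeatedly draw: with probability ``beta`` append the head of the intra
    list, else the head of the inter list; when one list empties, drain the
    other. Both source orders are preserved. Deterministic given ``seed``
    (and for beta in {0, 1} regardless of seed).
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    dup = set(r_intra.pairs) & set(r_inter.pairs)
    if dup:
        raise ValueError(f"lists share {len(dup)} pair(s), e.g. {next(iter(dup))}")
    rng = derive_rng(seed)
    merged: list[Pair] = []
    i = j = 0
    n_a, n_b = len(r_intra), len(r_inter)
    while i < n_a and j < n_b:
        if rng.random() < beta:
            merged.append(r_intra.pairs[i])
            i += 1
        else:
            merged.append(r_inter.pairs[j])
            j += 1
    merged.extend(r_intra.pairs[i:])
    merged.extend(r_inter.pairs[j:])
    return RankedList(merged)


def split_by_community(
    scored: list[ScoredPair], partition: Partition
) -> tuple[list[ScoredPair], list[ScoredPair]]:
    """Split scored candidates into (intra, inter) lists by community."""
    intra, inter = [], []
    for sp in scored:
        if classify_pair(partition, *sp.pair) == "intra":
            intra.append(sp)
        else:
            inter.append(sp)
    return intra, inter


def community_ranking(
    g_train: nx.Graph,
    base_method: str,
    beta: float,
    seed=None,
    partition: Partition | None = None,
) -> RankedList:
    """Full community-based ranking of all candidates of ``g_train``.

    The partition is detected on the training graph (seeded) unless supplied.
    """
    if partition is None:
        partition = detect_communities(g_train, seed=derive_rng(seed).integers(2**31))
    scored = score_candidates(g_train, base_method)
    intra, inter = split_by_community(scored, partition)
    return interleave(
        rank_descending(intra), rank_descending(inter), beta, seed=seed
    )


def predict_top_L(
    g_train: nx.Graph,
    method: str = "CBCN",
    beta: float = 1.0,
    L: int = 10,
    seed=None,
    partition: Partition | None = None,
) -> RankedList:
    """Top-L predicted missing links of the training graph.

    ``method`` is one of CN, RA (plain score ranking; beta ignored) or CBCN,
    CBRA (beta-interleaved community-based ranking). If L exceeds the number
    of candidate pairs, all candidates are returned.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    key = method.upper()
    if key not in PREDICTORS:
        raise ValueError(f"unknown method {method!r}; use one of {PREDICTORS}")
    if key in ("CN", "RA"):
        full = rank_descending(score_candidates(g_train, key))
    else:
        full = community_ranking(
            g_train, key[2:], beta, seed=seed, partition=partition
        )
    return full.top(L)
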