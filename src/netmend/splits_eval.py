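"""Edge-set splitting and evaluation metrics.

A link-prediction experiment hides part of the edge set: the training set
E_T is observed, the probe set E_P is the ground truth to recover, and an
optional learning set E_L stands in for the probe while tuning parameters.
Metrics: AUC (probability that a probe link outranks a nonexistent pair),
precision at L, the mean edge betweenness <B> of the predicted links once
inserted, and intra/inter prediction counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._util import Pair, canon_pair, derive_rng, pair_sort_key
from .community import Partition, classify_pair
from .graph_core import edge_betweenness
from .ranking import RankedList

__all__ = [
    "SplitDataset",
    "EvaluationReport",
    "split_edges",
    "auc",
    "precision_at_L",
    "mean_predicted_betweenness",
    "intra_inter_counts",
]


@dataclass
class SplitDataset:
    """Disjoint edge sets partitioning the source graph's edges."""

    train: list
    learn: list
    probe: list
    nodes: list = field(default_factory=list)

    @property
    def L(self) -> int:
        return len(self.probe)

    def train_graph(self) -> nx.Graph:
        """Graph on the full node set with the training edges only."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.train)
        return g

    def observed_graph(self) -> nx.Graph:
        """Training plus learning edges (everything known at predict time)."""
        g = self.train_graph()
        g.add_edges_from(self.learn)
        return g


@dataclass
class EvaluationReport:
    auc: float
    precision: float
    mean_B: float
    n_intra_pred: int = 0
    n_inter_pred: int = 0
    n_intra_correct: int = 0
    n_inter_correct: int = 0


def split_edges(g: nx.Graph, fractions, seed=None) -> SplitDataset:
    """Randomly partition the edges of ``g`` into train/learn/probe sets.

    ``fractions`` is (train, learn, probe); learn may be 0; the three must
    sum to 1. Set sizes are the rounded targets for learn and probe, with
    train taking the remainder. Deterministic per seed.
    """
    f_train, f_learn, f_probe = fractions
    if abs(f_train + f_learn + f_probe - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if f_train <= 0 or f_probe <= 0 or f_learn < 0:
        raise ValueError("train and probe fractions must be positive")
    edges = sorted((canon_pair(u, v) for u, v in g.edges()), key=pair_sort_key)
    rng = derive_rng(seed)
    order = rng.permutation(len(edges))
    m = len(edges)
    n_probe = int(round(f_probe * m))
    n_learn = int(round(f_learn * m))
    probe_ix = order[:n_probe]
    learn_ix = order[n_probe : n_probe + n_learn]
    train_ix = order[n_probe + n_learn :]
    return SplitDataset(
        train=[edges[i] for i in sorted(train_ix)],
        learn=[edges[i] for i in sorted(learn_ix)],
        probe=[edges[i] for i in sorted(probe_ix)],
        nodes=list(g.nodes),
    )


def _rank_values(ranking: RankedList) -> dict:
    """Map pair -> comparable 'higher is better' value.

    When the list carries scores, ties are genuine score ties; otherwise the
    strict list position defines the order (interleaved lists).
    """
    if ranking.scores is not None:
        return {canon_pair(*p): s for p, s in zip(ranking.pairs, ranking.scores)}
    n = len(ranking.pairs)
    return {canon_pair(*p): float(n - i) for i, p in enumerate(ranking.pairs)}


def auc(
    ranking: RankedList,
    probe,
    nonexistent,
    sample_n: int | None = None,
    seed=None,
) -> float:
    """AUC of a ranking: (n' + 0.5 n'') / n over probe-vs-nonexistent
    comparisons, where n' counts the probe link ranked strictly higher and
    n'' ties.

    By default every probe x nonexistent pair is compared exhaustively (the
    infinite-sample limit of the usual sampled estimator); pass ``sample_n``
    to draw that many random comparisons instead.
    """
    probe = [canon_pair(*p) for p in probe]
    nonexistent = [canon_pair(*q) for q in nonexistent]
    if not probe or not nonexistent:
        raise ValueError("probe and nonexistent sets must be nonempty")
    values = _rank_values(ranking)
    missing = [p for p in list(probe) + list(nonexistent) if p not in values]
    if missing:
        raise KeyError(
            f"{len(missing)} pair(s) absent from the ranking, e.g. {missing[0]}"
        )
    pv = np.array([values[p] for p in probe])
    qv = np.array([values[q] for q in nonexistent])
    if sample_n is not None:
        rng = derive_rng(seed)
        pv = pv[rng.integers(len(pv), size=sample_n)]
        qv = qv[rng.integers(len(qv), size=sample_n)]
        return float(np.mean((pv > qv) + 0.5 * (pv == qv)))
    qs = np.sort(qv)
    n_less = np.searchsorted(qs, pv, side="left")
    n_leq = np.searchsorted(qs, pv, side="right")
    wins = n_less.sum()
    ties = (n_leq - n_less).sum()
    return float((wins + 0.5 * ties) / (len(pv) * len(qs)))


def precision_at_L(ranking: RankedList, probe, L: int | None = None) -> float:
    """Fraction of the top-L ranked pairs that are probe links.

    L defaults to |probe| (the number of missing links).
    """
    probe = {canon_pair(*p) for p in probe}
    if L is None:
        L = len(probe)
    if L <= 0:
        raise ValueError("L must be positive")
    if L > len(ranking):
        raise ValueError(f"L={L} exceeds ranking length {len(ranking)}")
    hits = sum(1 for p in ranking.pairs[:L] if canon_pair(*p) in probe)
    return hits / L


def mean_predicted_betweenness(g_train: nx.Graph, predicted: RankedList) -> float:
    """Mean edge betweenness <B> of the predicted links after insertion.

    All predicted links are added to the training graph at once, edge
    betweenness is computed on the augmented graph, and the mean is taken
    over the predicted links only.
    """
    if len(predicted) == 0:
        raise ValueError("no predicted links")
    for u, v in predicted:
        if g_train.has_edge(u, v):
            raise ValueError(f"predicted pair {(u, v)} is already an edge")
    aug = g_train.copy()
    aug.add_edges_from(predicted.pairs)
    eb = edge_betweenness(aug)
    return float(np.mean([eb[canon_pair(u, v)] for u, v in predicted]))


def intra_inter_counts(
    predicted: RankedList, probe, p: Partition
) -> tuple[int, int, int, int]:
    """(n_intra_pred, n_inter_pred, n_intra_correct, n_inter_correct)."""
    probe = {canon_pair(*e) for e in probe}
    n_intra = n_inter = c_intra = c_inter = 0
    for pair in predicted:
        kind = classify_pair(p, *pair)
        hit = canon_pair(*pair) in probe
        if kind == "intra":
            n_intra += 1
            c_intra += hit
        else:
            n_inter += 1
            c_inter += hit
    return n_intra, n_inter, c_intra, c_inter
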