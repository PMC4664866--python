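"""GN planted-partition benchmark graphs and recovery accuracy.

The classic benchmark: n = 128 nodes in 4 equal communities; each node has
k_in expected neighbours inside its community and k_out = total_degree - k_in
outside, realised as independent Bernoulli edges (p_in within blocks, p_out
between). Larger k_in means clearer community structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from ._util import derive_rng
from .community import Partition

__all__ = ["PlantedGraph", "generate_gn", "classification_accuracy"]


@dataclass
class PlantedGraph:
    graph: nx.Graph
    truth: Partition
    k_in: float
    k_out: float


def generate_gn(
    k_in: float = 12.0,
    total_degree: float = 16.0,
    n: int = 128,
    n_comm: int = 4,
    seed=None,
) -> PlantedGraph:
    """Sample a GN planted-partition graph.

    Intra-community pairs connect with p_in = k_in / (n/n_comm - 1) and
    inter-community pairs with p_out = (total_degree - k_in) / (n - n/n_comm),
    so expected intra/inter degrees are k_in and k_out = total_degree - k_in.
    """
    if n % n_comm != 0:
        raise ValueError(f"n={n} not divisible by n_comm={n_comm}")
    if not 0 <= k_in <= total_degree:
        raise ValueError(f"k_in must be in [0, total_degree], got {k_in}")
    size = n // n_comm
    p_in = k_in / (size - 1)
    p_out = (total_degree - k_in) / (n - size)
    if p_in > 1 or p_out > 1:
        raise ValueError("degree parameters imply an edge probability > 1")

    rng = derive_rng(seed)
    block = np.repeat(np.arange(n_comm), size)
    iu, ju = np.triu_indices(n, k=1)
    same = block[iu] == block[ju]
    prob = np.where(same, p_in, p_out)
    keep = rng.random(len(prob)) < prob

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    truth = Partition({int(i): int(block[i]) for i in range(n)})
    return PlantedGraph(g, truth, float(k_in), float(total_degree - k_in))


def classification_accuracy(found: Partition, truth: Partition) -> float:
    """Fraction of nodes classified correctly under the best label matching.

    Community labels are aligned by maximum-weight bipartite matching of the
    label-overlap (confusion) table, so the score is invariant to label
    permutations.
    """
    if set(found.assignment) != set(truth.assignment):
        raise ValueError("partitions cover different node sets")
    f_labels = sorted(found.labels(), key=str)
    t_labels = sorted(truth.labels(), key=str)
    f_ix = {lab: i for i, lab in enumerate(f_labels)}
    t_ix = {lab: i for i, lab in enumerate(t_labels)}
    confusion = np.zeros((len(f_labels), len(t_labels)))
    for node, lab in found.assignment.items():
        confusion[f_ix[lab], t_ix[truth[node]]] += 1
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    return float(confusion[rows, cols].sum() / len(found))
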