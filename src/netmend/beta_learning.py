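"""Choosing the interleaving parameter beta.

Three estimators are provided, all built on a beta -> (AUC, <B>) curve:

* the oracle beta* — the grid beta whose mean predicted-link betweenness
  <B>(beta) is closest to the <B> of the true missing links (requires probe
  knowledge, so it is a reference, not a usable estimator);
* the learned beta-hat* — the same matching run against a learning edge set
  E_L carved out of the training data (threefold validation), never touching
  the probe;
* the constrained beta-hat* — the learned value, unless matching <B> would
  cost more than a set fraction of the plain-method AUC, in which case beta
  is raised to the point where the AUC floor is met.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._util import canon_pair, derive_rng
from .community import detect_communities
from .ranking import RankedList, interleave, rank_descending, split_by_community
from .similarity import score_candidates
from .splits_eval import auc, mean_predicted_betweenness, split_edges

__all__ = [
    "BetaCurve",
    "beta_curve",
    "baseline_auc",
    "estimate_beta_star",
    "learn_beta_hat",
    "constrained_beta",
    "BetaLearningResult",
    "default_grid",
]


def default_grid(n_points: int = 101) -> np.ndarray:
    """Evenly spaced beta grid on [0, 1] (default 0, 0.01, ..., 1)."""
    return np.linspace(0.0, 1.0, n_points)


@dataclass
class BetaCurve:
    """AUC and <B> as functions of beta, averaged over interleaving draws."""

    grid: np.ndarray
    auc_values: np.ndarray
    meanB_values: np.ndarray
    reps: int
    auc_std: np.ndarray | None = None
    meanB_std: np.ndarray | None = None
    target_B: float | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("beta grid must be strictly increasing")
        if len(self.auc_values) != len(self.grid) or len(self.meanB_values) != len(
            self.grid
        ):
            raise ValueError("curve arrays must match the grid length")


def beta_curve(
    g_train: nx.Graph,
    held_out,
    method: str = "CBCN",
    grid=None,
    reps: int = 10,
    seed=None,
    partition=None,
) -> BetaCurve:
    """Trace AUC(beta) and <B>(beta) against a held-out edge set.

    The community partition is detected once on ``g_train`` (seeded) and the
    ``reps`` replicates vary only the stochastic interleaving draws, so the
    beta = 0 and beta = 1 endpoints have zero variance. Nonexistent pairs for
    the AUC are all non-edges of the training graph except the held-out
    links — exactly what is knowable at learning time.
    """
    held_out = [canon_pair(*e) for e in held_out]
    if not held_out:
        raise ValueError("held-out edge set is empty")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    base = method.upper()
    base = base[2:] if base.startswith("CB") else base

    if partition is None:
        partition = detect_communities(
            g_train, seed=derive_rng(seed, 0).integers(2**31)
        )
    scored = score_candidates(g_train, base)
    intra, inter = split_by_community(scored, partition)
    r_intra, r_inter = rank_descending(intra), rank_descending(inter)
    held_set = set(held_out)
    nonexistent = [sp.pair for sp in scored if sp.pair not in held_set]
    L = len(held_out)

    auc_mean, auc_sd, b_mean, b_sd = [], [], [], []
    for bi, beta in enumerate(grid):
        a_vals, b_vals = [], []
        for rep in range(reps):
            sub = derive_rng(seed, 1, bi, rep).integers(2**31)
            ranking = interleave(r_intra, r_inter, float(beta), seed=sub)
            a_vals.append(auc(ranking, held_out, nonexistent))
            b_vals.append(mean_predicted_betweenness(g_train, ranking.top(L)))
        auc_mean.append(np.mean(a_vals))
        auc_sd.append(np.std(a_vals))
        b_mean.append(np.mean(b_vals))
        b_sd.append(np.std(b_vals))
    return BetaCurve(
        grid=grid,
        auc_values=np.array(auc_mean),
        meanB_values=np.array(b_mean),
        reps=reps,
        auc_std=np.array(auc_sd),
        meanB_std=np.array(b_sd),
    )


def baseline_auc(g_train: nx.Graph, held_out, base_method: str = "CN") -> float:
    """AUC of the plain similarity ranking (CN or RA) on the same held-out
    set — the AUC_o reference for the constrained estimator."""
    held_out = [canon_pair(*e) for e in held_out]
    scored = score_candidates(g_train, base_method)
    ranking = rank_descending(scored)
    held_set = set(held_out)
    nonexistent = [sp.pair for sp in scored if sp.pair not in held_set]
    return auc(ranking, held_out, nonexistent)


def estimate_beta_star(curve: BetaCurve, target_B: float) -> float:
    """The grid beta whose <B>(beta) is closest to ``target_B``; ties break
    toward larger beta (higher AUC)."""
    diffs = np.abs(curve.meanB_values - target_B)
    best = np.flatnonzero(diffs <= diffs.min() + 1e-12)[-1]
    return float(curve.grid[best])


def constrained_beta(
    curve: BetaCurve,
    auc_o: float,
    sacrifice: float = 0.1,
    target_B: float | None = None,
) -> float:
    """Learned beta with an accuracy floor.

    Let floor = (1 - sacrifice) * auc_o. If the <B>-matching beta keeps
    AUC(beta) >= floor it is returned unchanged; otherwise beta is raised to
    the grid point (>= the matching beta) whose AUC is nearest the floor.
    """
    if not 0.0 < sacrifice < 1.0:
        raise ValueError("sacrifice must be in (0, 1)")
    if target_B is None:
        target_B = curve.target_B
    if target_B is None:
        raise ValueError("target_B not given and not stored on the curve")
    floor = (1.0 - sacrifice) * auc_o
    b_match = estimate_beta_star(curve, target_B)
    ix = int(np.searchsorted(curve.grid, b_match))
    if curve.auc_values[ix] >= floor:
        return b_match
    upper = np.arange(ix, len(curve.grid))
    diffs = np.abs(curve.auc_values[upper] - floor)
    best = np.flatnonzero(diffs <= diffs.min() + 1e-12)[-1]
    return float(curve.grid[upper[best]])


@dataclass
class BetaLearningResult:
    beta_hat: float
    curve: BetaCurve
    target_B: float
    auc_o: float
    split: object = field(repr=False, default=None)

    def constrained(self, sacrifice: float = 0.1) -> float:
        return constrained_beta(self.curve, self.auc_o, sacrifice, self.target_B)


def learn_beta_hat(
    g: nx.Graph,
    method: str = "CBCN",
    fractions=(0.8, 0.1, 0.1),
    grid=None,
    reps: int = 10,
    seed=None,
    split=None,
) -> BetaLearningResult:
    """Threefold-validation estimate of beta.

    The observed edges are split into E_T (train), E_L (learn) and E_P
    (probe) per ``fractions``; the target <B> is the mean betweenness of the
    E_L links once added to the E_T graph; beta-hat* matches the curve built
    from E_T against E_L to that target. The probe set is never inspected.
    """
    if split is None:
        if fractions[1] <= 0:
            raise ValueError("learning fraction must be positive")
        split = split_edges(g, fractions, seed=derive_rng(seed, 99).integers(2**31))
    g_train = split.train_graph()
    learn_list = RankedList(list(split.learn))
    target_B = mean_predicted_betweenness(g_train, learn_list)
    curve = beta_curve(
        g_train, split.learn, method=method, grid=grid, reps=reps, seed=seed
    )
    curve.target_B = target_B
    base = method.upper()
    base = base[2:] if base.startswith("CB") else base
    auc_o = baseline_auc(g_train, split.learn, base)
    beta_hat = estimate_beta_star(curve, target_B)
    return BetaLearningResult(beta_hat, curve, target_B, auc_o, split=split)
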