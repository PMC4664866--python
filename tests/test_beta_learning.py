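import networkx as nx
import numpy as np
import pytest

from netmend.beta_learning import (
    BetaCurve,
    baseline_auc,
    beta_curve,
    constrained_beta,
    default_grid,
    estimate_beta_star,
    learn_beta_hat,
)
from netmend.gn_benchmark import generate_gn
from netmend.splits_eval import split_edges


def synthetic_curve(grid, meanB, auc_vals, target=None):
    return BetaCurve(
        grid=np.asarray(grid),
        auc_values=np.asarray(auc_vals),
        meanB_values=np.asarray(meanB),
        reps=1,
        target_B=target,
    )


class TestEstimateBetaStar:
    grid = np.linspace(0, 1, 11)
    meanB = np.linspace(50, 10, 11)  # monotone decreasing in beta

    def test_crossing_point(self):
        curve = synthetic_curve(self.grid, self.meanB, np.ones(11))
        assert estimate_beta_star(curve, 30.0) == pytest.approx(0.5)

    def test_target_above_curve_returns_zero(self):
        curve = synthetic_curve(self.grid, self.meanB, np.ones(11))
        assert estimate_beta_star(curve, 99.0) == 0.0

    def test_target_below_curve_returns_one(self):
        curve = synthetic_curve(self.grid, self.meanB, np.ones(11))
        assert estimate_beta_star(curve, 1.0) == 1.0

    def test_tie_breaks_toward_larger_beta(self):
        curve = synthetic_curve([0.0, 0.5, 1.0], [30, 20, 30], [0.5, 0.6, 0.7])
        assert estimate_beta_star(curve, 30.0) == 1.0


class TestConstrainedBeta:
    grid = np.linspace(0, 1, 11)
    meanB = np.linspace(50, 10, 11)
    auc_vals = np.linspace(0.5, 0.9, 11)  # increasing in beta

    def test_inactive_constraint_returns_match(self):
        curve = synthetic_curve(self.grid, self.meanB, self.auc_vals, target=30.0)
        # floor = 0.9*0.7 = 0.63 <= AUC(0.5) = 0.7
        assert constrained_beta(curve, auc_o=0.7) == pytest.approx(0.5)

    def test_binding_constraint_moves_to_floor_crossing(self):
        curve = synthetic_curve(self.grid, self.meanB, self.auc_vals, target=30.0)
        # floor = 0.9*0.9 = 0.81 -> nearest AUC on beta >= 0.5 is at beta 0.8
        assert constrained_beta(curve, auc_o=0.9) == pytest.approx(0.8)

    def test_constrained_never_below_match(self):
        curve = synthetic_curve(self.grid, self.meanB, self.auc_vals, target=30.0)
        for auc_o in (0.5, 0.7, 0.9, 0.99):
            assert constrained_beta(curve, auc_o) >= 0.5 - 1e-12

    def test_tiny_sacrifice_floor_near_zero(self):
        curve = synthetic_curve(self.grid, self.meanB, self.auc_vals, target=30.0)
        assert constrained_beta(curve, auc_o=0.9, sacrifice=0.999) == 0.5

    def test_invalid_sacrifice_rejected(self):
        curve = synthetic_curve(self.grid, self.meanB, self.auc_vals, target=30.0)
        with pytest.raises(ValueError):
            constrained_beta(curve, auc_o=0.9, sacrifice=0.0)

    def test_missing_target_rejected(self):
        curve = synthetic_curve(self.grid, self.meanB, self.auc_vals)
        with pytest.raises(ValueError):
            constrained_beta(curve, auc_o=0.9)


class TestBetaCurve:
    def test_default_grid(self):
        g = default_grid()
        assert len(g) == 101 and g[0] == 0.0 and g[-1] == 1.0

    def test_endpoints_have_zero_variance(self):
        pg = generate_gn(k_in=14, seed=0)
        split = split_edges(pg.graph, (0.9, 0.0, 0.1), seed=0)
        curve = beta_curve(
            split.train_graph(), split.probe, "CBCN",
            grid=[0.0, 1.0], reps=3, seed=0,
        )
        assert curve.auc_std[0] == pytest.approx(0.0, abs=1e-12)
        assert curve.auc_std[-1] == pytest.approx(0.0, abs=1e-12)
        assert curve.meanB_std[0] == pytest.approx(0.0, abs=1e-12)
        assert curve.meanB_std[-1] == pytest.approx(0.0, abs=1e-12)

    def test_empty_held_out_rejected(self, karate):
        with pytest.raises(ValueError):
            beta_curve(karate, [], "CBCN", grid=[0.0, 1.0], reps=1, seed=0)

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            synthetic_curve([0.5, 0.2], [1, 2], [0.5, 0.5])


class TestLearnBetaHat:
    def test_deterministic_under_seed(self, karate):
        grid = np.linspace(0, 1, 6)
        a = learn_beta_hat(karate, "CBCN", grid=grid, reps=2, seed=3)
        b = learn_beta_hat(karate, "CBCN", grid=grid, reps=2, seed=3)
        assert a.beta_hat == b.beta_hat
        assert np.allclose(a.curve.auc_values, b.curve.auc_values)

    def test_single_community_graph_flat_curve(self):
        # a dense near-clique: one community, so no inter candidates and the
        # interleaved list is beta-independent -> tie-break value returned
        g = nx.complete_graph(8)
        g.remove_edges_from([(0, 1), (2, 3), (4, 5)])
        grid = np.linspace(0, 1, 6)
        res = learn_beta_hat(g, "CBCN", grid=grid, reps=2, seed=0,
                             split=split_edges(g, (0.8, 0.1, 0.1), seed=1))
        assert np.allclose(res.curve.meanB_values, res.curve.meanB_values[0])
        assert res.beta_hat == 1.0  # ties break toward the largest beta

    def test_probe_never_inspected(self, karate):
        grid = np.linspace(0, 1, 6)
        split = split_edges(karate, (0.8, 0.1, 0.1), seed=2)
        a = learn_beta_hat(karate, "CBCN", grid=grid, reps=2, seed=5, split=split)
        corrupted = type(split)(
            train=split.train, learn=split.learn, probe=[], nodes=split.nodes
        )
        b = learn_beta_hat(
            karate, "CBCN", grid=grid, reps=2, seed=5, split=corrupted
        )
        assert a.beta_hat == b.beta_hat and a.auc_o == b.auc_o

    def test_baseline_auc_in_unit_interval(self, karate):
        split = split_edges(karate, (0.9, 0.0, 0.1), seed=0)
        v = baseline_auc(split.train_graph(), split.probe, "RA")
        assert 0.0 <= v <= 1.0
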