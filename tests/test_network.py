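"""Fast layer: graph construction, payoff matrix and fleet extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from centolla import (
    FisherNetwork,
    GameParams,
    NeighborhoodCounts,
    Strategy,
    build_er_network,
    mean_total_profit_sweep,
    neighborhood_counts,
    payoff,
    poisson_mixture_extraction,
    total_extraction,
)


def edgeless(n, strategy):
    return FisherNetwork.from_edges(n, [], strategy)


class TestBuildErNetwork:
    def test_exact_edge_count_and_mean_degree(self, rng):
        net = build_er_network(1000, 1000, rng)
        assert net.m_links == 1000
        assert net.degrees().mean() == pytest.approx(2.0)
        assert net.degrees().sum() == 2 * net.m_links  # handshake lemma

    def test_simple_graph(self, rng):
        net = build_er_network(50, 100, rng)
        assert (net.edges[:, 0] != net.edges[:, 1]).all()
        assert len({tuple(e) for e in net.edges}) == net.m_links

    def test_empty_graph(self, rng):
        net = build_er_network(5, 0, rng)
        assert net.m_links == 0
        assert (net.degrees() == 0).all()

    def test_infeasible_edge_count_rejected(self, rng):
        with pytest.raises(ValueError):
            build_er_network(5, 11, rng)

    def test_default_start_is_all_super(self, rng):
        net = build_er_network(20, 10, rng)
        assert (net.strategies == Strategy.SUPER).all()


class TestNeighborhoodCounts:
    def test_isolated_node(self, rng):
        net = build_er_network(5, 0, rng)
        assert neighborhood_counts(net, 0) == NeighborhoodCounts(0, 0)

    def test_all_super_neighbours(self, rng):
        net = FisherNetwork.from_edges(4, [(0, 1), (0, 2), (0, 3)], Strategy.SUPER)
        assert neighborhood_counts(net, 0) == NeighborhoodCounts(0, 3)

    def test_path_with_mixed_strategies(self):
        # A-B-C with A, C standard and B super
        net = FisherNetwork.from_edges(3, [(0, 1), (1, 2)], [0, 1, 0])
        assert neighborhood_counts(net, 1) == NeighborhoodCounts(2, 0)
        assert neighborhood_counts(net, 0) == NeighborhoodCounts(0, 1)

    def test_counts_sum_to_degree(self, rng):
        net = build_er_network(100, 200, rng)
        net.strategies[:] = rng.integers(0, 2, size=100)
        deg = net.degrees()
        for node in range(100):
            k = neighborhood_counts(net, node)
            assert k.k_c + k.k_d == deg[node]

    def test_unknown_node_rejected(self, rng):
        net = build_er_network(5, 2, rng)
        with pytest.raises(KeyError):
            neighborhood_counts(net, 7)


class TestPayoff:
    def test_isolated_standard_fisher(self):
        gp = GameParams(n=10, a=1.0, psi=0.3, gamma=0.7, m_links=0)
        # bracket is 1 and 1^gamma = 1 for any gamma
        assert payoff(Strategy.STANDARD, NeighborhoodCounts(0, 0), gp, 1.0) == (
            pytest.approx(gp.a / gp.n / 2.0)
        )

    def test_crowded_super_neighbourhood_value(self):
        gp = GameParams(n=1000, a=0.64, psi=0.3, gamma=0.25)
        got = payoff(Strategy.STANDARD, NeighborhoodCounts(0, 2), gp, 1.0)
        assert got == pytest.approx(0.00064 / (1.0 + 1.6**0.25))
        assert got == pytest.approx(3.012e-4, rel=1e-3)

    @given(
        k_c=st.integers(0, 20),
        k_d=st.integers(0, 20),
        psi=st.floats(0.0, 2.0),
        gamma=st.floats(0.0, 1.0),
        a=st.floats(0.0, 2.0),
        x=st.floats(0.0, 1.5),
    )
    def test_super_is_proportional_to_standard(self, k_c, k_d, psi, gamma, a, x):
        """d = (1 + psi) c at equal arguments — the basis of the constant temptation."""
        gp = GameParams(n=100, a=a, psi=psi, gamma=gamma, m_links=0)
        k = NeighborhoodCounts(k_c, k_d)
        c = payoff(Strategy.STANDARD, k, gp, x)
        d = payoff(Strategy.SUPER, k, gp, x)
        assert d == pytest.approx((1.0 + psi) * c, rel=1e-12, abs=1e-300)

    @pytest.mark.parametrize("gamma, strictly", [(0.25, True), (0.0, False)])
    def test_interference_monotonicity(self, gamma, strictly):
        """More competitors never raise the payoff; with gamma=0 they are ignored."""
        gp = GameParams(n=100, a=1.0, psi=0.3, gamma=gamma, m_links=0)
        base = payoff(Strategy.STANDARD, NeighborhoodCounts(0, 0), gp, 1.0)
        for k in [NeighborhoodCounts(1, 0), NeighborhoodCounts(0, 1),
                  NeighborhoodCounts(3, 2)]:
            v = payoff(Strategy.STANDARD, k, gp, 1.0)
            if strictly:
                assert v < base
            else:
                assert v == pytest.approx(base)


class TestTotalExtraction:
    def test_edgeless_all_standard_closed_form(self):
        gp = GameParams(n=50, a=0.8, psi=0.3, gamma=0.25, m_links=0)
        assert total_extraction(edgeless(50, Strategy.STANDARD), gp, 1.0) == (
            pytest.approx(gp.a / 2.0)
        )

    def test_edgeless_all_super_closed_form(self):
        gp = GameParams(n=50, a=0.8, psi=0.3, gamma=0.25, m_links=0)
        assert total_extraction(edgeless(50, Strategy.SUPER), gp, 1.0) == (
            pytest.approx(gp.a * (1.0 + gp.psi) / 2.0)
        )

    def test_hand_summed_small_graph(self):
        """Fleet extraction equals the per-vessel hand sum on a 5-node graph."""
        gp = GameParams(n=5, a=1.0, psi=0.3, gamma=0.25, m_links=4)
        # star centred on 0 plus edge (3, 4); strategies: 0,2 super
        edges = [(0, 1), (0, 2), (0, 3), (3, 4)]
        strategies = [1, 0, 1, 0, 0]
        net = FisherNetwork.from_edges(5, edges, strategies)
        expected = sum(
            payoff(Strategy(strategies[i]), neighborhood_counts(net, i), gp, 0.7)
            for i in range(5)
        )
        assert total_extraction(net, gp, 0.7) == pytest.approx(expected, rel=1e-12)

    def test_scales_linearly_with_stock(self, rng):
        gp = GameParams(n=30, a=1.0, m_links=20)
        net = build_er_network(30, 20, rng)
        full = total_extraction(net, gp, 1.0)
        assert total_extraction(net, gp, 0.25) == pytest.approx(0.25 * full)

    def test_ensemble_matches_poisson_mixture(self, rng):
        """ER(1000, 1000) ensemble mean vs the degree-mixture closed form."""
        gp = GameParams(n=1000, a=0.64, psi=0.3, gamma=0.25, m_links=1000)
        vals = np.array([
            total_extraction(build_er_network(1000, 1000, rng), gp, 1.0)
            for _ in range(200)
        ])
        oracle = poisson_mixture_extraction(gp, Strategy.SUPER, 1.0)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - oracle) < 3.0 * se


class TestProfitSweep:
    def test_zero_interference_collapses_to_closed_form(self, rng):
        """With gamma=0 the bracket term drops and the graph is irrelevant."""
        gp = GameParams(n=200, a=1.0, psi=0.3, m_links=200)
        table = mean_total_profit_sweep(
            [0.0], [0.3], Strategy.SUPER, 5, gp, rng
        )
        assert table["sd"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert table["mean"].iloc[0] == pytest.approx(gp.a * 1.3 / 2.0)

    def test_vanishing_illegal_field_removes_super_premium_and_interference(self):
        """At psi=0 the super premium vanishes (c = d per vessel) and super
        neighbours exert no interference: the bracket k_c + 1 + psi*k_d is 1
        in an all-super fleet, so its profit is flat at a/2 for every gamma,
        while the all-standard fleet still feels its k_c competitors."""
        gp = GameParams(n=200, a=1.0, psi=0.0, m_links=200)
        grid = [0.0, 0.5, 1.0]
        sup = mean_total_profit_sweep(grid, [0.0], Strategy.SUPER, 10,
                                      gp, np.random.default_rng(5))
        std = mean_total_profit_sweep(grid, [0.0], Strategy.STANDARD, 10,
                                      gp, np.random.default_rng(5))
        assert sup["mean"].tolist() == pytest.approx([0.5, 0.5, 0.5])
        assert sup["mean"].iloc[0] == pytest.approx(std["mean"].iloc[0])
        assert (std["mean"].to_numpy()[1:] < 0.5).all()

    def test_profit_decreases_with_interference(self, rng):
        gp = GameParams(n=500, a=1.0, psi=0.3, m_links=500)
        table = mean_total_profit_sweep(
            np.linspace(0.0, 1.0, 5), [0.3], Strategy.SUPER, 30, gp, rng
        )
        means = table["mean"].to_numpy()
        assert (np.diff(means) < 0).all()
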