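import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from blastnet import netsig, simulate


def build_graph(edges, confidence=0.9):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, confidence=confidence)
    return g


class TestFilterGraph:
    def test_threshold_is_inclusive_at_published_value(self):
        g = nx.Graph()
        g.add_edge("a", "b", confidence=0.118)
        g.add_edge("b", "c", confidence=0.119)
        kept = netsig.filter_graph(g, 0.119)
        assert not kept.has_edge("a", "b")
        assert kept.has_edge("b", "c")
        assert set(kept.nodes) == {"a", "b", "c"}  # isolated nodes retained

    def test_zero_threshold_keeps_everything(self):
        g = build_graph([("a", "b"), ("b", "c")], confidence=0.01)
        assert netsig.filter_graph(g, 0.0).number_of_edges() == 2

    @pytest.mark.parametrize("bad", [-0.1, 1.0001])
    def test_invalid_threshold(self, bad):
        with pytest.raises(ValueError):
            netsig.filter_graph(nx.Graph(), bad)


class TestEnumerateNeighborhoods:
    def test_star_hub_takes_whole_star(self, star_graph):
        nets = {n.seed: n for n in netsig.enumerate_neighborhoods(star_graph, (1, 500))}
        assert nets["G0"].members == frozenset(star_graph.nodes)
        assert nets["G1"].members == {"G0", "G1"}

    def test_isolated_node_forms_size_one_network(self):
        g = nx.Graph()
        g.add_node("lonely")
        nets = netsig.enumerate_neighborhoods(g, (1, 500))
        assert len(nets) == 1 and nets[0].n == 1
        assert netsig.enumerate_neighborhoods(g, (3, 500)) == []

    def test_path_center(self):
        g = build_graph([("a", "b"), ("b", "c")])
        nets = {n.seed: n for n in netsig.enumerate_neighborhoods(g, (1, 500))}
        assert nets["b"].members == {"a", "b", "c"}


class TestIrwinHall:
    @pytest.mark.parametrize(
        "p, expected_s, expected_pint",
        [
            ([0.3], 0.3, 0.3),
            ([0.5, 0.5], 1.0, 0.5),
            ([0.1, 0.1, 0.1], 0.3, 0.3**3 / 6),
        ],
    )
    def test_closed_form_anchors(self, p, expected_s, expected_pint):
        S, p_int = netsig.edgington_integrate(p)
        assert S == pytest.approx(expected_s)
        assert p_int == pytest.approx(expected_pint, rel=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            netsig.edgington_integrate([])

    @given(st.integers(min_value=2, max_value=50), st.floats(0.05, 0.95))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_cdf_properties(self, n, frac):
        s = frac * n
        val = netsig.irwin_hall_cdf(s, n)
        assert 0.0 <= val <= 1.0
        # symmetry of the Irwin--Hall distribution about n/2
        assert val == pytest.approx(1.0 - netsig.irwin_hall_cdf(n - s, n), abs=1e-9)
        # monotone in s
        assert val <= netsig.irwin_hall_cdf(min(n, s + 0.1), n) + 1e-12

    def test_gaussian_crossover_is_continuous(self):
        # at n just past the exact/approximate switch the two evaluations agree
        n = netsig.EXACT_IRWIN_HALL_MAX_N
        for frac in (0.4, 0.5, 0.6):
            exact = netsig.irwin_hall_cdf(frac * n, n)
            approx = float(
                __import__("scipy.stats", fromlist=["norm"]).norm.cdf(
                    frac * n, loc=n / 2, scale=math.sqrt(n / 12)
                )
            )
            assert exact == pytest.approx(approx, abs=5e-3)


def chain_plus_star(n_genes, star_members):
    """Graph mapping all genes: a chain over everything plus one star."""
    genes = [f"G{i:04d}" for i in range(n_genes)]
    g = build_graph(list(zip(genes[:-1], genes[1:])))
    for leaf in star_members[1:]:
        g.add_edge(star_members[0], leaf, confidence=0.9)
    return g, genes


class TestPermutationTest:
    def test_unbeatable_network(self):
        genes = [f"G{i:04d}" for i in range(2000)]
        rng = np.random.default_rng(3)
        p = pd.Series(rng.uniform(size=2000), index=genes)
        star = genes[:5]
        p.loc[star] = 1e-6
        g, _ = chain_plus_star(2000, star)
        net = netsig.NeighborhoodNetwork(seed=star[0], members=frozenset(star))
        (score,) = netsig.permutation_test([net], p, n_perm=10_000, seed=0)
        assert score.perm_count == 0
        assert score.p_emp == pytest.approx(1 / 10_001)

    def test_worst_possible_network_has_p_emp_one(self):
        genes = [f"G{i:04d}" for i in range(50)]
        p = pd.Series(np.linspace(0.01, 0.99, 50), index=genes)
        members = frozenset(p.nlargest(3).index)
        seed_gene = sorted(members)[0]
        p.loc[list(members)] = 1.0
        net = netsig.NeighborhoodNetwork(seed=seed_gene, members=members)
        (score,) = netsig.permutation_test([net], p, n_perm=1000, seed=0)
        assert score.p_emp == 1.0

    def test_monotone_in_member_p(self):
        genes = [f"G{i:04d}" for i in range(100)]
        rng = np.random.default_rng(8)
        base = pd.Series(rng.uniform(size=100), index=genes)
        members = frozenset(genes[:6])
        net = netsig.NeighborhoodNetwork(seed=genes[0], members=members)
        (before,) = netsig.permutation_test([net], base, n_perm=2000, seed=11)
        improved = base.copy()
        improved.loc[genes[1]] = improved.loc[genes[1]] / 10
        (after,) = netsig.permutation_test([net], improved, n_perm=2000, seed=11)
        assert after.S <= before.S
        assert after.p_int <= before.p_int
        assert after.perm_count <= before.perm_count

    def test_excluded_members_are_counted(self):
        p = pd.Series({"a": 0.1, "b": 0.2})
        net = netsig.NeighborhoodNetwork(seed="a", members=frozenset({"a", "b", "zz"}))
        (score,) = netsig.permutation_test([net], p, n_perm=1000, seed=0)
        assert score.n_mapped == 2 and score.n_excluded == 1
        assert score.S == pytest.approx(0.3)

    def test_refuses_small_n_perm(self):
        p = pd.Series({"a": 0.1, "b": 0.2})
        net = netsig.NeighborhoodNetwork(seed="a", members=frozenset({"a", "b"}))
        with pytest.raises(ValueError, match="unstable"):
            netsig.permutation_test([net], p, n_perm=999, seed=0)


class TestSelection:
    def _score(self, seed, perm_count, n_perm, S=0.5, n=5):
        net = netsig.NeighborhoodNetwork(
            seed=seed, members=frozenset([seed] + [f"{seed}_{i}" for i in range(n - 1)])
        )
        return netsig.NetworkScore(
            network=net, n_mapped=n, n_excluded=0, S=S,
            p_int=netsig.irwin_hall_cdf(S, n), perm_count=perm_count, n_perm=n_perm,
        )

    def test_strict_count_rule_at_published_scale(self):
        ok = self._score("a", 999, 10_000_000)
        borderline = self._score("b", 1000, 10_000_000)
        selected = netsig.select_networks([ok, borderline], selection_rate=1e-4)
        assert [s.network.seed for s in selected] == ["a"]
        assert ok.selected and not borderline.selected

    def test_scaled_rule_at_desk_n_perm(self):
        zero = self._score("a", 0, 100_000)
        nine = self._score("b", 9, 100_000)
        ten = self._score("c", 10, 100_000)
        selected = netsig.select_networks([zero, nine, ten], selection_rate=1e-4)
        assert {s.network.seed for s in selected} == {"a", "b"}

    def test_order_invariance(self):
        scores = [self._score(s, c, 100_000) for s, c in [("a", 3), ("b", 1), ("c", 2)]]
        fwd = [s.network.seed for s in netsig.select_networks(scores, 1e-3)]
        rev = [s.network.seed for s in netsig.select_networks(scores[::-1], 1e-3)]
        assert fwd == rev == ["b", "c", "a"]


class TestPipelineAndFdr:
    def test_planted_network_detected_and_deterministic(self, small_config):
        graph = simulate.generate_ppi_graph(small_config)
        seed_node = max(graph.degree, key=lambda kv: kv[1])[0]
        small_config.planted_networks = [
            simulate.PlantedNetwork(seed=seed_node, effect_log2=2.5)
        ]
        matrix, labels, _ = simulate.generate_expression(small_config, graph)
        cfg = netsig.NetsigConfig(n_perm=2000, confidence_threshold=0.0, seed=4)
        scores1, sel1 = netsig.run_netsig(matrix, labels, graph, cfg)
        scores2, sel2 = netsig.run_netsig(matrix, labels, graph, cfg)
        assert any(s.network.seed == seed_node for s in sel1)
        assert [s.perm_count for s in scores1] == [s.perm_count for s in scores2]

    def test_fdr_with_signal_is_below_null_level(self, small_config):
        graph = simulate.generate_ppi_graph(small_config)
        seed_node = max(graph.degree, key=lambda kv: kv[1])[0]
        small_config.planted_networks = [
            simulate.PlantedNetwork(seed=seed_node, effect_log2=2.5)
        ]
        matrix, labels, _ = simulate.generate_expression(small_config, graph)
        cfg = netsig.NetsigConfig(
            n_perm=1000, confidence_threshold=0.0, seed=4,
            selection_rate=1e-3, n_label_perms=5,
        )
        est = netsig.estimate_fdr(matrix, labels, graph, cfg)
        assert est.n_selected_observed >= 1
        assert est.fdr is not None and est.fdr < 0.5

    def test_fdr_undefined_without_observed_selections(self, small_config):
        graph = simulate.generate_ppi_graph(small_config)
        matrix, labels, _ = simulate.generate_expression(small_config, graph)
        cfg = netsig.NetsigConfig(
            n_perm=1000, confidence_threshold=0.0, seed=4,
            selection_rate=1e-6, n_label_perms=3,
        )
        est = netsig.estimate_fdr(matrix, labels, graph, cfg)
        assert est.fdr is None and "undefined" in est.note
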