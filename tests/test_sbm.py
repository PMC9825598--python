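"""Layered block model: description length, incremental moves, annealing,
layer randomisation and back-projection."""

import math

import numpy as np
import pytest

from ldgraph.benchmarks import (exhaustive_min_sigma, planted_partition_graph,
                                random_small_graph, set_partitions)
from ldgraph.evaluate import adjusted_rand
from ldgraph.graphs import NodeTable
from ldgraph.grid import make_grid
from ldgraph.sbm import (BlockState, LayeredGraph, ModelComparison, SBMError,
                         anneal, backproject, description_length,
                         init_partition, mcmc_sweep, randomize_layers)


def path_graph():
    return LayeredGraph(4, np.array([[0, 1], [1, 2], [2, 3]]),
                        np.array([0.2, 0.5, 0.8]), np.array([1, 2, 3]))


def two_cliques(w_lo=0.15, w_hi=0.85):
    """Two disconnected triangles with distinct layer-A means."""
    edges = np.array([[0, 1], [0, 2], [1, 2], [3, 4], [3, 5], [4, 5]])
    w = np.array([w_lo] * 3 + [w_hi] * 3)
    c = np.array([2, 3, 2, 9, 8, 9])
    return LayeredGraph(6, edges, w, c)


class TestDescriptionLength:
    def test_single_block_structure_term_closed_form(self):
        """At B=1 the structure term reduces to E + E ln(2E)."""
        br = description_length(path_graph(), [0, 0, 0, 0])
        E = 3
        assert br["structure"] == pytest.approx(E + E * math.log(2 * E))

    def test_breakdown_sums_to_total(self):
        g = random_small_graph(4)
        b = np.arange(g.n_nodes) % 3
        br = description_length(g, b)
        parts = br["structure"] + br["partition"] + br["layer_A"] + br["layer_C"]
        assert br["total"] == pytest.approx(parts)

    def test_label_permutation_invariance(self):
        g = random_small_graph(5)
        b = np.arange(g.n_nodes) % 2
        s1 = description_length(g, b)["total"]
        s2 = description_length(g, 1 - b)["total"]
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_unassigned_node_rejected(self):
        with pytest.raises(SBMError):
            description_length(path_graph(), [0, 0, 0])

    def test_missing_count_layer_contributes_zero(self):
        g = LayeredGraph(3, np.array([[0, 1], [1, 2]]), np.array([0.3, 0.7]))
        br = description_length(g, [0, 0, 1])
        assert br["layer_C"] == 0.0


class TestIncrementalMoves:
    @pytest.mark.parametrize("seed", [3, 17, 91])
    def test_incremental_equals_recount_along_chain(self, seed):
        """After any sequence of accepted moves the incrementally maintained
        Sigma equals a from-scratch recount to 1e-8."""
        g = random_small_graph(seed)
        st = BlockState(g, np.zeros(g.n_nodes, int))
        rng = np.random.default_rng(seed)
        for _ in range(120):
            v = int(rng.integers(g.n_nodes))
            t = int(rng.integers(g.n_nodes + 2))
            d = st.move_delta(v, t)
            st.apply_move(v, t, d)
        assert st.sigma == pytest.approx(st.recount(), abs=1e-8)

    def test_merge_delta_consistent_with_merge(self):
        g = random_small_graph(7)
        st = BlockState(g, np.arange(g.n_nodes))
        blocks = list(st.n_r)
        d = st.merge_delta(blocks[0], blocks[1])
        before = st.sigma
        st.apply_merge(blocks[0], blocks[1])
        assert st.sigma == pytest.approx(before + d, abs=1e-8)

    def test_greedy_merge_limit_only_downhill(self):
        """At very large beta only Sigma-non-increasing moves are accepted."""
        g = random_small_graph(13)
        st = BlockState(g, np.arange(g.n_nodes))
        rng = np.random.default_rng(0)
        prev = st.sigma
        for _ in range(10):
            mcmc_sweep(st, 1e6, rng)
            assert st.sigma <= prev + 1e-4
            prev = st.sigma


class TestInitAndAnneal:
    def test_two_cliques_merge_to_two_blocks(self):
        """Exhaustive oracle confirms the 2-block optimum; greedy
        agglomeration reaches it."""
        g = two_cliques()
        opt, b_opt = exhaustive_min_sigma(g)
        assert len(np.unique(b_opt)) == 2
        st = init_partition(g, "singletons_merge", seed=0)
        assert st.sigma == pytest.approx(opt, abs=1e-9)

    def test_frozen_optimum_survives_cold_sweeps(self):
        g = two_cliques()
        opt, b_opt = exhaustive_min_sigma(g)
        st = BlockState(g, b_opt)
        rng = np.random.default_rng(1)
        for _ in range(10):
            mcmc_sweep(st, 1e6, rng)
        assert st.sigma == pytest.approx(opt, abs=1e-9)

    def test_init_deterministic(self):
        g = random_small_graph(21)
        a = init_partition(g, "singletons_merge", seed=4)
        b = init_partition(g, "singletons_merge", seed=4)
        assert np.array_equal(a.b, b.b)
        r1 = init_partition(g, "random_B", seed=9, B=3)
        r2 = init_partition(g, "random_B", seed=9, B=3)
        assert np.array_equal(r1.b, r2.b)

    def test_anneal_never_worse_than_init(self):
        g = random_small_graph(33)
        init = init_partition(g, "singletons_merge", seed=2)
        best = anneal(g, wait=10, seed=2, max_sweeps_per_stage=30)
        assert best.sigma <= init.sigma + 1e-9

    def test_anneal_deterministic_under_seed(self):
        g = random_small_graph(44)
        a = anneal(g, wait=10, seed=5, max_sweeps_per_stage=30)
        b = anneal(g, wait=10, seed=5, max_sweeps_per_stage=30)
        assert a.sigma == pytest.approx(b.sigma)
        assert np.array_equal(a.b, b.b)

    def test_recovery_degrades_as_separation_vanishes(self):
        """Mean ARI over seeds is non-increasing (Spearman rho > 0 against
        separation) as the planted layer-A contrast shrinks to zero."""
        from scipy.stats import spearmanr
        levels = [1.0, 0.75, 0.5, 0.25, 0.0]
        means = []
        for sep in levels:
            aris = []
            for seed in (1, 2, 3):
                g, truth = planted_partition_graph(
                    n_nodes=120, p_in=0.2, p_out=0.07, separation=sep, seed=seed)
                fit = anneal(g, wait=15, seed=seed, max_sweeps_per_stage=50)
                aris.append(adjusted_rand(fit.b, truth))
            means.append(np.mean(aris))
        rho, _ = spearmanr(levels, means)
        assert rho > 0


class TestLayerRandomisation:
    def test_deterministic_and_involution(self):
        g = random_small_graph(55)
        a = randomize_layers(g, seed=8)
        b = randomize_layers(g, seed=8)
        assert np.allclose(a.weight_A, b.weight_A)
        back = randomize_layers(a, seed=8)
        assert np.allclose(back.weight_A, g.weight_A)
        assert np.array_equal(back.count_C, g.count_C)

    def test_swap_fraction_near_half(self):
        n = 10001
        edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
        g = LayeredGraph(n, edges, np.linspace(0, 1, n - 1),
                         np.arange(n - 1) % 7)
        out = randomize_layers(g, seed=3)
        frac = out.swap_mask.mean()
        # binomial 99.9% interval at E=10000
        assert abs(frac - 0.5) < 3.3 * 0.5 / math.sqrt(n - 1)

    def test_single_layer_rejected(self):
        g = LayeredGraph(3, np.array([[0, 1], [1, 2]]), np.array([0.3, 0.7]))
        with pytest.raises(SBMError):
            randomize_layers(g, seed=0)


class TestComparisonAndBackprojection:
    def test_odds_arithmetic(self):
        cmp = ModelComparison(sigma_layered=4.0, sigma_null=10.0)
        assert cmp.delta == pytest.approx(6.0)
        assert cmp.log10_posterior_odds == pytest.approx(6.0 / math.log(10))

    def _nodes(self, n):
        return NodeTable(np.array([[i, 0, 0] for i in range(n)]),
                         make_grid((n, 1, 1)))

    def test_node_mean_incident(self):
        g = LayeredGraph(3, np.array([[0, 1], [1, 2]]), np.array([0.2, 0.4]),
                         np.array([1, 1]))
        st = BlockState(g, [0, 0, 0])
        m = backproject(st, self._nodes(3), layer="A",
                        aggregation="node_mean_incident")
        assert m.data[1, 0, 0] == pytest.approx(0.3)
        assert m.data[0, 0, 0] == pytest.approx(0.2)

    def test_block_mean_single_edge_block(self):
        g = LayeredGraph(2, np.array([[0, 1]]), np.array([0.7]), np.array([2]))
        st = BlockState(g, [0, 0])
        m = backproject(st, self._nodes(2), layer="A", aggregation="block_mean")
        assert np.allclose(m.data[:2, 0, 0], 0.7)

    def test_full_map_matches_hand_enumeration(self):
        g = two_cliques()
        st = BlockState(g, [0, 0, 0, 1, 1, 1])
        m = backproject(st, self._nodes(6), layer="A",
                        aggregation="node_mean_incident")
        # every node has two incident edges of its clique's weight
        assert np.allclose(m.data[:3, 0, 0], 0.15)
        assert np.allclose(m.data[3:6, 0, 0], 0.85)
        mc = backproject(st, self._nodes(6), layer="C",
                         aggregation="block_mean")
        assert np.allclose(mc.data[:3, 0, 0], (2 + 3 + 2) / 3)

    def test_unknown_layer_rejected(self):
        g = two_cliques()
        st = BlockState(g, [0] * 6)
        with pytest.raises(SBMError):
            backproject(st, self._nodes(6), layer="Z")


def test_set_partition_enumeration_counts_bell_numbers():
    assert sum(1 for _ in set_partitions(4)) == 15
    assert sum(1 for _ in set_partitions(8)) == 4140
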