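"""Graph construction from masks: resampling, node/edge enumeration,
two-layer assembly and filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldgraph.cohort import LesionMask
from ldgraph.graphs import (GraphConstructionError, NodeTable,
                            assemble_group_graph, build_patient_edge_vector,
                            complete_pair_edges, enumerate_nodes, filter_graph,
                            md_involvement, patient_weight, resample_mask,
                            spatial_adjacency_edges)
from ldgraph.grid import GeometryError, make_grid

from conftest import mask_from_voxels, record


class TestResample:
    def test_constant_block_stays_lesioned(self):
        grid = make_grid((4, 4, 4))
        m = LesionMask("p", np.ones(grid.shape, np.uint8), grid)
        out = resample_mask(m, (4, 4, 4))
        assert out.grid.shape == (1, 1, 1) and out.data[0, 0, 0] == 1

    def test_minority_block_cleared_majority_kept(self):
        grid = make_grid((2, 2, 4))
        data = np.zeros(grid.shape, np.uint8)
        # first 2x2x2 block: 3 of 8 lesioned -> 0; second: 4 of 8 -> 1 (tie)
        data[0, 0, 0] = data[0, 1, 0] = data[1, 0, 0] = 1
        data[0, 0, 2] = data[0, 1, 2] = data[1, 0, 2] = data[1, 1, 2] = 1
        out = resample_mask(LesionMask("p", data, grid), (2, 2, 2))
        assert out.data[0, 0, 0] == 0 and out.data[0, 0, 1] == 1

    def test_non_integer_ratio_rejected(self):
        grid = make_grid((4, 4, 4))
        m = LesionMask("p", np.ones(grid.shape, np.uint8), grid)
        with pytest.raises(GeometryError):
            resample_mask(m, (3, 3, 3))


class TestNodesAndEdges:
    def test_lesioned_anywhere_counts(self, small_grid):
        m1 = mask_from_voxels(small_grid, [(4, 4, 4), (4, 4, 5), (4, 5, 4),
                                           (5, 4, 4), (5, 5, 5)])
        assert len(enumerate_nodes([m1], small_grid)) == 5
        m2 = mask_from_voxels(small_grid, [(2, 2, 2), (2, 2, 3), (2, 3, 2),
                                           (7, 7, 7)], "p1")
        assert len(enumerate_nodes([m1, m2], small_grid)) == 9

    def test_node_ordering_stable(self, small_grid):
        m = mask_from_voxels(small_grid, [(5, 5, 5), (2, 2, 2), (7, 3, 4)])
        a = enumerate_nodes([m], small_grid)
        b = enumerate_nodes([m], small_grid)
        assert np.array_equal(a.voxel_indices, b.voxel_indices)
        assert (np.diff(a.flat_index()) > 0).all()  # lexicographic

    @pytest.mark.parametrize("n,expected", [(2, 1), (10, 45), (1017, 516636)])
    def test_complete_pair_count(self, n, expected):
        nodes = NodeTable(np.argwhere(np.ones((n, 1, 1), bool)),
                          make_grid((n, 1, 1)))
        assert len(complete_pair_edges(nodes)) == expected

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 2000))
    def test_complete_pair_closed_form(self, n):
        nodes = NodeTable(np.argwhere(np.ones((n, 1, 1), bool)),
                          make_grid((n, 1, 1)))
        assert len(complete_pair_edges(nodes)) == n * (n - 1) // 2

    def test_single_node_rejected(self):
        nodes = NodeTable(np.array([[0, 0, 0]]), make_grid((2, 2, 2)))
        with pytest.raises(GraphConstructionError):
            complete_pair_edges(nodes)

    def test_face_adjacency(self, small_grid):
        nodes = NodeTable(np.array([[2, 2, 2], [2, 2, 3]]), small_grid)
        assert len(spatial_adjacency_edges(nodes, 6)) == 1

    def test_corner_adjacency_only_at_26(self, small_grid):
        nodes = NodeTable(np.array([[2, 2, 2], [3, 3, 3]]), small_grid)
        assert len(spatial_adjacency_edges(nodes, 6)) == 0
        assert len(spatial_adjacency_edges(nodes, 26)) == 1

    def test_cube_all_pairs_adjacent_at_26(self, small_grid):
        """Brute-force oracle: in a 2x2x2 cube every pair is within the
        26-neighbourhood, so the edge set is all 28 pairs."""
        vox = np.array([(i, j, k) for i in (2, 3) for j in (2, 3) for k in (2, 3)])
        nodes = NodeTable(vox, small_grid)
        brute = sum(1 for a in range(8) for b in range(a + 1, 8)
                    if (np.abs(vox[a] - vox[b]) <= 1).all())
        edges = spatial_adjacency_edges(nodes, 26)
        assert brute == 28 and len(edges) == 28

    def test_invalid_connectivity_rejected(self, small_grid):
        nodes = NodeTable(np.array([[1, 1, 1], [1, 1, 2]]), small_grid)
        with pytest.raises(GraphConstructionError):
            spatial_adjacency_edges(nodes, 10)


class TestEdgeVectorsAndAssembly:
    def test_edge_vector_definition_on_path(self, small_grid):
        # nodes a-b-c in a line; only a, b lesioned -> exactly edge (a,b)
        nodes = NodeTable(np.array([[2, 2, 2], [2, 2, 3], [2, 2, 4]]), small_grid)
        edges = spatial_adjacency_edges(nodes, 6)
        m = mask_from_voxels(small_grid, [(2, 2, 2), (2, 2, 3)])
        vec = build_patient_edge_vector(m, nodes, edges)
        assert vec.sum() == 1
        assert vec[np.where((edges.pairs == [0, 1]).all(axis=1))[0][0]] == 1

    def test_edge_vector_full_lesion(self, small_grid):
        nodes = NodeTable(np.array([[2, 2, 2], [2, 2, 3], [2, 2, 4]]), small_grid)
        edges = complete_pair_edges(nodes)
        m = mask_from_voxels(small_grid, [(2, 2, 2), (2, 2, 3), (2, 2, 4)])
        assert build_patient_edge_vector(m, nodes, edges).all()

    def test_patient_weight_readings(self):
        r = record(score=12.0, nart=120.0)
        assert patient_weight(r, "nart_over_score") == pytest.approx(10.0)
        assert patient_weight(r, "inv_score_over_nart") == pytest.approx(
            1.0 / (12.0 * 120.0))
        assert patient_weight(record(score=0.0, nart=100.0)) == pytest.approx(200.0)

    def test_three_patient_toy_matches_hand_enumeration(self, small_grid):
        """Brute-force oracle over three overlapping 2-voxel lesions."""
        v1, v2 = (3, 3, 3), (3, 3, 4)
        masks = [mask_from_voxels(small_grid, [v1, v2], f"p{i}") for i in range(3)]
        masks[2] = mask_from_voxels(small_grid, [v1], "p2")  # damages one node only
        records = [record("p0", 12.0, 120.0), record("p1", 6.0, 120.0),
                   record("p2", 3.0, 120.0)]
        nodes = enumerate_nodes(masks, small_grid)
        edges = spatial_adjacency_edges(nodes, 6)
        g = assemble_group_graph(masks, records, nodes, edges)
        assert g.n_edges == 1
        assert g.cooccurrence[0] == 2  # p2 damages only one endpoint
        # contributing means: (120/12 + 120/6)/2 = 15; single edge rescales to 0.5
        assert g.deficit_weight[0] == pytest.approx(0.5)

    def test_unlesioned_edges_absent(self, small_grid):
        m = mask_from_voxels(small_grid, [(3, 3, 3), (3, 3, 4)])
        nodes = NodeTable(np.array([[3, 3, 3], [3, 3, 4], [6, 6, 6]]), small_grid)
        edges = complete_pair_edges(nodes)
        g = assemble_group_graph([m], [record()], nodes, edges)
        assert g.n_edges == 1

    def test_cooccurrence_bounded_by_lesion_frequency(self, scored_cohort,
                                                      small_grid):
        cfg, masks, records, _ = scored_cohort
        nodes = enumerate_nodes(masks, small_grid)
        edges = spatial_adjacency_edges(nodes, 26)
        g = assemble_group_graph(masks, records, nodes, edges)
        freq = np.zeros(len(nodes), dtype=int)
        flat = nodes.flat_index()
        for m in masks:
            freq += m.data.ravel()[flat]
        e = g.edges.pairs
        assert (g.cooccurrence <= len(masks)).all()
        assert (g.cooccurrence <= np.minimum(freq[e[:, 0]], freq[e[:, 1]])).all()

    def test_patient_vector_sum_consistency(self, scored_cohort, small_grid):
        """Sum of per-patient edge vectors equals the assembled counts."""
        cfg, masks, records, _ = scored_cohort
        nodes = enumerate_nodes(masks, small_grid)
        edges = spatial_adjacency_edges(nodes, 26)
        g = assemble_group_graph(masks, records, nodes, edges)
        total = sum(build_patient_edge_vector(m, nodes, edges).astype(int)
                    for m in masks)
        kept = total[total > 0]
        assert np.array_equal(np.sort(kept), np.sort(g.cooccurrence))


class TestFilter:
    def test_noop_filter(self, small_grid):
        masks = [mask_from_voxels(small_grid, [(3, 3, 3), (3, 3, 4)], f"p{i}")
                 for i in range(5)]
        recs = [record(f"p{i}") for i in range(5)]
        nodes = enumerate_nodes(masks, small_grid)
        edges = spatial_adjacency_edges(nodes, 6)
        g = assemble_group_graph(masks, recs, nodes, edges)
        out = filter_graph(g, node_quantile=0.0, min_count=1)
        assert out.n_nodes == g.n_nodes and out.n_edges == g.n_edges

    def test_degree_tie_rule_keeps_median(self, small_grid):
        # path graph: end nodes degree 1, middle degree 2; median degree
        # threshold with >= tie rule keeps everything at quantile 0.5 when
        # the median equals the minimum
        masks = [mask_from_voxels(small_grid,
                                  [(3, 3, 3), (3, 3, 4), (3, 3, 5)], f"p{i}")
                 for i in range(4)]
        recs = [record(f"p{i}") for i in range(4)]
        nodes = enumerate_nodes(masks, small_grid)
        edges = spatial_adjacency_edges(nodes, 6)
        g = assemble_group_graph(masks, recs, nodes, edges)
        out = filter_graph(g, node_quantile=0.5, min_count=1)
        deg = g.degrees()
        expected = (deg >= np.quantile(deg, 0.5)).sum()
        assert out.n_nodes <= expected  # isolated-node drop may shrink further

    def test_filtered_sizes_match_recount_oracle(self, scored_cohort, small_grid):
        """Exhaustive recount of the surviving order and size."""
        cfg, masks, records, _ = scored_cohort
        nodes = enumerate_nodes(masks, small_grid)
        edges = spatial_adjacency_edges(nodes, 26)
        g = assemble_group_graph(masks, records, nodes, edges)
        out = filter_graph(g, node_quantile=0.5, min_count=3)
        deg = g.degrees()
        thresh = np.quantile(deg, 0.5)
        keep_node = deg >= thresh
        e = g.edges.pairs
        keep_edge = (keep_node[e[:, 0]] & keep_node[e[:, 1]]
                     & (g.cooccurrence >= 3))
        surviving_nodes = len(np.unique(e[keep_edge]))
        assert out.n_edges == int(keep_edge.sum())
        assert out.n_nodes == surviving_nodes

    def test_filter_to_empty_raises(self, small_grid):
        m = mask_from_voxels(small_grid, [(3, 3, 3), (3, 3, 4)])
        nodes = enumerate_nodes([m], small_grid)
        edges = spatial_adjacency_edges(nodes, 6)
        g = assemble_group_graph([m], [record()], nodes, edges)
        with pytest.raises(GraphConstructionError):
            filter_graph(g, min_count=5)


class TestMDInvolvement:
    def test_subset_is_100(self, small_grid):
        m = mask_from_voxels(small_grid, [(3, 3, 3), (3, 3, 4)])
        tmpl = np.zeros(small_grid.shape, bool)
        tmpl[3] = True
        assert md_involvement(m, tmpl) == 100.0

    def test_disjoint_is_0(self, small_grid):
        m = mask_from_voxels(small_grid, [(3, 3, 3)])
        tmpl = np.zeros(small_grid.shape, bool)
        tmpl[7] = True
        assert md_involvement(m, tmpl) == 0.0

    def test_partial_fraction(self, small_grid):
        vox = [(3, 3, k) for k in range(10)]
        m = mask_from_voxels(small_grid, vox)
        tmpl = np.zeros(small_grid.shape, bool)
        for k in range(3):
            tmpl[3, 3, k] = True
        assert md_involvement(m, tmpl) == pytest.approx(30.0)
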