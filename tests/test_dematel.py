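"""DEMATEL: aggregation, normalisation, total influence, INRM, retest."""

import numpy as np
import pytest

from danpv.dematel import (
    DirectMatrix,
    NormalizedMatrix,
    TotalInfluenceMatrix,
    aggregate_panel,
    build_inrm,
    causal_profile,
    dimension_priority,
    dimension_total_influence,
    normalize,
    retest_consistency,
    total_influence,
)
from danpv.framework import make_framework

from conftest import random_substochastic


def neumann_series(d, terms=60):
    """Independent oracle: T = sum of D^k for k >= 1, truncated."""
    total = np.zeros_like(d)
    power = np.eye(d.shape[0])
    for _ in range(terms):
        power = power @ d
        total += power
    return total


class TestAggregate:
    def test_elementwise_mean(self):
        a = DirectMatrix(np.array([[0.0, 2], [4, 0]]))
        b = DirectMatrix(np.array([[0.0, 4], [0, 0]]))
        out = aggregate_panel([a, b])
        assert np.array_equal(out.values, [[0, 3], [2, 0]])

    def test_single_matrix_identity(self):
        a = DirectMatrix(np.array([[0.0, 1], [2, 0]]))
        assert np.array_equal(aggregate_panel([a]).values, a.values)

    def test_nine_equal_matrices_idempotent(self):
        a = DirectMatrix(np.array([[0.0, 3], [1, 0]]))
        out = aggregate_panel([a] * 9)
        assert np.array_equal(out.values, a.values)

    def test_shape_mismatch(self):
        a = DirectMatrix(np.zeros((2, 2)))
        b = DirectMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="shape"):
            aggregate_panel([a, b])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            DirectMatrix(np.array([[1.0, 2], [3, 0]]))


class TestNormalize:
    def test_max_sum_divisor(self):
        d = normalize(DirectMatrix(np.array([[0.0, 2], [4, 0]])))
        assert np.allclose(d.values, [[0, 0.5], [1, 0]])

    def test_zero_matrix(self):
        d = normalize(DirectMatrix(np.zeros((3, 3))))
        assert np.all(d.values == 0)

    def test_symmetric_ones(self):
        m = np.ones((3, 3)) - np.eye(3)
        d = normalize(DirectMatrix(m))
        assert np.allclose(d.values, m / 2)

    def test_row_and_column_sums_bounded(self, rng):
        m = rng.integers(0, 5, size=(8, 8)).astype(float)
        np.fill_diagonal(m, 0)
        d = normalize(DirectMatrix(m))
        assert d.values.sum(axis=1).max() <= 1 + 1e-12
        assert d.values.sum(axis=0).max() <= 1 + 1e-12


class TestTotalInfluence:
    def test_nilpotent_no_indirect_paths(self):
        t = total_influence(NormalizedMatrix(np.array([[0.0, 0.5], [0, 0]])))
        assert np.allclose(t.values, [[0, 0.5], [0, 0]])

    def test_scalar_geometric_series(self):
        t = total_influence(NormalizedMatrix(np.array([[0.5]])))
        assert t.values[0, 0] == pytest.approx(1.0)

    def test_matches_neumann_series_oracle(self, rng):
        for _ in range(5):
            d = random_substochastic(rng, 4)
            t = total_influence(NormalizedMatrix(d))
            assert np.allclose(t.values, neumann_series(d), atol=1e-8)

    def test_closed_form_identity(self, rng):
        d = random_substochastic(rng, 6)
        t = total_influence(NormalizedMatrix(d)).values
        assert np.max(np.abs(t - (d + d @ t))) < 1e-10

    def test_ill_conditioned_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            total_influence(NormalizedMatrix(np.array([[1.0]])))


class TestDimensionLevel:
    def test_constant_matrix(self, tiny_framework):
        t_c = TotalInfluenceMatrix(np.full((4, 4), 0.3))
        t_d = dimension_total_influence(t_c, tiny_framework)
        assert np.allclose(t_d.values, 0.3)

    def test_singleton_blocks_identity(self):
        fw = make_framework({"D1": ["C1"], "D2": ["C2"]})
        t_c = TotalInfluenceMatrix(np.array([[0.1, 0.2], [0.3, 0.4]]))
        t_d = dimension_total_influence(t_c, fw)
        assert np.array_equal(t_d.values, t_c.values)

    def test_block_mean_by_hand(self, tiny_framework):
        m = np.zeros((4, 4))
        m[0:2, 2:4] = [[1, 3], [5, 7]]
        t_d = dimension_total_influence(TotalInfluenceMatrix(m), tiny_framework)
        assert t_d.values[0, 1] == 4.0

    def test_commutes_with_scaling(self, tiny_framework, rng):
        m = rng.random((4, 4))
        one = dimension_total_influence(TotalInfluenceMatrix(m), tiny_framework)
        two = dimension_total_influence(TotalInfluenceMatrix(2.5 * m), tiny_framework)
        assert np.allclose(two.values, 2.5 * one.values)


class TestCausalProfile:
    def test_symmetric_matrix_zero_relation(self, rng):
        m = rng.random((5, 5))
        m = (m + m.T) / 2
        prof = causal_profile(TotalInfluenceMatrix(m))
        assert np.allclose(prof.relation, 0)

    def test_single_edge(self):
        prof = causal_profile(TotalInfluenceMatrix(np.array([[0.0, 1], [0, 0]])))
        assert np.array_equal(prof.relation, [1, -1])

    def test_conservation_identities(self, rng):
        m = rng.random((6, 6))
        prof = causal_profile(TotalInfluenceMatrix(m))
        assert prof.prominence.sum() == pytest.approx(2 * m.sum())
        assert prof.relation.sum() == pytest.approx(0, abs=1e-12)


class TestDimensionPriority:
    def test_sorted_by_relation(self):
        prof = causal_profile(
            TotalInfluenceMatrix(np.array([[0.0, 0.4], [0, 0]]), codes=("Da", "Db"))
        )
        assert dimension_priority(prof) == ["Da", "Db"]

    def test_prescribed_order_from_constructed_matrix(self):
        # rows with descending constant levels induce relation in that order;
        # verified against the definition r - c computed by plain sums
        codes = ("D2", "D3", "D5", "D1", "D4", "D6")
        levels = [0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
        m = np.array([[lv] * 6 for lv in levels])
        np.fill_diagonal(m, 0)
        prof = causal_profile(TotalInfluenceMatrix(m, codes=codes))
        expected = sorted(
            range(6), key=lambda i: -(m[i].sum() - m[:, i].sum())
        )
        assert dimension_priority(prof) == [codes[i] for i in expected]
        assert dimension_priority(prof) == list(codes)

    def test_all_equal_preserves_input_order(self):
        m = np.full((3, 3), 0.2)
        np.fill_diagonal(m, 0)
        prof = causal_profile(TotalInfluenceMatrix(m, codes=("X", "Y", "Z")))
        assert dimension_priority(prof) == ["X", "Y", "Z"]


class TestInrm:
    def _graphs(self, t_d, codes):
        t = TotalInfluenceMatrix(t_d, level="dimension", codes=codes)
        prof = causal_profile(t)
        return build_inrm(t, t, prof, prof)

    def test_single_dominant_edge(self):
        m = np.array([[0.0, 1.0], [0.1, 0.0]])
        inrm = self._graphs(m, ("D1", "D2"))
        assert list(inrm.dimension_graph.edges) == [("D1", "D2")]

    def test_constant_off_diagonal_gives_complete_digraph(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 0)
        inrm = self._graphs(m, ("A", "B", "C"))
        assert inrm.dimension_graph.number_of_edges() == 6  # threshold inclusive

    def test_node_coordinates_are_prominence_relation(self):
        m = np.array([[0.0, 1.0], [0.1, 0.0]])
        inrm = self._graphs(m, ("D1", "D2"))
        node = inrm.dimension_graph.nodes["D1"]
        assert node["prominence"] == pytest.approx(1.1)
        assert node["relation"] == pytest.approx(0.9)

    def test_dot_export_contains_edges(self):
        m = np.array([[0.0, 1.0], [0.1, 0.0]])
        dot = self._graphs(m, ("D1", "D2")).to_dot("dimension")
        assert '"D1" -> "D2"' in dot


class TestRetest:
    def test_identical_matrices(self):
        m = np.random.default_rng(0).random((4, 4))
        report = retest_consistency(m, m)
        assert report.total_abs_diff == 0
        assert report.mean_abs_diff == 0

    def test_published_scale_arithmetic(self):
        # a 16x16 questionnaire pair with total difference 4.791 averages
        # below the 0.019-per-entry consistency bound
        m1 = np.zeros((16, 16))
        m2 = np.zeros((16, 16))
        m2[0, 1] = 4.791
        report = retest_consistency(m1, m2)
        assert report.n_pairs == 256
        assert report.mean_abs_diff == pytest.approx(4.791 / 256)
        assert report.mean_abs_diff < 0.019

    def test_single_cell_difference(self):
        a = np.zeros((2, 2))
        b = a.copy()
        b[0, 1] = 1
        report = retest_consistency(a, b)
        assert report.total_abs_diff == 1
        assert report.mean_abs_diff == 0.25

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            retest_consistency(np.zeros((2, 2)), np.zeros((3, 3)))
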