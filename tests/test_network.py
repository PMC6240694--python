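"""Correlation, adjacency, TOM and consensus-calibration mathematics."""

import numpy as np
import pandas as pd
import pytest

from coexnet import (
    AdjacencyMatrix,
    ExpressionMatrix,
    TOMMatrix,
    ValidationError,
    calibrate_toms,
    consensus_tom,
    signed_adjacency,
    spearman_correlation,
    topological_overlap,
)


def _expr_from_rows(rows: dict[str, list[float]]) -> ExpressionMatrix:
    frame = pd.DataFrame(rows).T
    frame.columns = [f"s{i}" for i in range(frame.shape[1])]
    return ExpressionMatrix(frame)


def random_adjacency(rng: np.random.Generator, n: int) -> AdjacencyMatrix:
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(tuple(f"G{i}" for i in range(n)), a)


def tom_brute_force(a: np.ndarray) -> np.ndarray:
    """Triple-loop oracle for the topological overlap formula."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


class TestSpearman:
    def test_monotone_transform_gives_perfect_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        cor = spearman_correlation(
            _expr_from_rows({"x": x, "y": list(np.exp(x))})
        )
        assert cor.values[0, 1] == pytest.approx(1.0)

    def test_reversed_profile_gives_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        cor = spearman_correlation(_expr_from_rows({"x": x, "y": [-v for v in x]}))
        assert cor.values[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        # ranks of y=(1,3,2,4) against x=(1,2,3,4): Pearson on ranks = 0.8
        cor = spearman_correlation(
            _expr_from_rows({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        )
        assert cor.values[0, 1] == pytest.approx(0.8)

    def test_constant_gene_gets_zero_correlation(self):
        cor = spearman_correlation(
            _expr_from_rows({"x": [1, 2, 3, 4], "c": [5, 5, 5, 5]})
        )
        assert cor.values[0, 1] == 0.0
        assert cor.values[1, 1] == 1.0

    def test_invariant_under_monotone_per_gene_transforms(self, tiny_expression):
        base = spearman_correlation(tiny_expression)
        frame = tiny_expression.frame.copy()
        transforms = [np.exp, lambda v: v**3, lambda v: 5 * v - 2]
        for i in range(frame.shape[0]):
            frame.iloc[i] = transforms[i % 3](frame.iloc[i])
        trans = spearman_correlation(ExpressionMatrix(frame))
        np.testing.assert_allclose(base.values, trans.values, atol=1e-12)

    def test_needs_four_samples(self):
        with pytest.raises(ValidationError):
            spearman_correlation(_expr_from_rows({"x": [1, 2, 3], "y": [1, 2, 3]}))


class TestSignedAdjacency:
    @pytest.mark.parametrize(
        "r, expected",
        [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5**10)],
    )
    def test_closed_form_values(self, r, expected):
        cor = spearman_correlation(
            _expr_from_rows({"x": [1, 2, 3, 4], "y": [4, 3, 2, 1]})
        )
        values = cor.values.copy()
        values[0, 1] = values[1, 0] = r
        adj = signed_adjacency(type(cor)(cor.gene_ids, values), beta=10)
        assert adj.values[0, 1] == pytest.approx(expected, abs=1e-15)

    def test_beta_below_one_rejected(self):
        cor = spearman_correlation(
            _expr_from_rows({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        )
        with pytest.raises(ValidationError):
            signed_adjacency(cor, beta=0.5)


class TestTopologicalOverlap:
    def test_two_gene_network_equals_adjacency(self):
        for a12 in (0.2, 0.7, 1.0):
            adj = AdjacencyMatrix(
                ("A", "B"), np.array([[1.0, a12], [a12, 1.0]])
            )
            tom = topological_overlap(adj)
            assert tom.values[0, 1] == pytest.approx(a12)

    def test_complete_unit_graph_has_full_overlap(self):
        adj = AdjacencyMatrix(tuple("ABCDE"), np.ones((5, 5)))
        tom = topological_overlap(adj)
        np.testing.assert_allclose(tom.values, 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            adj = random_adjacency(rng, 15)
            tom = topological_overlap(adj)
            np.testing.assert_allclose(
                tom.values, tom_brute_force(adj.values), atol=1e-10
            )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        adj = random_adjacency(rng, 12)
        perm = rng.permutation(12)
        permuted = AdjacencyMatrix(
            tuple(np.array(adj.gene_ids)[perm]), adj.values[np.ix_(perm, perm)]
        )
        tom = topological_overlap(adj)
        tom_p = topological_overlap(permuted)
        np.testing.assert_allclose(
            tom_p.values, tom.values[np.ix_(perm, perm)], atol=1e-12
        )

    def test_block_size_guard(self):
        rng = np.random.default_rng(0)
        adj = random_adjacency(rng, 30)
        with pytest.raises(ValidationError, match="filter"):
            topological_overlap(adj, max_block_size=20)

    def test_bounds_and_symmetry_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            tom = topological_overlap(random_adjacency(rng, 20))
            assert tom.values.min() >= 0.0 and tom.values.max() <= 1.0
            np.testing.assert_allclose(tom.values, tom.values.T, atol=1e-12)


class TestCalibrationAndConsensus:
    def _random_tom(self, rng, n=20):
        return topological_overlap(random_adjacency(rng, n))

    def test_identical_inputs_scale_by_one(self):
        rng = np.random.default_rng(5)
        tom = self._random_tom(rng)
        out = calibrate_toms([tom, tom, tom])
        assert out[0].calibration.scale_factors == pytest.approx((1.0, 1.0, 1.0))

    def test_halved_tom_is_rescaled_to_equal_quantile(self):
        rng = np.random.default_rng(6)
        tom = self._random_tom(rng)
        halved_values = np.clip(tom.values * 0.5, 0, 1)
        np.fill_diagonal(halved_values, 1.0)
        halved = TOMMatrix(tom.gene_ids, halved_values)
        out = calibrate_toms([tom, halved], quantile=0.95)
        iu = np.triu_indices(tom.n_genes, k=1)
        q0 = np.quantile(out[0].values[iu], 0.95)
        q1 = np.quantile(out[1].values[iu], 0.95)
        assert q0 == pytest.approx(q1, abs=1e-12)

    def test_three_random_toms_share_quantile_after_calibration(self):
        rng = np.random.default_rng(7)
        toms = [self._random_tom(rng) for _ in range(3)]
        out = calibrate_toms(toms, quantile=0.95)
        iu = np.triu_indices(toms[0].n_genes, k=1)
        qs = [np.quantile(t.values[iu], 0.95) for t in out]
        # the reference (median) quantile stays; the others are scaled to it
        assert max(qs) - min(qs) < 1e-12

    def test_mismatched_gene_sets_report_difference(self):
        rng = np.random.default_rng(8)
        t1 = self._random_tom(rng, 10)
        t2 = topological_overlap(random_adjacency(rng, 10))
        t2 = TOMMatrix(tuple(f"H{i}" for i in range(10)), t2.values)
        with pytest.raises(ValidationError, match="symmetric difference"):
            calibrate_toms([t1, t2])

    def test_consensus_is_entrywise_minimum(self):
        rng = np.random.default_rng(9)
        toms = calibrate_toms([self._random_tom(rng) for _ in range(2)])
        cons = consensus_tom(toms)
        assert cons.is_consensus
        iu = np.triu_indices(cons.n_genes, k=1)
        expected = np.minimum(toms[0].values, toms[1].values)
        np.testing.assert_allclose(cons.values[iu], expected[iu], atol=0)
        assert np.all(cons.values[iu] <= toms[0].values[iu] + 1e-15)
        assert np.all(cons.values[iu] <= toms[1].values[iu] + 1e-15)

    def test_consensus_of_identical_toms_is_identity(self):
        rng = np.random.default_rng(10)
        tom = self._random_tom(rng)
        cons = consensus_tom(calibrate_toms([tom, tom]))
        np.testing.assert_allclose(cons.values, tom.values, atol=1e-12)
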