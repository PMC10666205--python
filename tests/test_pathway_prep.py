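import numpy as np
import pytest
from scipy import stats

import regenne as rg
from regenne.containers import ExpressionMatrix, PathwayCollection, ValidationError
from regenne.pathway_prep import (
    build_pathway_tensors,
    match_pathway_genes,
    order_genes,
    overlap_summary,
    row_aggregate,
    spearman_matrix,
)


def oracle_order(block):
    """Brute-force reference: rank-then-Pearson correlations, geometric-mean
    aggregate, argsort descending with stable index tie-break."""
    ranks = np.column_stack([stats.rankdata(c) for c in block.T])
    corr = np.corrcoef(ranks, rowvar=False)
    corr = np.atleast_2d(corr)
    absr = np.abs(corr)
    scores = np.prod(np.maximum(absr, 1e-12), axis=1) ** (1.0 / absr.shape[1])
    return np.argsort(-scores, kind="stable")


class TestSpearmanMatrix:
    def test_perfect_monotone_and_reversed(self):
        block = np.array([[1, 10, 3], [2, 20, 2], [3, 30, 1]], dtype=float)
        rho = spearman_matrix(block)
        assert rho[0, 1] == pytest.approx(1.0)
        assert rho[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(rho, rho.T)

    def test_five_point_value_matches_rank_pearson_oracle(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = np.array([1, 3, 2, 5, 4], dtype=float)
        rho = spearman_matrix(np.column_stack([x, y]))
        expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho[0, 1] == pytest.approx(expected)
        assert rho[0, 1] == pytest.approx(0.8)

    def test_zero_variance_column_gets_zero_correlation(self):
        block = np.column_stack([np.arange(5.0), np.ones(5)])
        rho = spearman_matrix(block)
        assert rho[0, 1] == 0.0 and rho[1, 1] == 1.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            spearman_matrix(np.ones((1, 3)))


class TestRowAggregate:
    def test_duplicated_columns_score_one(self):
        corr = np.ones((4, 4))
        np.testing.assert_allclose(row_aggregate(corr), 1.0)

    def test_single_gene_scores_one(self):
        np.testing.assert_allclose(row_aggregate(np.ones((1, 1))), [1.0])

    def test_geometric_mean_closed_form(self):
        corr = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        scores = row_aggregate(corr)
        assert scores[0] == pytest.approx((1.0 * 0.5 * 0.2) ** (1 / 3), abs=1e-12)
        assert scores[0] == pytest.approx(0.4642, abs=1e-4)

    def test_sign_ignored(self):
        corr = np.array([[1.0, -0.5], [-0.5, 1.0]])
        np.testing.assert_allclose(row_aggregate(corr), row_aggregate(np.abs(corr)))


class TestOrderGenes:
    def test_matches_bruteforce_oracle_on_random_blocks(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            block = rng.standard_normal((60, 12))
            op = order_genes(block)
            np.testing.assert_array_equal(op.gene_order, oracle_order(block))

    def test_scores_non_increasing(self):
        rng = np.random.default_rng(5)
        op = order_genes(rng.standard_normal((40, 9)))
        assert np.all(np.diff(op.row_scores) <= 1e-15)

    def test_equal_scores_preserve_original_order(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(30)
        block = np.column_stack([col, col, col])  # all scores identical
        op = order_genes(block)
        np.testing.assert_array_equal(op.gene_order, [0, 1, 2])

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(2)
        block = rng.standard_normal((50, 8))
        perm = rng.permutation(50)
        np.testing.assert_array_equal(
            order_genes(block).gene_order, order_genes(block[perm]).gene_order
        )

    def test_duplicated_gene_copies_rise_to_top_adjacent(self):
        rng = np.random.default_rng(4)
        block = rng.standard_normal((80, 5))
        dup = np.column_stack([block, block[:, 2]])  # copy of column 2
        order = order_genes(dup).gene_order
        assert {order[0], order[1]} == {2, 5}

    def test_aggregate_choice_is_order_equivalent_for_geometric_family(self):
        # any strictly increasing transform of the product of |rho| gives the
        # same permutation; compare geometric mean vs log-sum directly
        rng = np.random.default_rng(9)
        block = rng.standard_normal((50, 10))
        corr = spearman_matrix(block)
        geo = row_aggregate(corr, "geometric")
        logsum = np.log(np.maximum(np.abs(corr), 1e-12)).sum(axis=1)
        np.testing.assert_array_equal(
            np.argsort(-geo, kind="stable"), np.argsort(-logsum, kind="stable")
        )


class TestMatchAndBuild:
    def _expr(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(8)]
        return ExpressionMatrix(
            [f"s{i}" for i in range(30)], genes, rng.standard_normal((30, 8))
        )

    def test_matches_intersection_and_drops_small(self):
        expr = self._expr()
        coll = PathwayCollection.from_mapping(
            {"A": ["G0", "G1", "G9"], "B": ["G9"], "C": ["G2", "G3", "G4", "G5"]}
        )
        tset = match_pathway_genes(expr, coll, min_genes=2)
        assert tset.names == ["A", "C"]
        assert tset.blocks[0].shape == (30, 2)
        assert ("B", "too_few_genes") in tset.dropped_pathways

    def test_shared_gene_appears_in_both_blocks(self):
        expr = self._expr()
        coll = PathwayCollection.from_mapping(
            {"A": ["G0", "G1", "G2"], "B": ["G2", "G3", "G4"]}
        )
        tset = match_pathway_genes(expr, coll, min_genes=2)
        col = expr.values[:, 2]
        np.testing.assert_array_equal(tset.blocks[0][:, 2], col)
        np.testing.assert_array_equal(tset.blocks[1][:, 0], col)

    def test_no_surviving_pathway_is_error(self):
        expr = self._expr()
        coll = PathwayCollection.from_mapping({"A": ["X1", "X2", "X3", "X4", "X5"]})
        with pytest.raises(ValidationError):
            match_pathway_genes(expr, coll, min_genes=5)

    def test_narrow_pathway_padded_to_min_length(self):
        expr = self._expr()
        coll = PathwayCollection.from_mapping({"A": ["G0", "G1", "G2"]})
        tset = build_pathway_tensors(expr, coll, min_genes=3)
        pw = tset.pathways[0]
        assert pw.n_padded == 1 and pw.width == 4
        assert tset.blocks[0].shape == (30, 4)
        np.testing.assert_array_equal(tset.blocks[0][:, 3], 0.0)

    def test_blocks_follow_gene_order(self):
        expr = self._expr()
        coll = PathwayCollection.from_mapping({"A": [f"G{i}" for i in range(8)]})
        tset = build_pathway_tensors(expr, coll)
        pw = tset.pathways[0]
        np.testing.assert_array_equal(
            tset.blocks[0], expr.values[:, pw.column_indices]
        )
        assert np.all(np.diff(pw.row_scores) <= 1e-15)


class TestOverlapSummary:
    def test_counts_and_row_count(self):
        coll = PathwayCollection.from_mapping(
            {
                "A": ["G1", "G2", "G3"],
                "B": ["G2", "G3", "G4"],
                "C": ["X1", "X2"],
                "D": ["G1", "X1"],
                "E": ["Y1"],
            }
        )
        df = overlap_summary(coll)
        assert len(df) == 10  # k(k-1)/2 for k=5
        ab = df[(df.pathway_a == "A") & (df.pathway_b == "B")].shared_genes.iloc[0]
        assert ab == 2
        ce = df[(df.pathway_a == "C") & (df.pathway_b == "E")].shared_genes.iloc[0]
        assert ce == 0

    def test_consistent_with_simulated_overlap(self, small_bundle):
        df = overlap_summary(small_bundle.pathways)
        n_shared = int(np.ceil(0.5 * 10))  # small preset: overlap_frac=0.5
        names = small_bundle.pathways.names
        for a, b in zip(names[:-1], names[1:]):
            row = df[(df.pathway_a == a) & (df.pathway_b == b)]
            assert row.shared_genes.iloc[0] == n_shared
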