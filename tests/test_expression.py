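"""Quantile normalization, tissue enrichment and expression trees."""

import numpy as np
import pandas as pd
import pytest

from treexpress.expression import (EnrichedGeneSet, ExpressionTable,
                                   build_expression_tree,
                                   cross_database_check,
                                   expression_tree_table,
                                   quantile_normalize, tissue_divergence,
                                   tissue_enriched_genes)
from treexpress.species import SpeciesSet


def _table(values, species, tissues, genes=None, normalized=False):
    cols = pd.MultiIndex.from_product([species, tissues],
                                      names=["species", "tissue"])
    genes = genes or [f"g{i}" for i in range(len(values))]
    return ExpressionTable(pd.DataFrame(values, index=genes, columns=cols),
                           normalized=normalized)


class TestQuantileNormalize:
    def test_worked_example(self):
        t = _table([[5, 4], [2, 1], [3, 2]], ["h"], ["a", "b"])
        # columns are (h,a)=[5,2,3] and (h,b)=[4,1,2]
        out = quantile_normalize(t)
        assert out.data[("h", "a")].tolist() == [4.5, 1.5, 2.5]
        assert out.data[("h", "b")].tolist() == [4.5, 1.5, 2.5]

    def test_identical_columns_fixed_point(self):
        t = _table([[5, 5], [1, 1], [3, 3]], ["h"], ["a", "b"])
        out = quantile_normalize(t)
        assert np.array_equal(out.data.to_numpy(), t.data.to_numpy())

    def test_ties_get_mean_of_reference(self):
        t = _table([[1, 10], [1, 20], [2, 30]], ["h"], ["a", "b"])
        out = quantile_normalize(t)
        ref = [(1 + 10) / 2, (1 + 20) / 2, (2 + 30) / 2]
        expected_tied = (ref[0] + ref[1]) / 2
        assert out.data[("h", "a")].tolist() == [expected_tied, expected_tied, ref[2]]

    def test_all_order_statistics_identical(self):
        rng = np.random.default_rng(0)
        t = _table(rng.gamma(2.0, 3.0, (200, 6)), ["h", "c"], ["a", "b", "c"])
        out = quantile_normalize(t)
        cols = out.data.to_numpy()
        ref = np.sort(cols[:, 0])
        for j in range(cols.shape[1]):
            assert np.array_equal(np.sort(cols[:, j]), ref)

    def test_double_normalization_rejected(self):
        t = _table([[1, 2]], ["h"], ["a", "b"])
        with pytest.raises(ValueError):
            quantile_normalize(quantile_normalize(t))


class TestEnrichment:
    def _norm_table(self, rows, tissues, species=("h", "c")):
        vals = np.repeat(np.asarray(rows, dtype=float), len(species), axis=0)
        # interleave so each species carries the same tissue profile
        data = np.column_stack([np.asarray(rows, dtype=float)[:, t]
                                for _s in species for t in range(len(tissues))])
        return _table(data, list(species), list(tissues), normalized=True)

    def test_fold_rule_and_inclusive_boundary(self):
        tissues = ["brain", "liver", "lung"]
        rows = [
            [10, 1, 1],   # 10 >= 5*1 -> enriched in brain
            [5, 1, 1],    # exactly 5x -> still enriched ("at least")
            [4.9, 1, 1],  # below the boundary
        ]
        t = self._norm_table(rows, tissues)
        got = tissue_enriched_genes(t, "brain")
        assert got.genes == {"g0", "g1"}

    def test_zero_denominator_rules(self):
        tissues = ["brain", "liver", "lung"]
        rows = [[3, 0, 0], [0, 0, 0]]
        t = self._norm_table(rows, tissues)
        got = tissue_enriched_genes(t, "brain")
        assert got.genes == {"g0"}

    def test_exactly_100_fails_strict_size_filter(self):
        tissues = ["brain", "liver", "lung"]
        rows = [[10, 1, 1]] * 100 + [[1, 1, 1]] * 50
        t = self._norm_table(rows, tissues)
        got = tissue_enriched_genes(t, "brain")
        assert len(got.genes) == 100
        assert not got.passed_size_filter
        rows.append([10, 1, 1])
        t2 = self._norm_table(rows, tissues)
        assert tissue_enriched_genes(t2, "brain").passed_size_filter

    def test_order_invariance(self):
        tissues = ["brain", "liver", "lung"]
        rng = np.random.default_rng(1)
        rows = rng.gamma(1.0, 5.0, (40, 3))
        t = self._norm_table(rows, tissues)
        base = tissue_enriched_genes(t, "brain").genes
        shuffled = ExpressionTable(
            t.data.sample(frac=1, random_state=0)[
                [c for c in t.data.columns[::-1]]
            ],
            normalized=True,
        )
        assert tissue_enriched_genes(shuffled, "brain").genes == base


class TestExpressionTrees:
    def test_delta_example(self, trio):
        t = _table([[1, 3, 6]], ["s1", "s2", "s3"], ["brain"],
                   genes=["g0"], normalized=True)
        vec = build_expression_tree(t, "g0", "brain", trio)
        assert vec.values.tolist() == [2.0, 5.0, 3.0]

    def test_translation_invariance(self, trio):
        base = _table([[1, 3, 6]], ["s1", "s2", "s3"], ["brain"],
                      genes=["g0"], normalized=True)
        shifted = _table([[11, 13, 16]], ["s1", "s2", "s3"], ["brain"],
                         genes=["g0"], normalized=True)
        a = build_expression_tree(base, "g0", "brain", trio)
        b = build_expression_tree(shifted, "g0", "brain", trio)
        assert np.allclose(a.values, b.values)

    def test_triangle_inequality(self, trio):
        rng = np.random.default_rng(2)
        t = _table(rng.random((20, 3)) * 10, ["s1", "s2", "s3"], ["brain"],
                   normalized=True)
        tab = expression_tree_table(t, t.genes, "brain", trio)
        ab = tab["s1|s2"].to_numpy()
        ac = tab["s1|s3"].to_numpy()
        bc = tab["s2|s3"].to_numpy()
        assert np.all(ab <= ac + bc + 1e-12)
        assert np.all(ac <= ab + bc + 1e-12)

    def test_divergence_pythagoras(self, trio):
        t = _table([[0, 3, 0], [0, 4, 0]], ["s1", "s2", "s3"], ["brain"],
                   normalized=True)
        vec = tissue_divergence(t, "brain", trio)
        assert vec.distance("s1", "s2") == pytest.approx(5.0)
        assert vec.distance("s1", "s3") == 0.0

    def test_divergence_decomposition(self, trio):
        rng = np.random.default_rng(3)
        t = _table(rng.random((15, 3)) * 4, ["s1", "s2", "s3"], ["brain"],
                   normalized=True)
        total = tissue_divergence(t, "brain", trio)
        per_gene = expression_tree_table(t, t.genes, "brain", trio)
        assert np.allclose(total.values ** 2,
                           (per_gene.to_numpy() ** 2).sum(axis=0))


class TestCrossDatabase:
    def _pair(self, rho, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        tissues = ["liver", "kidney", "muscle", "lung"]
        x = rng.standard_normal((n, 4))
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal((n, 4))
        a = quantile_normalize(_table(2.0 ** (5 + x), ["h"], tissues))
        b = quantile_normalize(_table(2.0 ** (5 + y), ["h"], tissues))
        return a, b, tissues

    def test_identity_gives_r_one(self):
        a, _b, tissues = self._pair(0.5)
        r = cross_database_check(a, a, tissues)
        assert np.allclose(r.to_numpy(), 1.0)

    def test_recovers_planted_correlation(self):
        a, b, tissues = self._pair(0.99, seed=4)
        r = cross_database_check(a, b, tissues)
        assert np.all(np.abs(r.to_numpy() - 0.99) < 0.01)

    def test_independent_columns_near_zero(self):
        a, b, tissues = self._pair(0.0, seed=5)
        r = cross_database_check(a, b, tissues)
        assert np.all(np.abs(r.to_numpy()) < 0.05)

    def test_empty_intersection_errors(self):
        a, b, tissues = self._pair(0.5)
        b.data.index = [f"x{i}" for i in range(len(b.data))]
        with pytest.raises(ValueError):
            cross_database_check(a, b, tissues)
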