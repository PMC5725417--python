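"""Tree correlation, permutation null, KS/KW tests and ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from treexpress.association import (CorrelationSample, Density,
                                    ZeroVarianceError, bonferroni,
                                    bootstrap_null, compare_distributions,
                                    correlation_distribution,
                                    kruskal_2samp_sorted, ks_2samp_sorted,
                                    pearson_rows, rank_signature_genes,
                                    tree_correlation, AssociationResult)
from treexpress.trees import PairDistanceVector


class TestTreeCorrelation:
    def test_identity_and_antisymmetry(self, trio):
        g = PairDistanceVector(trio, [0.1, 0.5, 0.3])
        e = PairDistanceVector(trio, [0.1, 0.5, 0.3])
        assert tree_correlation(g, e) == pytest.approx(1.0)
        anti = PairDistanceVector(trio, [0.9, 0.5, 0.7])  # -g + 1
        assert tree_correlation(g, anti) == pytest.approx(-1.0)

    def test_worked_value(self):
        assert tree_correlation([0, 1, 2], [0, 2, 3]) == pytest.approx(
            0.981981, abs=1e-6
        )

    def test_zero_variance_signals(self, trio):
        g = PairDistanceVector(trio, [0.2, 0.2, 0.2])
        e = PairDistanceVector(trio, [0.1, 0.5, 0.3])
        with pytest.raises(ZeroVarianceError):
            tree_correlation(g, e)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        g, e = rng.random(15), rng.random(15)
        base = tree_correlation(g, e)
        assert tree_correlation(3.2 * g + 1.1, e) == pytest.approx(base, abs=1e-12)
        assert tree_correlation(g, 0.5 * e + 7.0) == pytest.approx(base, abs=1e-12)

    def test_pearson_rows_matches_scipy(self):
        rng = np.random.default_rng(1)
        G, E = rng.random((30, 15)), rng.random((30, 15))
        r = pearson_rows(G, E)
        for i in range(30):
            assert r[i] == pytest.approx(stats.pearsonr(G[i], E[i])[0], abs=1e-12)


class TestDensity:
    def test_area_is_one(self):
        rng = np.random.default_rng(2)
        d = Density.from_sample(rng.uniform(-1, 1, 500))
        assert d.area == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_top_bin(self):
        d = Density.from_sample(np.ones(50))
        assert d.area == pytest.approx(1.0, abs=1e-9)
        assert np.count_nonzero(d.density) == 1


def _cell_tables(n=40, seed=0, coupled=False):
    rng = np.random.default_rng(seed)
    G = rng.random((n, 15))
    E = G + 0.05 * rng.standard_normal((n, 15)) if coupled \
        else rng.random((n, 15))
    genes = [f"g{i}" for i in range(n)]
    cols = [f"p{k}" for k in range(15)]
    return (pd.DataFrame(G, index=genes, columns=cols),
            pd.DataFrame(E, index=genes, columns=cols), genes)


class TestNull:
    def test_identity_permutation_equals_observed(self):
        G, E, genes = _cell_tables()
        sample, _ = correlation_distribution("r", "t", genes, G, E)
        ident = np.tile(np.arange(len(genes)), (5, 1))
        null = bootstrap_null("r", {"t": (G, E)}, iterations=5,
                              permutations=ident)
        assert np.allclose(np.sort(null.values.reshape(5, -1)[0]),
                           np.sort(sample.values))

    def test_seed_reproducibility(self):
        G, E, _ = _cell_tables()
        a = bootstrap_null("r", {"t": (G, E)}, iterations=20, seed=42)
        b = bootstrap_null("r", {"t": (G, E)}, iterations=20, seed=42)
        assert np.array_equal(a.values, b.values)
        c = bootstrap_null("r", {"t": (G, E)}, iterations=20, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_iterations_validated(self):
        G, E, _ = _cell_tables()
        with pytest.raises(ValueError):
            bootstrap_null("r", {"t": (G, E)}, iterations=0)

    def test_density_averaged_over_tissues(self):
        G, E, _ = _cell_tables()
        G2, E2, _ = _cell_tables(seed=9)
        null = bootstrap_null("r", {"t1": (G, E), "t2": (G2, E2)},
                              iterations=10)
        assert null.density.area == pytest.approx(1.0, abs=1e-9)
        assert set(null.n_per_tissue) == {"t1", "t2"}


class TestDistributionTests:
    def test_ks_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.standard_normal(rng.integers(10, 60))
            b = rng.standard_normal(rng.integers(200, 2000)) + 0.2
            d, p = ks_2samp_sorted(a, np.sort(b))
            ref = stats.ks_2samp(a, b, method="asymp")
            assert d == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-6, abs=1e-12)

    def test_ks_brute_force_statistic(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(30)
        b = rng.standard_normal(45)
        d, _ = ks_2samp_sorted(a, np.sort(b))
        grid = np.concatenate([a, b])
        ecdf_a = np.array([(a <= x).mean() for x in grid])
        ecdf_b = np.array([(b <= x).mean() for x in grid])
        assert d == pytest.approx(np.abs(ecdf_a - ecdf_b).max(), abs=1e-12)

    def test_kruskal_matches_scipy_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.standard_normal(rng.integers(10, 60))
            b = rng.standard_normal(rng.integers(100, 800)) + 0.3
            h, p = kruskal_2samp_sorted(a, np.sort(b))
            ref = stats.kruskal(a, b)
            assert h == pytest.approx(ref.statistic, rel=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_kruskal_close_with_heavy_ties(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 10, 50).astype(float)
        b = rng.integers(0, 10, 500).astype(float)
        h, _ = kruskal_2samp_sorted(a, np.sort(b))
        ref = stats.kruskal(a, b)
        # only the tie-correction divisor is omitted
        assert h == pytest.approx(ref.statistic, rel=2e-2)

    def test_shift_detected_and_self_comparison_quiet(self):
        rng = np.random.default_rng(7)
        from treexpress.association import NullDistribution

        null_values = rng.uniform(-0.6, 0.6, 20000)
        null = NullDistribution("r", null_values,
                                Density.from_sample(null_values), 100, 0)
        same = CorrelationSample("r", "t", [f"g{i}" for i in range(300)],
                                 null_values[:300])
        res = compare_distributions(same, null)
        assert res.ks_p > 0.05
        shifted = CorrelationSample("r", "t", [f"g{i}" for i in range(300)],
                                    np.clip(null_values[:300] + 0.5, -1, 1))
        res2 = compare_distributions(shifted, null)
        assert res2.ks_p < 1e-6
        assert res2.shift == "positive"


class TestCorrectionAndRanking:
    def _res(self, p):
        return AssociationResult("r", "t", 10, 0.1, p, 0.1, p, 0.0, 0.0, "positive")

    @pytest.mark.parametrize("raw,m,expected", [
        (0.001, 48, 0.048),
        (0.5, 48, 1.0),
        (0.01, 1, 0.01),
    ])
    def test_bonferroni(self, raw, m, expected):
        (res,) = bonferroni([self._res(raw)], family_size=m)
        assert res.ks_p_bonf == pytest.approx(expected)

    def test_family_defaults_to_cell_count(self):
        results = bonferroni([self._res(0.01) for _ in range(4)])
        assert results[0].ks_p_bonf == pytest.approx(0.04)

    def test_rank_signature_genes(self):
        sample = CorrelationSample("r", "t", ["a", "b", "c"],
                                   np.array([0.9, 0.1, 0.5]))
        top2 = rank_signature_genes(sample, 2)
        assert top2["gene_id"].tolist() == ["a", "c"]
        assert rank_signature_genes(sample, 0).empty
        assert len(rank_signature_genes(sample, 10)) == 3

    def test_rank_ties_broken_lexicographically(self):
        sample = CorrelationSample("r", "t", ["z", "a", "m"],
                                   np.array([0.5, 0.5, 0.5]))
        assert rank_signature_genes(sample, 3)["gene_id"].tolist() == ["a", "m", "z"]


class TestObservedDistribution:
    def test_all_equal_trees_all_ones(self):
        G, _, genes = _cell_tables()
        sample, dens = correlation_distribution("r", "t", genes, G, G.copy())
        assert np.allclose(sample.values, 1.0)
        assert dens.area == pytest.approx(1.0, abs=1e-9)

    def test_independent_trees_centered(self):
        G, E, genes = _cell_tables(n=300, seed=8)
        sample, _ = correlation_distribution("r", "t", genes, G, E)
        assert abs(sample.values.mean()) < 0.1

    def test_too_few_genes_errors(self):
        G, E, genes = _cell_tables(n=2)
        with pytest.raises(ValueError):
            correlation_distribution("r", "t", genes, G, E)

    def test_zero_variance_genes_dropped_with_reason(self):
        G, E, genes = _cell_tables(n=10)
        G.iloc[0] = 0.5
        sample, _ = correlation_distribution("r", "t", genes, G, E)
        assert ("g0", "zero variance") in sample.dropped
        assert len(sample.genes) == 9
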