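import numpy as np
import pandas as pd
import pytest

from degfunnel.coexpression import (
    CoexpressionError,
    adjacency,
    correlate_with_trait,
    correlation_matrix,
    detect_modules,
    module_eigengene,
    module_refine_degs,
    module_trait_analysis,
    pick_soft_threshold,
    scale_free_fit,
    select_modules,
    tom_similarity,
)
from tests.conftest import make_expression


def brute_force_tom(A):
    """Naive O(n³) topological overlap for cross-checking."""
    A = np.asarray(A, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    k = A.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (L + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return tom


class TestTOM:
    def test_uniform_adjacency_closed_form(self):
        # 3 genes with a_ij = a everywhere: TOM_ij = (a² + a)/(2a + 1 − a) = a
        for a in (0.2, 0.5, 0.9):
            A = np.full((3, 3), a)
            np.fill_diagonal(A, 0.0)
            tom = tom_similarity(A)
            off = tom[~np.eye(3, dtype=bool)]
            np.testing.assert_allclose(off, a, rtol=1e-12)

    def test_zero_adjacency(self):
        tom = tom_similarity(np.zeros((4, 4)))
        assert np.allclose(tom, np.eye(4))

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(2)
        C = rng.uniform(-1, 1, size=(20, 20))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        A = adjacency(C, power=6)
        tom = tom_similarity(A)
        np.testing.assert_allclose(tom, brute_force_tom(A), rtol=1e-10)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12

    def test_constant_gene_rejected(self):
        vals = np.vstack([np.ones(12), np.random.default_rng(0).normal(size=(3, 12))])
        em = make_expression(vals, 6)
        with pytest.raises(CoexpressionError, match="constant"):
            correlation_matrix(em.values)


class TestDetectModules:
    def _blocks(self, size):
        n = 2 * size
        D = np.ones((n, n))
        D[:size, :size] = 0.0
        D[size:, size:] = 0.0
        np.fill_diagonal(D, 0.0)
        return D

    def test_two_separated_blocks(self):
        labels = detect_modules(self._blocks(40), min_module_size=30)
        assert sorted(pd.Series(labels).value_counts().tolist()) == [40, 40]
        assert set(labels) == {1, 2}

    def test_blocks_below_min_size_go_grey(self):
        labels = detect_modules(self._blocks(20), min_module_size=30)
        assert (labels == 0).all()

    def test_fewer_genes_than_min_size_all_grey(self):
        with pytest.warns(UserWarning, match="min_module_size"):
            labels = detect_modules(np.zeros((5, 5)), min_module_size=30)
        assert (labels == 0).all()

    def test_labels_ordered_by_decreasing_size(self):
        n1, n2 = 50, 35
        n = n1 + n2
        D = np.ones((n, n))
        D[:n1, :n1] = 0.0
        D[n1:, n1:] = 0.0
        np.fill_diagonal(D, 0.0)
        labels = detect_modules(D, min_module_size=30)
        assert (labels[:n1] == 1).all() and (labels[n1:] == 2).all()


class TestMergeModules:
    def test_identical_pattern_modules_merge_distinct_stay(self):
        from degfunnel.coexpression import merge_similar_modules

        rng = np.random.default_rng(10)
        v = rng.normal(size=12)
        w = rng.normal(size=12)
        vals = np.vstack(
            [v + 0.01 * rng.normal(size=12) for _ in range(10)]
            + [v + 0.01 * rng.normal(size=12) for _ in range(10)]
            + [w + 0.01 * rng.normal(size=12) for _ in range(10)]
        )
        em = make_expression(vals, 6)
        labels = np.repeat([1, 2, 3], 10)
        merged = merge_similar_modules(em, labels, threshold=0.25)
        assert len(set(merged)) == 2
        # the two copies of pattern v share a label; pattern w keeps its own
        assert len(set(merged[:20])) == 1
        assert merged[20] != merged[0]


class TestEigengene:
    def test_rank_one_module(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=12)
        vals = np.vstack([2.0 * v + 1.0, -0.5 * v, v])
        em = make_expression(vals, 6)
        e, var_exp = module_eigengene(em.values)
        assert var_exp == pytest.approx(1.0)
        vz = (v - v.mean()) / v.std(ddof=1)
        # eigengene proportional to the standardized pattern up to sign rule
        assert abs(np.corrcoef(e, vz)[0, 1]) == pytest.approx(1.0)

    def test_sign_orientation_toward_mean_profile(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=12)
        vals = np.vstack([v, v, v, -v])  # mean profile follows +v
        em = make_expression(vals, 6)
        e, _ = module_eigengene(em.values)
        assert np.corrcoef(e, v)[0, 1] > 0

    def test_matches_svd_oracle_and_unit_variance(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(30, 12))
        em = make_expression(vals, 6)
        e, var_exp = module_eigengene(em.values)
        assert e.std(ddof=1) == pytest.approx(1.0)
        Z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
        u, s, vt = np.linalg.svd(Z)
        assert abs(np.corrcoef(e, vt[0])[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert var_exp == pytest.approx(s[0] ** 2 / (s**2).sum())

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(20, 12))
        em = make_expression(vals, 6)
        e1, _ = module_eigengene(em.values)
        perm = rng.permutation(20)
        e2, _ = module_eigengene(em.values.iloc[perm])
        np.testing.assert_allclose(e1, e2, atol=1e-10)


class TestTraitCorrelation:
    def test_perfect_correlation(self):
        trait = np.array([1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2])
        r, p = correlate_with_trait(trait.astype(float), trait)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_orthogonal_vector(self):
        trait = np.array([1, 1, 1, 2, 2, 2])
        e = np.array([1.0, -1.0, 0.0, 1.0, -1.0, 0.0])
        r, p = correlate_with_trait(e, trait)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_t_transform(self):
        rng = np.random.default_rng(8)
        e = rng.normal(size=12)
        trait = np.array([1, 2] * 6, dtype=float)
        r, p = correlate_with_trait(e, trait)
        r_hand = np.corrcoef(e, trait)[0, 1]
        t = r_hand * np.sqrt(10) / np.sqrt(1 - r_hand**2)
        from scipy import stats
        assert r == pytest.approx(r_hand, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 10), rel=1e-9)

    def test_constant_eigengene_rejected(self):
        with pytest.raises(CoexpressionError, match="constant"):
            correlate_with_trait(np.ones(6), np.array([1, 1, 1, 2, 2, 2]))


class TestSelection:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["module", "size", "var_explained", "r", "p"])

    def test_threshold_rules(self):
        table = self._table([
            (1, 40, 0.5, 0.6, 0.01),    # selected positive
            (2, 40, 0.5, 0.6, 0.10),    # p too large
            (3, 40, 0.5, -0.9, 0.001),  # selected negative
            (4, 40, 0.5, 0.5, 0.01),    # |r| not strictly above threshold
        ])
        pos, neg = select_modules(table, r_min=0.5, alpha=0.05)
        assert pos == [1]
        assert neg == [3]

    def test_module_refinement_set_algebra(self, small_expression):
        em, truth = small_expression
        trait = em.samples.trait_codes().to_numpy()
        labels = truth.gene_module.to_numpy()
        ms = module_trait_analysis(em, labels, trait)
        degs = set(em.genes[:150])
        m_degs = module_refine_degs(degs, ms)
        assert m_degs <= degs
        selected_genes = ms.genes_of(ms.selected_modules)
        assert m_degs == degs & selected_genes

    def test_no_selected_modules_empty_mdeg(self, small_expression):
        em, truth = small_expression
        ms = module_trait_analysis(
            em, truth.gene_module.to_numpy(), em.samples.trait_codes().to_numpy()
        )
        ms.trait_table["selected"] = False
        assert module_refine_degs(set(em.genes[:10]), ms) == set()

    def test_disjoint_universe_rejected(self, small_expression):
        em, truth = small_expression
        ms = module_trait_analysis(
            em, truth.gene_module.to_numpy(), em.samples.trait_codes().to_numpy()
        )
        with pytest.raises(CoexpressionError, match="disjoint"):
            module_refine_degs({"NOT_A_GENE"}, ms)


class TestSoftThreshold:
    def test_r2_matches_hand_regression(self):
        # 3-point connectivity histogram with a known log-log fit
        k = np.array([1.0] * 50 + [50.0] * 30 + [100.0] * 20)
        r2 = scale_free_fit(k, n_bins=3)
        x = np.log10([1.0, 50.0, 100.0])
        y = np.log10([0.5, 0.3, 0.2])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        expected = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 == pytest.approx(expected, rel=1e-10)

    def test_degenerate_identical_genes_fall_back(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=12)
        vals = np.vstack([v + 1e-9 * rng.normal(size=12) for _ in range(10)])
        em = make_expression(vals, 6)
        with pytest.warns(UserWarning):
            beta, table = pick_soft_threshold(em, powers=(1, 2), default=6.0)
        assert beta == 6.0

    def test_deterministic_given_seeded_data(self, small_expression):
        em, _ = small_expression
        b1, t1 = pick_soft_threshold(em)
        b2, t2 = pick_soft_threshold(em)
        assert b1 == b2
        pd.testing.assert_frame_equal(t1, t2)
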