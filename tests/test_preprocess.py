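import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degfunnel.io_formats import ProbeMatrix
from degfunnel.preprocess import (
    PreprocessError,
    background_correct,
    detection_filter,
    gene_detection_counts,
    log2_transform,
    low_expression_filter,
    preprocess_pipeline,
    quantile_normalize,
    summarize_to_genes,
)
from tests.conftest import make_sheet


def probe_matrix(intensity, detection=None, symbols=None, nc=None, samples=None):
    intensity = np.asarray(intensity, dtype=float)
    n, m = intensity.shape
    idx = pd.Index([f"p{i}" for i in range(n)], name="ProbeID")
    cols = samples or [f"S{j}" for j in range(m)]
    if detection is None:
        detection = np.full((n, m), 0.01)
    nc = np.asarray(nc if nc is not None else [False] * n)
    symbols = symbols or [("" if nc[i] else f"g{i}") for i in range(n)]
    return ProbeMatrix(
        gene_symbol=pd.Series(symbols, index=idx),
        is_negative_control=pd.Series(nc, index=idx),
        intensity=pd.DataFrame(intensity, index=idx, columns=cols),
        detection_p=pd.DataFrame(np.asarray(detection, dtype=float), index=idx, columns=cols),
    )


class TestBackgroundCorrect:
    def test_subtracts_control_mean(self):
        pm = probe_matrix([[100], [200], [50]], nc=[False, False, True])
        out = background_correct(pm)
        assert out.intensity.loc["p0", "S0"] == 50
        assert out.intensity.loc["p1", "S0"] == 150

    def test_zero_controls_leave_matrix_unchanged(self):
        pm = probe_matrix([[100], [200], [0]], nc=[False, False, True])
        out = background_correct(pm)
        np.testing.assert_array_equal(
            out.intensity.loc[["p0", "p1"]].to_numpy(), [[100], [200]]
        )

    def test_no_controls_rejected(self):
        pm = probe_matrix([[1], [2]])
        with pytest.raises(PreprocessError, match="negative-control"):
            background_correct(pm)

    def test_columnwise_oracle_on_simulated_matrix(self, small_dataset):
        pm, *_ = small_dataset
        out = background_correct(pm)
        nc = pm.is_negative_control.astype(bool).to_numpy()
        for s in pm.sample_ids:
            expected = pm.intensity[s].to_numpy() - pm.intensity[s].to_numpy()[nc].mean()
            np.testing.assert_allclose(out.intensity[s].to_numpy(), expected)


class TestDetectionFilter:
    def _pm(self, detection):
        n = len(detection)
        samples = [f"P{i}_{tp}" for i in range(1, 4) for tp in ("0W", "12W")]
        return probe_matrix(np.ones((n, 6)), detection=detection, samples=samples)

    def test_detected_in_one_group_retained(self):
        # detected in all 0W samples, undetected in all 12W samples
        det = [[0.01, 0.2, 0.01, 0.2, 0.01, 0.2]]
        pm = self._pm(det)
        out = detection_filter(pm, make_sheet(3))
        assert out.n_probes == 1

    def test_undetected_everywhere_removed(self):
        pm = self._pm([[0.2] * 6])
        out = detection_filter(pm, make_sheet(3))
        assert out.n_probes == 0

    def test_brute_force_oracle(self, small_dataset):
        pm, em, samples, *_ = small_dataset
        out = detection_filter(pm, samples, alpha=0.05)
        g0 = samples.samples_at("0W")
        g1 = samples.samples_at("12W")
        survivors = set()
        for probe in pm.probe_ids:
            if pm.is_negative_control[probe]:
                continue
            fail0 = all(pm.detection_p.loc[probe, s] > 0.05 for s in g0)
            fail1 = all(pm.detection_p.loc[probe, s] > 0.05 for s in g1)
            if not (fail0 and fail1):
                survivors.add(probe)
        assert set(out.probe_ids) == survivors

    def test_idempotent(self, small_dataset):
        pm, _, samples, *_ = small_dataset
        once = detection_filter(pm, samples)
        twice = detection_filter(once, samples)
        assert once.probe_ids == twice.probe_ids


class TestQuantileNormalize:
    def test_hand_example_no_ties(self):
        pm = probe_matrix([[1, 4], [2, 5], [3, 6]])
        out = quantile_normalize(pm).intensity.to_numpy()
        np.testing.assert_allclose(out, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_hand_example_with_reordering(self):
        pm = probe_matrix([[1, 6], [2, 4], [3, 8]])
        out = quantile_normalize(pm).intensity.to_numpy()
        np.testing.assert_allclose(out[:, 1], [4.0, 2.5, 5.5])

    def test_identical_columns_fixed_point(self):
        pm = probe_matrix([[1, 1], [5, 5], [9, 9]])
        out = quantile_normalize(pm).intensity.to_numpy()
        np.testing.assert_allclose(out, [[1, 1], [5, 5], [9, 9]])

    def test_all_equal_column_gets_tie_mean(self):
        pm = probe_matrix([[1, 7], [2, 7], [3, 7]])
        out = quantile_normalize(pm).intensity.to_numpy()
        # reference = (4, 4.5, 5); tied column spans all three quantiles
        np.testing.assert_allclose(out[:, 1], [4.5, 4.5, 4.5])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(2, 40))
    def test_sorted_columns_identical_property(self, seed, m, n):
        rng = np.random.default_rng(seed)
        pm = probe_matrix(rng.gamma(2.0, 50.0, size=(n, m)))
        out = quantile_normalize(pm).intensity.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, m):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)


class TestLog2Transform:
    def test_basic_values(self):
        out = log2_transform(probe_matrix([[4.0]]), floor=0.0, offset=0.0).intensity
        assert out.loc["p0", "S0"] == 2.0
        out2 = log2_transform(probe_matrix([[0.0]]), floor=0.0, offset=1.0).intensity
        assert out2.iloc[0, 0] == 0.0

    def test_monotone(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-5, 100, size=(50, 1))
        out = log2_transform(probe_matrix(x)).intensity.to_numpy().ravel()
        order = np.argsort(x.ravel(), kind="mergesort")
        assert (np.diff(out[order]) >= 0).all()

    def test_non_finite_rejected(self):
        with pytest.raises(PreprocessError, match="non-finite"):
            log2_transform(probe_matrix([[np.nan]]))


class TestSummarize:
    def test_median_of_probes(self):
        sheet = make_sheet(3)
        vals = np.tile([[1.0], [3.0], [100.0]], (1, 6))
        pm = probe_matrix(vals, symbols=["gA"] * 3, samples=sheet.sample_ids)
        em = summarize_to_genes(pm, sheet)
        assert (em.values.loc["gA"] == 3.0).all()

    def test_single_probe_identity_and_symbolless_dropped(self):
        sheet = make_sheet(3)
        vals = np.arange(12, dtype=float).reshape(2, 6)
        pm = probe_matrix(vals, symbols=["gA", ""], samples=sheet.sample_ids)
        em = summarize_to_genes(pm, sheet)
        assert em.genes == ["gA"]
        np.testing.assert_array_equal(em.values.loc["gA"].to_numpy(), vals[0])

    def test_probe_order_permutation_invariant(self, small_dataset):
        pm, _, samples, *_ = small_dataset
        rng = np.random.default_rng(0)
        perm = rng.permutation(pm.probe_ids)
        shuffled = pm.subset_probes(perm)
        a = summarize_to_genes(pm, samples).values
        b = summarize_to_genes(shuffled, samples).values
        pd.testing.assert_frame_equal(a, b)

    def test_median_oracle_gene_by_gene(self, small_dataset):
        pm, _, samples, *_ = small_dataset
        em = summarize_to_genes(pm, samples)
        rng = np.random.default_rng(1)
        for gene in rng.choice(em.genes, size=10, replace=False):
            probes = pm.gene_symbol.index[pm.gene_symbol == gene]
            expected = pm.intensity.loc[probes].median(axis=0)
            np.testing.assert_allclose(em.values.loc[gene].to_numpy(),
                                       expected[em.values.columns].to_numpy())


class TestLowExpressionFilter:
    def _em(self):
        sheet = make_sheet(6)
        vals = np.ones((3, 12))
        df = pd.DataFrame(vals, index=pd.Index(["a", "b", "c"], name="gene"),
                          columns=sheet.sample_ids)
        from degfunnel.io_formats import ExpressionMatrix
        return ExpressionMatrix(df, sheet)

    def test_boundary_at_three_of_twelve(self):
        em = self._em()
        counts = pd.Series({"a": 3, "b": 2, "c": 12})
        out = low_expression_filter(em, counts, min_samples=3)
        assert out.genes == ["a", "c"]

    def test_min_zero_is_identity(self):
        em = self._em()
        counts = pd.Series({"a": 0, "b": 0, "c": 0})
        out = low_expression_filter(em, counts, min_samples=0)
        assert out.genes == ["a", "b", "c"]

    def test_min_exceeding_samples_rejected(self):
        em = self._em()
        with pytest.raises(PreprocessError, match="exceeds"):
            low_expression_filter(em, pd.Series({"a": 1}), min_samples=13)


class TestPipeline:
    def test_provenance_records_fixed_order(self, small_dataset):
        pm, _, samples, *_ = small_dataset
        em = preprocess_pipeline(pm, samples)
        steps = " ".join(str(p) for p in em.provenance)
        for name in ("background", "detection_filter", "quantile", "log2",
                     "summarize", "low_expression"):
            assert name in steps

    def test_detection_counts_match_any_probe_rule(self, small_dataset):
        pm, *_ = small_dataset
        counts = gene_detection_counts(pm, alpha=0.05)
        gene = counts.index[0]
        probes = pm.gene_symbol.index[pm.gene_symbol == gene]
        expected = (pm.detection_p.loc[probes] <= 0.05).any(axis=0).sum()
        assert counts[gene] == expected
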