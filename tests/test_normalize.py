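"""TMM factors, CPM transforms, expression filtering, and sample PCA."""

import numpy as np
import pandas as pd
import pytest

import editbench as eb
from editbench._errors import DegenerateDataError, ParameterError


def _toy(values, samples=None):
    values = np.asarray(values)
    samples = samples or [f"S{i+1}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"G{i+1}" for i in range(values.shape[0])], columns=samples)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        c = _toy(np.tile([[10], [200], [3000], [50]] * 4, (1, 2)))
        f = eb.tmm_factors(c)
        assert np.allclose(f.factors, 1.0)

    def test_library_doubling_is_absorbed(self):
        col = np.array([10, 200, 3000, 50, 7, 400, 120, 33, 900, 60, 10, 5])
        c = _toy(np.column_stack([col, 2 * col]))
        f = eb.tmm_factors(c)
        assert np.allclose(f.factors, 1.0)

    def test_toy_matches_hand_computed_trimmed_weighted_mean(self):
        """12-gene two-sample toy with one 10-fold inflated gene, enumerated by hand."""
        a = np.array([100, 200, 300, 400, 500, 600, 700, 800, 900, 1000, 1100, 1200])
        b = a.copy()
        b[0] *= 10  # composition outlier
        c = _toy(np.column_stack([a, b]))
        f = eb.tmm_factors(c, trim_m=0.30, trim_a=0.05)

        # independent enumeration of the TMM definition on the toy
        na, nb = a.sum(), b.sum()
        m = np.log2((b / nb) / (a / na))
        aa = 0.5 * (np.log2(b / nb) + np.log2(a / na))
        w = 1.0 / ((nb - b) / (nb * b) + (na - a) / (na * a))
        n = len(m)
        lo = int(np.floor(n * 0.30)) + 1
        keep_m = (pd.Series(m).rank() >= lo) & (pd.Series(m).rank() <= n + 1 - lo)
        lo_a = int(np.floor(n * 0.05)) + 1
        keep_a = (pd.Series(aa).rank() >= lo_a) & (pd.Series(aa).rank() <= n + 1 - lo_a)
        keep = (keep_m & keep_a).to_numpy()
        fb = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
        expected = np.array([1.0, fb]) / np.sqrt(fb)
        # reference is S1 (equal upper quartiles scaled -> closest to mean)
        assert np.allclose(np.sort(f.factors.to_numpy()), np.sort(expected), rtol=1e-10)

    def test_matches_edger_reference_values(self):
        """Frozen cross-check against edgeR 4.0 calcNormFactors on a seeded fixture."""
        rng = np.random.default_rng(100)
        x = rng.negative_binomial(
            5, 5 / (5 + rng.lognormal(4, 1.5, size=(200, 1)) * np.ones((1, 4))), size=(200, 4)
        )
        x[:, 1] = (x[:, 1] * 2.0).astype(int)
        x[:10, 2] = x[:10, 2] * 10
        c = _toy(x, samples=list("ABCD"))
        f = eb.tmm_factors(c)
        expected = [1.04494240, 1.09486153, 0.79924572, 1.09362426]
        assert np.allclose(f.factors.to_numpy(), expected, atol=5e-7)

    def test_scaling_one_sample_leaves_factors_invariant(self, null_counts_3v3):
        _, counts = null_counts_3v3
        f1 = eb.tmm_factors(counts)
        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        f2 = eb.tmm_factors(scaled)
        # M-values and the trim set are exactly invariant; the precision
        # weights shift slightly with library size, so agreement is near-exact
        assert np.allclose(f1.factors, f2.factors, atol=0.01)

    def test_degenerate_inputs_raise(self):
        c = _toy(np.zeros((20, 2), dtype=int))
        with pytest.raises(DegenerateDataError):
            eb.tmm_factors(c)
        c2 = _toy(np.array([[5, 0], [0, 7], [3, 1], [2, 2]]))
        with pytest.raises(DegenerateDataError):
            eb.tmm_factors(c2)  # <10 genes expressed in both


class TestCPM:
    def test_columns_sum_to_one_million(self, null_counts_3v3):
        _, counts = null_counts_3v3
        v = eb.cpm(counts, factors=None, log=False, prior_count=0.0)
        assert np.allclose(v.sum(axis=0), 1e6)

    def test_zero_count_log_is_finite(self):
        c = _toy([[0, 0], [100, 120], [50, 60], [10, 10]])
        v = eb.cpm(c, log=True, prior_count=0.5)
        assert np.isfinite(v.to_numpy()).all()

    def test_unit_case(self):
        c = _toy([[100], [1_000_000 - 100]], samples=["S1"])
        v = eb.cpm(c, factors=pd.Series([1.0], index=["S1"]), log=False)
        assert v.iloc[0, 0] == pytest.approx(100.0)

    def test_monotone_in_count(self):
        c = _toy([[0, 5], [10, 5], [1000, 5], [10, 5]])
        v = eb.cpm(c, log=True)
        assert v["S1"].iloc[2] > v["S1"].iloc[1] > v["S1"].iloc[0]


class TestFilter:
    def test_zero_threshold_keeps_everything(self, null_counts_3v3):
        _, counts = null_counts_3v3
        assert eb.filter_low_expression(counts, min_cpm=0.0, min_samples=1).all()

    def test_all_zero_gene_excluded(self):
        c = _toy([[0, 0], [100, 120], [50, 60]])
        mask = eb.filter_low_expression(c, min_cpm=1.0, min_samples=1)
        assert not mask.iloc[0]
        assert mask.iloc[1]

    def test_toy_mask_matches_direct_cpm_evaluation(self):
        c = _toy([[1, 0], [10, 10], [0, 0], [500, 2], [3, 3]])
        mask = eb.filter_low_expression(c, min_cpm=10_000, min_samples=2)
        v = c / c.sum(axis=0).to_numpy() * 1e6
        expected = (v >= 10_000).sum(axis=1) >= 2
        assert mask.equals(expected)

    def test_min_samples_validation(self):
        c = _toy([[1, 2], [3, 4]])
        with pytest.raises(ParameterError):
            eb.filter_low_expression(c, min_samples=5)


class TestPCA:
    def test_duplicated_samples_have_identical_scores(self, null_counts_3v3):
        _, counts = null_counts_3v3
        lc = eb.cpm(counts, log=True)
        dup = pd.concat([lc, lc.iloc[:, [0]].rename(columns={lc.columns[0]: "dup"})], axis=1)
        res = eb.pca_samples(dup, scale=False)
        assert np.allclose(res.scores.iloc[0], res.scores.loc["dup"], atol=1e-8)

    def test_variance_explained_sorted_and_bounded(self, null_counts_3v3):
        _, counts = null_counts_3v3
        res = eb.pca_samples(eb.cpm(counts, log=True))
        ve = res.variance_explained
        assert (np.diff(ve) <= 1e-12).all()
        assert 0 < ve.sum() <= 1 + 1e-9

    def test_three_sample_toy_matches_hand_eigendecomposition(self):
        rng = np.random.default_rng(42)
        lc = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        lc.iloc[:, 2] += 3 * lc.iloc[:, 0]  # dominant axis
        res = eb.pca_samples(lc, center=True, scale=True)
        # oracle: eigenvalues of the correlation-ish covariance of scaled data
        X = lc.to_numpy().T
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
        share = evals[0] / evals.sum()
        assert res.variance_explained[0] == pytest.approx(share, abs=1e-10)

    def test_reconstruction(self):
        rng = np.random.default_rng(1)
        lc = pd.DataFrame(rng.normal(size=(30, 5)))
        res = eb.pca_samples(lc, center=True, scale=True)
        X = lc.to_numpy().T
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, X, atol=1e-8)

    def test_single_sample_raises(self):
        with pytest.raises(DegenerateDataError):
            eb.pca_samples(pd.DataFrame({"a": [1.0, 2.0]}))
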