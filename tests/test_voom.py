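"""Precision weights, consensus block correlation, and the moderated t-test."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

import editbench as eb
from editbench._errors import DesignError, ParameterError
from editbench.de import (
    consensus_block_correlation,
    design_matrix,
    precision_weights,
    weighted_moderated_t,
)
from editbench.de.limma import fit_f_dist
from tests.conftest import null_params


def _two_group(design):
    return design_matrix(design, factors=("status",), coef="status")


class TestPrecisionWeights:
    def test_weights_positive_and_near_constant_for_homoscedastic_log_data(self):
        """Counts with constant log-scale noise: the trend is flat, weights ~equal."""
        rng = np.random.default_rng(9)
        mu = rng.uniform(4, 12, size=600)  # wide abundance range, log2 scale
        y = np.rint(2 ** (mu[:, None] + rng.normal(0, 0.25, size=(600, 6)))).astype(int)
        counts = pd.DataFrame(y, index=[f"G{i}" for i in range(600)],
                              columns=[f"S{i}" for i in range(6)])
        design = eb.make_design(1, 3, 3)
        counts.columns = design["sample_id"]
        _, w = precision_weights(counts, _two_group(design))
        assert (w.to_numpy() > 0).all()
        cv = w.to_numpy().std() / w.to_numpy().mean()
        assert cv < 0.2

    def test_nb_counts_show_decreasing_sd_trend(self, null_counts_3v3):
        design, counts = null_counts_3v3
        logcpm, w = precision_weights(counts, _two_group(design))
        # weights grow with abundance when the sqrt-sd trend decreases
        abund = logcpm.mean(axis=1)
        lo = w[abund < abund.quantile(0.2)].mean(axis=None)
        hi = w[abund > abund.quantile(0.8)].mean(axis=None)
        assert hi > lo

    def test_span_validation(self, null_counts_3v3):
        design, counts = null_counts_3v3
        with pytest.raises(ParameterError):
            precision_weights(counts, _two_group(design), span=1.5)


class TestBlockCorrelation:
    def test_null_correlation_is_near_zero(self):
        design = eb.make_design(4, 3, 3)
        counts, _ = eb.simulate_counts(design, null_params(n_genes=2000, seed=81))
        dm = _two_group(design)
        logcpm, _ = precision_weights(counts, dm)
        rho = consensus_block_correlation(logcpm, dm, design["line"])
        assert abs(rho) < 0.05

    def test_rho_increases_with_line_variance(self):
        design = eb.make_design(4, 3, 3)
        rhos = []
        for sl in (0.0, 0.3, 0.6):
            p = dataclasses.replace(null_params(n_genes=1200, seed=82), sigma_line=sl)
            counts, _ = eb.simulate_counts(design, p)
            dm = _two_group(design)
            logcpm, _ = precision_weights(counts, dm)
            rhos.append(consensus_block_correlation(logcpm, dm, design["line"]))
        assert rhos[0] < rhos[1] < rhos[2]
        assert rhos[2] > 0.2

    def test_singleton_blocks_raise(self, null_counts_3v3):
        design, counts = null_counts_3v3
        dm = _two_group(design)
        logcpm, _ = precision_weights(counts, dm)
        with pytest.raises(DesignError):
            consensus_block_correlation(logcpm, dm, list(range(len(design))))


class TestModeratedT:
    def _setup(self, seed=91, n=400):
        design = eb.make_design(1, 3, 3)
        counts, _ = eb.simulate_counts(design, null_params(n_genes=n, seed=seed))
        dm = _two_group(design)
        logcpm, w = precision_weights(counts, dm)
        return design, dm, logcpm, w

    def test_prior_df_zero_equals_per_gene_wls_oracle(self):
        """With no moderation the statistic is the ordinary WLS t-test."""
        design, dm, logcpm, w = self._setup()
        res = weighted_moderated_t(logcpm, w, dm, prior_df=0)
        X = dm.X
        n, p = X.shape
        for g in [0, 5, 17, 123, 399]:
            yv = logcpm.iloc[g].to_numpy()
            wv = w.iloc[g].to_numpy()
            W = np.diag(wv)
            A = np.linalg.inv(X.T @ W @ X)
            beta = A @ X.T @ W @ yv
            resid = yv - X @ beta
            s2 = float(resid @ W @ resid) / (n - p)
            tval = beta[1] / np.sqrt(s2 * A[1, 1])
            pval = 2 * t_dist.sf(abs(tval), n - p)
            assert res.loc[g, "p"] == pytest.approx(pval, rel=1e-8)
            assert res.loc[g, "log2fc"] == pytest.approx(beta[1], rel=1e-8)

    def test_identical_residual_variances_leave_t_unmoderated(self):
        """Shrinkage toward the pooled prior is a no-op when variances agree."""
        design = eb.make_design(1, 3, 3)
        dm = _two_group(design)
        rng = np.random.default_rng(4)
        noise = rng.normal(0, 0.3, size=6)  # same residual pattern for every gene
        y = np.add.outer(rng.uniform(3, 10, size=50), noise)
        logcpm = pd.DataFrame(y, columns=design["sample_id"])
        w = pd.DataFrame(np.ones_like(y), columns=design["sample_id"])
        moderated = weighted_moderated_t(logcpm, w, dm)
        ordinary = weighted_moderated_t(logcpm, w, dm, prior_df=0)
        # the t statistics coincide exactly; recover them by inverting the
        # two-sided p at each fit's degrees of freedom
        t_mod = t_dist.isf(moderated["p"] / 2, 1e6)
        t_ord = t_dist.isf(ordinary["p"] / 2, 4)
        assert np.allclose(t_mod, t_ord, rtol=1e-5)

    def test_infinite_prior_df_uses_pooled_variance(self):
        design, dm, logcpm, w = self._setup(seed=92, n=200)
        res = weighted_moderated_t(logcpm, w, dm, prior_df=np.inf)
        X = dm.X
        n, p = X.shape
        s2 = []
        b1 = []
        se = []
        for g in range(len(logcpm)):
            yv = logcpm.iloc[g].to_numpy()
            W = np.diag(w.iloc[g].to_numpy())
            A = np.linalg.inv(X.T @ W @ X)
            beta = A @ X.T @ W @ yv
            resid = yv - X @ beta
            s2.append(float(resid @ W @ resid) / (n - p))
            b1.append(beta[1])
            se.append(np.sqrt(A[1, 1]))
        pooled = np.mean(s2)
        t_expected = np.array(b1) / (np.array(se) * np.sqrt(pooled))
        # compare through p-values at the large-df limit
        p_expected = 2 * t_dist.sf(np.abs(t_expected), 1e6)
        assert np.allclose(res["p"], p_expected, atol=1e-8)

    def test_blocked_fit_runs_and_is_calibrated_under_line_structure(self):
        design = eb.make_design(4, 3, 3)
        p = dataclasses.replace(null_params(n_genes=600, seed=93), sigma_line=0.5)
        counts, _ = eb.simulate_counts(design, p)
        dm = _two_group(design)
        logcpm, w = precision_weights(counts, dm)
        rho = consensus_block_correlation(logcpm, dm, design["line"])
        blocked = weighted_moderated_t(logcpm, w, dm, block=design["line"], rho=rho)
        assert blocked["method"].iloc[0] == "weighted_moderated_t_blocked"
        assert ((blocked["p"] >= 0) & (blocked["p"] <= 1)).all()

    def test_rank_deficient_design_raises(self):
        design = eb.make_design(1, 3, 3)
        dm = _two_group(design)
        with pytest.raises(DesignError):
            dm.matrix["dup"] = dm.matrix["status[edited]"]
            type(dm)(dm.matrix, dm.coef)


def test_fit_f_dist_recovers_known_prior():
    """Sample variances drawn from a scaled F shape give back (d0, s0)."""
    rng = np.random.default_rng(17)
    d, d0, s0 = 4, 8.0, 0.07
    s2 = s0 * rng.chisquare(d, size=20000) / d * d0 / rng.chisquare(d0, size=20000)
    d0_hat, s0_hat = fit_f_dist(s2, d)
    assert d0_hat == pytest.approx(d0, rel=0.2)
    assert s0_hat == pytest.approx(s0, rel=0.1)


def test_blocking_restores_calibration_and_power_under_line_structure():
    """Line offsets inflate unblocked residuals: the unblocked edit-contrast
    test is badly conservative, while the blocked GLS fit is calibrated and
    recovers more true effects."""
    ub_frac, bl_frac = [], []
    for rep in range(3):
        design = eb.make_design(4, 3, 3)
        p = dataclasses.replace(null_params(n_genes=800, phi=0.05, seed=700 + rep),
                                sigma_line=0.6)
        counts, _ = eb.simulate_counts(design, p)
        ub = eb.edit_contrast_de(counts, design, engine="wmt", adjust_line=False)
        bl = eb.edit_contrast_de(counts, design, engine="wmt", adjust_line=True)
        ub_frac.append(float((ub.p < 0.05).mean()))
        bl_frac.append(float((bl.p < 0.05).mean()))
    assert np.median(ub_frac) < 0.02  # unblocked: variance inflated, conservative
    assert abs(np.median(bl_frac) - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 800)

    # with true edit effects, blocking recovers more of them
    design = eb.make_design(4, 3, 3)
    p = dataclasses.replace(null_params(n_genes=800, phi=0.05, seed=750), sigma_line=0.6)
    p.edit_effects = {f"G{i:06d}": 1.2 * (1 if i % 2 else -1) for i in range(10, 90)}
    counts, truth = eb.simulate_counts(design, p)
    planted = set(truth.loc[truth.affected, "gene_id"])
    from editbench.de.result import significant_genes
    ub_tp = len(significant_genes(eb.edit_contrast_de(counts, design, "wmt", adjust_line=False)) & planted)
    bl_tp = len(significant_genes(eb.edit_contrast_de(counts, design, "wmt", adjust_line=True)) & planted)
    assert bl_tp > ub_tp
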