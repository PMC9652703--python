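"""Univariate and bivariate pooling engines."""

import math

import numpy as np
import pytest
from scipy.special import logit

from dxmeta.meta_pool import (
    BivariateFit,
    PoolingError,
    fit_bivariate,
    monte_carlo_summary,
    pool_dsl,
    summarize_fit,
)
from dxmeta.study_table import ContingencyTable
from dxmeta.synthetic_data import MetaSimConfig, simulate_tables


def _table(tp, fp, fn, tn, sid="t"):
    return ContingencyTable(tp, fp, fn, tn, study_id=sid)


class TestUnivariate:
    def test_single_study_pooling_is_identity(self):
        est, het = pool_dsl([_table(8, 1, 2, 9)], "sen")
        assert est.point == pytest.approx(0.8)
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert est.k == 1

    def test_identical_replicates_have_no_heterogeneity(self):
        tabs = [_table(30, 10, 20, 40, sid=f"s{i}") for i in range(3)]
        est, het = pool_dsl(tabs, "sen", force_model="random")
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0
        assert est.point == pytest.approx(0.6)

    def test_fixed_effect_equals_direct_weighted_mean(self):
        # oracle: inverse-variance weighted mean of ln DOR computed directly
        tabs = [_table(30, 10, 20, 40), _table(25, 15, 10, 60), _table(45, 5, 20, 30)]
        y = np.array([math.log(t.dor) for t in tabs])
        v = np.array([1 / t.tp + 1 / t.fp + 1 / t.fn + 1 / t.tn for t in tabs])
        expected = np.exp(np.sum(y / v) / np.sum(1 / v))
        est, _ = pool_dsl(tabs, "dor", force_model="fixed")
        assert est.point == pytest.approx(expected, rel=1e-12)

    def test_empty_input_is_an_error(self):
        with pytest.raises(PoolingError):
            pool_dsl([], "sen")

    @pytest.mark.parametrize("metric", ["sen", "spe", "plr", "nlr", "dor"])
    def test_ci_brackets_point_on_real_data(self, tables, metric):
        est, het = pool_dsl(tables, metric)
        assert est.ci_low <= est.point <= est.ci_high
        assert 0.0 <= het.i2 <= 100.0

    def test_dor_heterogeneity_on_packaged_table(self, tables):
        _, het = pool_dsl(tables, "dor")
        assert het.df == 53
        assert het.q == pytest.approx(251.75, rel=0.005)
        assert het.i2 == pytest.approx(78.9, abs=0.2)


class TestBivariate:
    def test_too_few_studies_rejected(self):
        with pytest.raises(PoolingError):
            fit_bivariate([_table(8, 1, 2, 9)])

    def test_identical_large_tables_shrink_sigma_to_zero(self):
        tabs = [_table(800, 200, 200, 800, sid=f"s{i}") for i in range(6)]
        fit = fit_bivariate(tabs, likelihood="normal", method="reml")
        assert np.all(np.abs(fit.sigma) < 1e-3)
        assert fit.mu == pytest.approx([logit(0.8), logit(0.8)], abs=1e-3)

    def test_normal_reml_matches_independent_mixed_model_oracle(self):
        # frozen oracle: the same 8 tables fitted as a bivariate random-effects
        # meta-analysis (rma.mv, struct="UN", REML) in R metafor 4.8-0
        cells = [
            (24, 13, 23, 40), (66, 19, 18, 82), (79, 52, 32, 44), (33, 20, 12, 48),
            (63, 15, 46, 30), (74, 16, 33, 102), (49, 14, 13, 62), (54, 28, 37, 84),
        ]
        tabs = [_table(*c, sid=f"s{i}") for i, c in enumerate(cells)]
        fit = fit_bivariate(tabs, method="reml", likelihood="normal")
        assert fit.mu[0] == pytest.approx(0.7419254273, abs=1e-6)
        assert fit.mu[1] == pytest.approx(1.0410266556, abs=1e-6)
        assert fit.sigma[0, 0] == pytest.approx(0.1413684042, abs=1e-5)
        assert fit.sigma[1, 1] == pytest.approx(0.3409437013, abs=1e-5)
        rho = fit.sigma[0, 1] / math.sqrt(fit.sigma[0, 0] * fit.sigma[1, 1])
        assert rho == pytest.approx(0.1982992925, abs=1e-4)
        assert math.sqrt(fit.fixed_vcov[0, 0]) == pytest.approx(0.1601507781, abs=1e-5)
        assert math.sqrt(fit.fixed_vcov[1, 1]) == pytest.approx(0.2272797499, abs=1e-5)

    def test_parameter_recovery_on_large_synthetic_dataset(self):
        mu = (1.0, 1.2)
        tabs, truth = simulate_tables(
            MetaSimConfig(k=500, mu=mu, sigma=((0.3, 0.0), (0.0, 0.3)),
                          size_range=(50, 200), seed=7)
        )
        fit = fit_bivariate(tabs)
        assert fit.converged
        assert fit.mu[0] == pytest.approx(mu[0], abs=0.1)
        assert fit.mu[1] == pytest.approx(mu[1], abs=0.1)

    def test_binomial_beats_normal_approximation_near_boundary(self):
        # extreme specificities: the plug-in logit variances are biased, the
        # exact-binomial likelihood is not; both must still converge
        tabs, _ = simulate_tables(
            MetaSimConfig(k=40, mu=(1.0, 3.0), sigma=((0.2, 0.0), (0.0, 0.2)),
                          size_range=(20, 60), seed=3)
        )
        fb = fit_bivariate(tabs, likelihood="binomial")
        fn_ = fit_bivariate(tabs, likelihood="normal", method="reml")
        assert fb.converged and fn_.converged
        assert fb.mu[1] > fn_.mu[1]  # normal approximation shrinks toward 0


class TestSummarize:
    def test_symmetry_point_gives_unit_ratios(self):
        fit = BivariateFit(
            mu=np.zeros(2), sigma=np.eye(2) * 0.1, fixed_vcov=np.eye(2) * 0.01,
            loglik=0.0, converged=True, k=10, method="ml", likelihood="binomial",
        )
        est = {e.metric: e.point for e in summarize_fit(fit)}
        assert est["sen"] == pytest.approx(0.5)
        assert est["spe"] == pytest.approx(0.5)
        assert est["plr"] == pytest.approx(1.0)
        assert est["nlr"] == pytest.approx(1.0)
        assert est["dor"] == pytest.approx(1.0)

    def test_closed_form_dor_from_known_means(self):
        fit = BivariateFit(
            mu=np.array([logit(0.9), logit(0.8)]), sigma=np.eye(2) * 0.1,
            fixed_vcov=np.eye(2) * 0.01, loglik=0.0, converged=True, k=10,
            method="ml", likelihood="binomial",
        )
        est = {e.metric: e.point for e in summarize_fit(fit)}
        assert est["dor"] == pytest.approx(36.0, rel=1e-9)

    def test_dor_identity_plr_over_nlr(self, full_fit):
        est = {e.metric: e.point for e in summarize_fit(full_fit)}
        assert est["dor"] == pytest.approx(est["plr"] / est["nlr"], rel=1e-9)

    def test_monte_carlo_agrees_with_delta_method(self, full_fit):
        mc = monte_carlo_summary(full_fit, draws=4000, seed=11)
        delta = {e.metric: e for e in summarize_fit(full_fit)}
        for m in ("plr", "nlr", "dor"):
            assert mc[m][1] == pytest.approx(delta[m].ci_low, rel=0.06)
            assert mc[m][2] == pytest.approx(delta[m].ci_high, rel=0.06)
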