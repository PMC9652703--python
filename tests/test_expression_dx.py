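"""Expression normalisation, differential expression, ROC, logistic models."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dxmeta.expression_dx import (
    ExpressionError,
    ExpressionMatrix,
    LogisticModel,
    counts_to_tpm,
    diff_expr,
    fit_logistic_combo,
    roc_curve,
    stage_stratified_auc,
)
from dxmeta.synthetic_data import ExprSimConfig, simulate_expression


def _matrix(values, n_case, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = [f"S{i}" for i in range(values.shape[1])]
    labels = pd.Series(
        ["case"] * n_case + ["control"] * (values.shape[1] - n_case), index=samples
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), labels=labels
    )


def _pair_count_auc(scores, labels):
    """O(n^2) oracle: P(case score > control score) + 0.5 P(tie)."""
    cases = [s for s, l in zip(scores, labels) if l == "case"]
    ctrls = [s for s, l in zip(scores, labels) if l == "control"]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in ctrls)
    return wins / (len(cases) * len(ctrls))


class TestTPM:
    def test_columns_sum_to_one_million(self):
        m = _matrix([[10, 0, 5], [3, 7, 2], [1, 1, 1]], n_case=1)
        tpm = counts_to_tpm(m, {"G0": 1500.0, "G1": 700.0, "G2": 900.0})
        np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_length_scaling_hand_example(self):
        m = _matrix([[100, 100], [100, 100]], n_case=1)
        tpm = counts_to_tpm(m, {"G0": 1000.0, "G1": 2000.0})
        np.testing.assert_allclose(
            tpm.values.iloc[:, 0], [666666.6667, 333333.3333], rtol=1e-6
        )

    def test_all_zero_gene_stays_zero(self):
        m = _matrix([[0, 0], [5, 5]], n_case=1)
        tpm = counts_to_tpm(m, {"G0": 1000.0, "G1": 1000.0})
        assert (tpm.values.loc["G0"] == 0).all()

    def test_empty_library_rejected(self):
        m = _matrix([[0, 5], [0, 5]], n_case=1)
        with pytest.raises(ExpressionError, match="zero library"):
            counts_to_tpm(m, {"G0": 1000.0, "G1": 1000.0})


class TestDiffExpr:
    def test_tiny_exact_p_from_rank_null(self):
        # 2 vs 2, values (1,2) vs (3,4): U = 0; 2 of the 6 equally likely label
        # assignments are at least as extreme -> two-sided p = 1/3
        m = _matrix([[1, 2, 3, 4]], n_case=2)
        row = diff_expr(m)[0]
        assert row.p_value == pytest.approx(1 / 3)
        assert row.log_fc < 0

    def test_planted_upregulation_detected(self):
        expr = simulate_expression(
            ExprSimConfig(n_genes=30, n_case=50, n_control=50,
                          planted={"G003": 2.0}, seed=4)
        )
        rows = {r.gene: r for r in diff_expr(expr)}
        assert rows["G003"].direction == "up"
        assert rows["G003"].fdr < 0.05

    def test_constant_gene_gets_unit_p(self):
        m = _matrix([[5, 5, 5, 5, 5, 5], [1, 2, 3, 4, 5, 6]], n_case=3)
        rows = diff_expr(m)
        assert rows[0].p_value == 1.0

    def test_fdr_never_below_p(self):
        expr = simulate_expression(ExprSimConfig(n_genes=40, seed=8))
        for r in diff_expr(expr):
            assert r.fdr >= r.p_value - 1e-12
            assert 0.0 <= r.fdr <= 1.0


class TestROC:
    def test_perfect_separation(self):
        r = roc_curve([1, 2, 3, 4], ["control", "control", "case", "case"])
        assert r.auc == 1.0
        assert r.youden == pytest.approx(1.0)
        assert 2 < r.cutoff <= 3

    def test_auc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(12)
        scores = np.round(rng.normal(size=200), 1)  # coarse -> many ties
        labels = ["case" if rng.random() < 0.5 else "control" for _ in range(200)]
        if "case" not in labels:
            labels[0] = "case"
        if "control" not in labels:
            labels[1] = "control"
        r = roc_curve(scores, labels)
        assert r.auc == pytest.approx(_pair_count_auc(scores, labels), abs=1e-12)

    def test_youden_tie_breaks_toward_specificity(self):
        # two cut-offs reach Youden = 0.5; the higher-specificity one must win
        scores = [1, 2, 3, 4]
        labels = ["control", "case", "control", "case"]
        r = roc_curve(scores, labels)
        assert r.spe_at_cutoff == 1.0
        assert r.cutoff == 4

    def test_one_class_rejected(self):
        with pytest.raises(ExpressionError):
            roc_curve([1, 2], ["case", "case"])

    def test_hanley_mcneil_se_positive_and_bracketing(self):
        rng = np.random.default_rng(3)
        s = np.r_[rng.normal(1, 1, 60), rng.normal(0, 1, 60)]
        labels = ["case"] * 60 + ["control"] * 60
        r = roc_curve(s, labels)
        assert r.se > 0
        assert r.ci_low <= r.auc <= r.ci_high


class TestLogistic:
    def test_published_two_marker_model_score_at_origin(self):
        model = LogisticModel(
            intercept=-1.307, coefficients={"PVT1": 7.129, "C5orf66-AS1": -1.204}
        )
        m = _matrix([[0.0, 0.5], [0.0, 0.5]], n_case=1, genes=["PVT1", "C5orf66-AS1"])
        s = model.score(m)
        assert s.iloc[0] == pytest.approx(expit(-1.307), abs=1e-6)
        assert s.iloc[0] == pytest.approx(0.2130, abs=5e-4)

    def test_equation_rendering(self):
        model = LogisticModel(intercept=-1.307,
                              coefficients={"PVT1": 7.129, "C5orf66-AS1": -1.204})
        eq = model.equation()
        assert eq.startswith("logit(P) = ")
        assert "PVT1" in eq and "-1.204" in eq

    def test_parameter_recovery_from_generated_data(self):
        rng = np.random.default_rng(17)
        n = 2000
        x = rng.normal(size=(2, n))
        eta = -1.0 + 2.0 * x[0] - 1.0 * x[1]
        y = rng.random(n) < expit(eta)
        values = pd.DataFrame(x - x.min() + 0.0, index=["A", "B"],
                              columns=[f"S{i}" for i in range(n)])
        # shift to non-negative without changing slopes
        labels = pd.Series(["case" if yy else "control" for yy in y],
                           index=values.columns)
        expr = ExpressionMatrix(values=values, labels=labels)
        model = fit_logistic_combo(expr, ["A", "B"])
        assert model.coefficients["A"] == pytest.approx(2.0, abs=0.2)
        assert model.coefficients["B"] == pytest.approx(-1.0, abs=0.2)

    def test_null_covariates_rarely_significant(self):
        sig = 0
        n_seeds = 20
        for seed in range(n_seeds):
            expr = simulate_expression(
                ExprSimConfig(n_genes=2, n_case=40, n_control=40, seed=300 + seed)
            )
            import statsmodels.api as sm

            X = sm.add_constant(expr.values.T.to_numpy(float))
            res = sm.Logit(expr.case_mask().astype(float), X).fit(disp=False)
            if (res.pvalues[1:] < 0.05).any():
                sig += 1
        assert sig <= 2  # >= 90% of seeds fully null

    def test_perfect_separation_flagged(self):
        m = _matrix([[5, 6, 7, 1, 2, 3]], n_case=3)
        model = fit_logistic_combo(m, ["G0"])
        assert model.separated

    def test_missing_gene_rejected(self):
        m = _matrix([[1, 2, 3, 4]], n_case=2)
        with pytest.raises(ExpressionError):
            fit_logistic_combo(m, ["nope"])


@pytest.fixture(scope="module")
def staged_expr():
    # moderate effect and wide noise keep every stage AUC strictly below 1
    return simulate_expression(
        ExprSimConfig(
            n_genes=10, n_case=120, n_control=60,
            planted={"G000": 0.8}, noise=1.0,
            stage_effect={"I": 1.0, "II": 1.5, "III": 2.2, "IV": 3.2},
            seed=23,
        )
    )


class TestStages:
    def test_auc_monotone_in_planted_stage_effect(self, staged_expr):
        model = fit_logistic_combo(staged_expr, ["G000"])
        out = stage_stratified_auc(staged_expr, model)
        by_stage = {label: roc.auc for label, roc, _ in out}
        assert by_stage["I"] <= by_stage["II"] <= by_stage["III"] <= by_stage["IV"]
        assert [label for label, _, _ in out] == ["I", "II", "III", "IV", "II+III+IV"]

    def test_stage_one_has_no_self_comparison(self, staged_expr):
        model = fit_logistic_combo(staged_expr, ["G000"])
        out = stage_stratified_auc(staged_expr, model)
        assert out[0][2] is None
        assert all(comp is not None for _, _, comp in out[1:])

    def test_identical_stages_give_zero_z(self):
        # every 'stage' re-uses the same case data -> all AUCs equal, z = 0
        rng = np.random.default_rng(31)
        case_block = rng.lognormal(0.5, 1.0, size=(3, 10))   # overlapping groups
        ctrl_block = rng.lognormal(0.0, 1.0, size=(3, 20))
        values = np.hstack([case_block] * 4 + [ctrl_block])
        samples = [f"S{i}" for i in range(values.shape[1])]
        labels = pd.Series(["case"] * 40 + ["control"] * 20, index=samples)
        stage = pd.Series(
            ["I"] * 10 + ["II"] * 10 + ["III"] * 10 + ["IV"] * 10 + [None] * 20,
            index=samples, dtype=object,
        )
        expr = ExpressionMatrix(
            values=pd.DataFrame(values, index=["A", "B", "C"], columns=samples),
            labels=labels, stage=stage,
        )
        model = fit_logistic_combo(expr, ["A"])
        out = stage_stratified_auc(expr, model, min_cases=5)
        for _, _, comp in out[1:4]:
            assert comp.z == pytest.approx(0.0, abs=1e-12)

    def test_missing_stage_labels_rejected(self, staged_expr):
        expr = ExpressionMatrix(
            values=staged_expr.values, labels=staged_expr.labels, stage=None
        )
        model = LogisticModel(intercept=0.0, coefficients={"G000": 1.0})
        with pytest.raises(ExpressionError, match="stage"):
            stage_stratified_auc(expr, model)
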