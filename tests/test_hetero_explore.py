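"""Threshold effect, subgroups, and meta-regression."""

import numpy as np
import pytest
from scipy.special import logit

from dxmeta.hetero_explore import (
    backward_eliminate,
    moses_metaregression,
    subgroup_analysis,
    threshold_spearman,
)
from dxmeta.sroc_auc import moses_sroc
from dxmeta.study_table import ContingencyTable, metareg_design
from dxmeta.synthetic_data import MetaSimConfig, simulate_meta_dataset, simulate_tables


def _table(tp, fp, fn, tn, sid="t"):
    return ContingencyTable(tp, fp, fn, tn, study_id=sid)


class TestThreshold:
    def test_packaged_table_shows_no_threshold_effect(self, tables):
        res = threshold_spearman(tables)
        assert round(res.rho, 2) == 0.25
        assert res.p_value == pytest.approx(0.069, abs=5e-4)
        assert res.k == 54

    def test_planted_threshold_effect_detected(self):
        tabs, _ = simulate_tables(
            MetaSimConfig(k=50, mu=(1.0, 1.0), sigma=((0.3, 0.0), (0.0, 0.3)),
                          threshold_rho=0.9, size_range=(100, 300), seed=21)
        )
        res = threshold_spearman(tabs)
        assert res.rho > 0.5

    def test_monotone_transform_invariance(self, tables):
        # spearman on (TPR, FPR) directly equals spearman on their logits
        base = threshold_spearman(tables)
        from scipy.stats import spearmanr

        rho, _ = spearmanr([t.sen for t in tables], [t.fpr for t in tables])
        assert base.rho == pytest.approx(rho, abs=1e-12)

    def test_constant_rate_is_an_error(self):
        tabs = [_table(30, f, 30, 60 - f) for f in (5, 10, 20)]
        with pytest.raises(ValueError, match="constant"):
            threshold_spearman(tabs)


@pytest.fixture(scope="module")
def sample_type_report(records, tables):
    return subgroup_analysis(records, tables, "sample_type", seed=3, draws=1000)


class TestSubgroups:
    def test_circulating_outperforms_tissue(self, sample_type_report):
        circ, tissue = sample_type_report.groups
        assert (circ.label, tissue.label) == ("circulating", "tissue")
        assert (circ.k, tissue.k) == (19, 32)
        assert sample_type_report.n_excluded == 3  # gastric-juice rows
        assert round(circ.sroc.auc, 2) == pytest.approx(0.84, abs=0.011)
        assert round(tissue.sroc.auc, 2) == pytest.approx(0.77, abs=0.011)
        assert round(circ.estimate("dor").point) == 12
        assert round(tissue.estimate("dor").point) == 6

    def test_circulating_vs_tissue_difference_is_significant(self, sample_type_report):
        # printed two-sided p rounds to 0.01
        assert round(sample_type_report.comparison.p_value, 2) <= 0.01
        assert sample_type_report.comparison.p_value < 0.05

    def test_sample_size_groups_match_reported_dor(self, records, tables):
        rep = subgroup_analysis(records, tables, "sample_size", seed=3, draws=500)
        big, small = rep.groups
        assert (big.k, small.k) == (19, 35)
        assert round(big.estimate("dor").point) == 10
        assert round(small.estimate("dor").point) == 6

    def test_quality_groups_are_similar(self, records, tables):
        rep = subgroup_analysis(records, tables, "quality", seed=3, draws=500)
        hi, lo = rep.groups
        assert (hi.k, lo.k) == (38, 16)
        assert round(hi.sroc.auc, 2) == pytest.approx(0.80, abs=0.011)
        assert round(lo.sroc.auc, 2) == pytest.approx(0.78, abs=0.011)
        assert rep.comparison.p_value > 0.05

    def test_group_sizes_sum_to_eligible_rows(self, records, tables):
        rep = subgroup_analysis(records, tables, "location", seed=3, draws=200)
        eligible = sum(1 for r in records if r.location in ("intergenic", "antisense"))
        assert sum(g.k for g in rep.groups) == eligible

    def test_unknown_grouping_rejected(self, records, tables):
        with pytest.raises(ValueError, match="grouping"):
            subgroup_analysis(records, tables, "ethnicity")  # type: ignore[arg-type]


class TestMetaRegression:
    def test_sample_type_model_matches_reported_shape(self, records, tables):
        res = moses_metaregression(tables, metareg_design(records), ["sample_type"])
        term = res.term("sample_type")
        assert round(term.rdor, 2) == pytest.approx(1.82, abs=0.011)
        assert term.p_value < 0.01
        assert term.rdor_ci_low < term.rdor < term.rdor_ci_high
        assert res.tau2 == pytest.approx(0.475, abs=0.01)

    def test_sample_size_model_shows_positive_effect(self, records, tables):
        res = moses_metaregression(tables, metareg_design(records), ["sample_size"])
        term = res.term("sample_size")
        assert term.rdor > 1.5
        assert term.p_value < 0.05

    def test_rdor_is_exp_of_coefficient(self, records, tables):
        res = moses_metaregression(
            tables, metareg_design(records), ["location", "quality"]
        )
        for t in res.covariate_terms:
            assert t.rdor == pytest.approx(np.exp(t.coeff), rel=1e-12)

    def test_constant_covariate_is_rank_deficient(self, tables):
        design = {"flat": [1.0] * len(tables)}
        with pytest.raises(ValueError, match="rank"):
            moses_metaregression(tables, design, ["flat"])

    def test_without_covariates_equals_linear_sroc_line(self, tables):
        # oracle equivalence: the tau2=0 inverse-variance fit of D on S alone
        # reproduces the SROC regression under identical weighting
        u = np.array([logit(t.sen) for t in tables])
        v = np.array([logit(t.fpr) for t in tables])
        D, S = u - v, u + v
        var = np.array([1 / t.tp + 1 / t.fp + 1 / t.fn + 1 / t.tn for t in tables])
        w = 1 / var
        X = np.column_stack([np.ones(len(tables)), S])
        beta = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ D)
        c = moses_sroc(tables)
        assert c.intercept_a == pytest.approx(beta[0], rel=1e-9)
        assert c.slope_b == pytest.approx(beta[1], rel=1e-9)

    def test_balanced_orthogonal_design_rdor_equals_group_dor_ratio(self):
        # each group holds a symmetric S = +/- s pair with equal within-pair
        # variance, so S is weighted-orthogonal to the covariate and the RDOR
        # must equal the exact ratio of group DORs
        from scipy.special import expit

        def pair(d, s, sid):
            out = []
            for ss in (s, -s):
                sen = expit((ss + d) / 2)
                fpr = expit((ss - d) / 2)
                out.append(
                    _table(100 * sen, 100 * fpr, 100 * (1 - sen), 100 * (1 - fpr),
                           sid=f"{sid}{ss > 0}")
                )
            return out

        d_lo, d_hi, s = 0.9, 2.1, 0.8
        tabs = pair(d_lo, s, "lo") + pair(d_hi, s, "hi")
        x = {"grp": [1.0, 1.0, 2.0, 2.0]}
        res = moses_metaregression(tabs, x, ["grp"], tau2_method="mom")
        assert res.term("grp").rdor == pytest.approx(np.exp(d_hi - d_lo), rel=1e-6)


class TestBackwardElimination:
    def test_trajectory_on_packaged_table(self, records, tables):
        traj = backward_eliminate(tables, metareg_design(records))
        first = traj[0]
        worst = max(first.covariate_terms, key=lambda t: t.p_value)
        assert worst.name == "quality"           # largest p in the 4-covariate model
        # quality then location drop; the two survivors are reported singly
        survivors = {t.name for t in traj[2].covariate_terms}
        assert survivors == {"sample_type", "sample_size"}
        assert len(traj) == 5                    # A, B, C + two single-covariate models
        singles = {m.covariate_terms[0].name for m in traj[3:]}
        assert singles == {"sample_type", "sample_size"}

    def test_nothing_to_drop_gives_unit_trajectory(self, records, tables):
        traj = backward_eliminate(
            tables, metareg_design(records), start=["sample_type"]
        )
        assert len(traj) == 1

    def test_planted_covariate_effect_survives(self):
        # one real effect (ln RDOR = 0.6) among three null covariates
        kept = 0
        n_seeds = 10
        for seed in range(n_seeds):
            records, truth = simulate_meta_dataset(
                MetaSimConfig(
                    k=200, mu=(1.0, 1.0), sigma=((0.15, 0.0), (0.0, 0.15)),
                    size_range=(50, 200),
                    covariate_effects={"sample_type": 0.6},
                    seed=100 + seed,
                )
            )
            from dxmeta.study_table import reconstruct_all

            tabs = reconstruct_all(records)
            rng = np.random.default_rng(seed)
            design = {
                "sample_type": truth.covariates["sample_type"].astype(float),
                "n1": rng.integers(0, 2, 200).astype(float),
                "n2": rng.integers(0, 2, 200).astype(float),
                "n3": rng.integers(0, 2, 200).astype(float),
            }
            traj = backward_eliminate(tabs, design,
                                      start=["sample_type", "n1", "n2", "n3"])
            if any("sample_type" in {t.name for t in m.covariate_terms}
                   and m.term("sample_type").p_value < 0.05 for m in traj):
                kept += 1
        assert kept >= 9  # >= 90% of seeds
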