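import math

import numpy as np
import pytest
from scipy import stats

from informedbf.bayes_factors import (
    InvalidRecordError,
    StudyRecord,
    bf_ratio,
    bf_table,
    corr_bf10,
    corr_log_kernel,
    mc_marginal_oracle,
    posterior_prob_h1,
    ttest_bf10,
    ttest_log_kernel,
)
from informedbf.priors import PriorSpec


class TestStudyRecord:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="correlation", r=1.0, n=50),
            dict(kind="correlation", r=0.5, n=3),
            dict(kind="ttest", design="one_sample", t=2.0, n1=1),
            dict(kind="ttest", design="independent", t=2.0, n1=10, n2=1),
            dict(kind="ttest", design="sideways", t=2.0, n1=10),
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(InvalidRecordError):
            StudyRecord(study_id="x", **kwargs)

    def test_design_conventions(self):
        one = StudyRecord("a", "ttest", design="one_sample", t=1.0, n1=24)
        assert one.df == 23 and one.n_eff == 24
        ind = StudyRecord("b", "ttest", design="independent", t=1.0, n1=30, n2=60)
        assert ind.df == 88 and ind.n_eff == pytest.approx(20.0)


class TestCorrBF:
    def test_point_null_prior_gives_unit_bf(self, registry):
        res = corr_bf10(0.3, 260, registry["null (rho)"])
        assert res.bf10 == pytest.approx(1.0)

    def test_point_prior_equals_kernel(self):
        spec = PriorSpec("point", {"value": 0.25}, "pt")
        res = corr_bf10(0.4, 80, spec)
        assert res.log_bf10 == pytest.approx(corr_log_kernel(0.25, 0.4, 80))

    def test_matches_monte_carlo_oracle(self, registry):
        rec = StudyRecord("s", "correlation", r=0.3, n=260)
        quad = corr_bf10(0.3, 260, registry["default (rho)"])
        mc, se = mc_marginal_oracle(rec, registry["default (rho)"], 100_000, seed=11)
        assert abs(quad.bf10 - mc) < 3 * se

    def test_monotone_in_r_for_positive_prior(self, registry):
        prior = registry["Expert 3 (beta)"]
        rs = np.linspace(0.0, 0.9, 10)
        logs = [corr_bf10(r, 60, prior).log_bf10 for r in rs]
        assert np.all(np.diff(logs) > 0)

    def test_null_data_favor_h0_for_all_registry_priors(self, registry):
        for label, spec in registry.items():
            if spec.family not in ("beta", "uniform"):
                continue
            assert corr_bf10(0.0, 100, spec).bf10 < 1.0, label

    def test_invalid_inputs(self, registry):
        with pytest.raises(InvalidRecordError):
            corr_bf10(1.0, 50, registry["default (rho)"])
        with pytest.raises(InvalidRecordError):
            corr_bf10(0.2, 3, registry["default (rho)"])
        with pytest.raises(ValueError):
            corr_bf10(0.2, 50, registry["default (delta)"])  # wrong support


class TestTTestBF:
    def test_null_point_prior_gives_unit_bf(self, registry):
        rec = StudyRecord("s", "ttest", design="one_sample", t=2.5, n1=24)
        assert ttest_bf10(rec, registry["null (delta)"]).bf10 == pytest.approx(1.0)

    def test_point_prior_closed_form(self):
        rec = StudyRecord("s", "ttest", design="one_sample", t=2.5, n1=24)
        spec = PriorSpec("point", {"value": 0.4}, "pt")
        expected = math.exp(
            stats.nct.logpdf(2.5, 23, 0.4 * math.sqrt(24)) - stats.t.logpdf(2.5, 23)
        )
        assert ttest_bf10(rec, spec).bf10 == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize(
        "design,t,n1,n2",
        [("one_sample", 2.5, 24, None), ("paired", -0.8, 40, None), ("independent", 1.6, 30, 45)],
    )
    def test_matches_monte_carlo_oracle(self, registry, design, t, n1, n2):
        rec = StudyRecord("s", "ttest", design=design, t=t, n1=n1, n2=n2)
        quad = ttest_bf10(rec, registry["default (delta)"])
        mc, se = mc_marginal_oracle(rec, registry["default (delta)"], 100_000, seed=5)
        assert abs(quad.bf10 - mc) < 3 * se

    def test_negative_t_favors_null_under_positive_prior(self, registry):
        rec = StudyRecord("s", "ttest", design="one_sample", t=-2.0, n1=30)
        assert ttest_bf10(rec, registry["Expert 3 (t)"]).bf10 < 1.0


class TestDerivedQuantities:
    def test_posterior_probability(self):
        assert posterior_prob_h1(1.0) == pytest.approx(0.5)
        assert posterior_prob_h1(3.0) == pytest.approx(0.75)
        assert posterior_prob_h1(3.0, prior_odds=1 / 3) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            posterior_prob_h1(-1.0)

    def test_ratio_transitivity_and_identity(self, registry):
        a = corr_bf10(0.3, 100, registry["Expert 2 (beta)"], study_id="s")
        b = corr_bf10(0.3, 100, registry["Expert 5 (beta)"], study_id="s")
        c = corr_bf10(0.3, 100, registry["default (rho)"], study_id="s")
        assert bf_ratio(a, a) == pytest.approx(1.0)
        assert bf_ratio(a, b) * bf_ratio(b, c) == pytest.approx(bf_ratio(a, c))

    def test_ratio_requires_same_study(self, registry):
        a = corr_bf10(0.3, 100, registry["Expert 2 (beta)"], study_id="s1")
        b = corr_bf10(0.3, 100, registry["Expert 5 (beta)"], study_id="s2")
        with pytest.raises(ValueError):
            bf_ratio(a, b)


class TestOracle:
    def test_point_prior_zero_se(self, registry):
        rec = StudyRecord("s", "correlation", r=0.2, n=60)
        est, se = mc_marginal_oracle(rec, registry["null (rho)"], 10_000, seed=1)
        assert se == 0.0 and est == pytest.approx(1.0)

    def test_seed_determinism(self, registry):
        rec = StudyRecord("s", "correlation", r=0.2, n=100)
        a = mc_marginal_oracle(rec, registry["Expert 5 (beta)"], 10_000, seed=3)
        b = mc_marginal_oracle(rec, registry["Expert 5 (beta)"], 10_000, seed=3)
        assert a == b

    def test_quadrature_within_3se(self, registry):
        rec = StudyRecord("s", "correlation", r=0.2, n=100)
        quad = corr_bf10(0.2, 100, registry["Expert 5 (beta)"])
        est, se = mc_marginal_oracle(rec, registry["Expert 5 (beta)"], 100_000, seed=3)
        assert abs(quad.bf10 - est) < 3 * se


class TestSupremumBound:
    def test_bf_below_oracle_prior_bound(self, registry):
        # no prior can beat the best point mass ("oracle prior")
        grid = np.linspace(0, 1 - 1e-9, 4001)
        sup = float(np.max(np.exp(corr_log_kernel(grid, 0.3, 260))))
        for label, spec in registry.items():
            if spec.family in ("beta", "uniform"):
                assert corr_bf10(0.3, 260, spec).bf10 <= sup * (1 + 1e-9), label


class TestPredictiveAccuracyReward:
    def test_matched_prior_mode_earns_higher_median_bf(self, registry):
        # data generated at Expert 6's beta mode: E6 should out-predict experts
        # whose prior mode lies at least 0.2 away (E1 at 0, E2 at 0.197)
        rng = np.random.default_rng(2024)
        true_rho = registry["Expert 6 (beta)"].mode()
        logs = {lab: [] for lab in ("Expert 6 (beta)", "Expert 1 (beta)", "Expert 2 (beta)")}
        for _ in range(40):
            n = 150
            x = rng.standard_normal(n)
            y = true_rho * x + math.sqrt(1 - true_rho**2) * rng.standard_normal(n)
            r = float(np.corrcoef(x, y)[0, 1])
            for lab in logs:
                logs[lab].append(corr_bf10(r, n, registry[lab]).log_bf10)
        med = {lab: np.median(v) for lab, v in logs.items()}
        assert med["Expert 6 (beta)"] > med["Expert 1 (beta)"]
        assert med["Expert 6 (beta)"] > med["Expert 2 (beta)"]


class TestBatch:
    def test_long_format_and_skip(self, registry):
        records = [
            StudyRecord("a", "correlation", r=0.2, n=50),
            StudyRecord("b", "correlation", r=-0.4, n=30),
        ]
        priors = {k: registry[k] for k in ("Expert 1 (beta)", "default (rho)")}
        df = bf_table(records, priors)
        assert list(df.columns) == ["study_id", "prior_label", "log_bf10", "bf10"]
        assert len(df) == 4
        np.testing.assert_allclose(df["bf10"], np.exp(df["log_bf10"]))
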