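"""Univariate tests, logistic regression and the feature-selection report."""

import numpy as np
import pandas as pd
import pytest

from bristlekit.stats import (
    Cohort,
    IRLSLogisticRegression,
    feature_selection_report,
    fit_logistic,
    kruskal_wallis,
    likelihood_ratio_test,
    mann_whitney_u,
    LRT_MODEL_SEQUENCE,
)

from _oracles import enumerated_mwu_pvalue


class TestKruskalWallis:
    def test_three_group_rank_formula(self):
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7)

    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert h == 0.0 and p == 1.0

    def test_invariant_under_monotone_transform(self):
        groups = [[1.0, 5.0, 9.0], [2.0, 6.0], [3.0, 7.0, 11.0]]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([[np.exp(v) for v in g] for g in groups])
        assert h1 == pytest.approx(h2)

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestMannWhitney:
    def test_small_sample_exact_case(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_swap_antisymmetry(self):
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0, 7.0]
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(b, a)
        assert u1 + u2 == pytest.approx(len(a) * len(b))
        assert p1 == pytest.approx(p2)

    def test_identical_samples_centre_u(self):
        a = [1.0, 2.0, 3.0]
        u, p = mann_whitney_u(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (3, 3), (4, 5), (6, 6), (2, 6)])
    def test_exact_p_matches_full_enumeration(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(5):
            pooled = rng.choice(1000, size=n_a + n_b, replace=False).astype(float)
            a, b = pooled[:n_a], pooled[n_a:]
            u, p = mann_whitney_u(a, b)
            u_ref, p_ref = enumerated_mwu_pvalue(a, b)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_tied_large_samples_use_corrected_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, 30).astype(float)
        b = (rng.integers(0, 5, 30) + 1).astype(float)
        u, p = mann_whitney_u(a, b)
        assert 0 <= p <= 1


class TestLogisticIRLS:
    def test_symmetric_response_gives_zero_coefficients(self):
        res = fit_logistic(np.array([0.0, 0.0, 1.0, 1.0]), [0, 1, 0, 1])
        np.testing.assert_allclose(res.coefficients, 0.0, atol=1e-8)

    def test_intercept_only_closed_form(self):
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]  # k=3 of n=10
        res = fit_logistic(np.empty((10, 0)), y)
        k, n = 3, 10
        assert res.coefficients[0] == pytest.approx(np.log(k / (n - k)), abs=1e-8)
        expected_ll = k * np.log(k / n) + (n - k) * np.log(1 - k / n)
        assert res.log_likelihood == pytest.approx(expected_ll, abs=1e-8)

    def test_perfect_separation_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = [0, 0, 0, 1, 1, 1]
        res = fit_logistic(x, y)
        assert not res.converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.arange(4.0), [1, 1, 1, 1])

    def test_matches_statsmodels_mle(self):
        # independent cross-check against an established IRLS implementation
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 2))
        eta = 0.4 + 1.2 * X[:, 0] - 0.7 * X[:, 1]
        y = rng.uniform(size=80) < 1 / (1 + np.exp(-eta))
        res = fit_logistic(X, y.astype(int))
        ref = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(res.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(res.std_errors, ref.bse, atol=1e-5)
        assert res.log_likelihood == pytest.approx(ref.llf, abs=1e-8)

    def test_estimator_predicts_probabilities(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 1))
        y = (X[:, 0] + rng.normal(scale=0.5, size=60) > 0).astype(int)
        est = IRLSLogisticRegression().fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (60, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert (est.predict(X) == (proba[:, 1] > 0.5)).all()


class TestLikelihoodRatio:
    def _fits(self, rng, beta2=0.0, n=100):
        X = rng.normal(size=(n, 2))
        eta = 0.2 + 0.8 * X[:, 0] + beta2 * X[:, 1]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        nested = fit_logistic(pd.DataFrame({"x1": X[:, 0]}), y)
        full = fit_logistic(pd.DataFrame({"x1": X[:, 0], "x2": X[:, 1]}), y)
        return nested, full

    def test_identical_models_give_zero_statistic(self):
        nested, _ = self._fits(np.random.default_rng(0))
        res = likelihood_ratio_test(nested, nested)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_df_is_added_parameter_count(self):
        nested, full = self._fits(np.random.default_rng(3))
        assert likelihood_ratio_test(nested, full).df == 1

    def test_full_likelihood_dominates_nested(self):
        for seed in range(10):
            nested, full = self._fits(np.random.default_rng(seed), beta2=0.5)
            assert full.log_likelihood >= nested.log_likelihood - 1e-8

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 2))
        y = (rng.uniform(size=50) < 0.5).astype(int)
        m1 = fit_logistic(pd.DataFrame({"a": X[:, 0]}), y)
        m2 = fit_logistic(pd.DataFrame({"b": X[:, 1]}), y)
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(m1, m2)


class TestFeatureSelectionReport:
    def test_report_shapes_and_model_list(self, small_cohort):
        report = feature_selection_report(small_cohort, "dense_heterogeneous")
        assert report.control_group == "wildtype"
        assert list(report.univariate["feature"]) == ["RSA", "CN", "OP", "CQ", "CSV"]
        assert list(report.lrt["model"]) == [m for m, _, _ in LRT_MODEL_SEQUENCE]
        assert set(report.multiple_regression["feature"]) == {"RSA", "OP", "CQ", "CSV"}
        assert ((report.univariate["p_value"] >= 0) & (report.univariate["p_value"] <= 1)).all()

    def test_density_and_heterogeneity_shift_detected(self, small_cohort):
        report = feature_selection_report(small_cohort, "dense_heterogeneous")
        uni = report.univariate.set_index("feature")["p_value"]
        assert uni["RSA"] < 0.05
        assert uni["CSV"] < 0.05

    def test_unknown_mutant_rejected(self, small_cohort):
        with pytest.raises(KeyError):
            feature_selection_report(small_cohort, "nonexistent")

    def test_too_few_patterns_rejected(self):
        df = pd.DataFrame(
            {
                "pattern_id": ["a", "b", "c"],
                "group": ["ctl", "ctl", "mut"],
                "RSA": [0.1, 0.2, 0.3],
                "CN": [1, 2, 3],
                "OP": [0.1, 0.1, 0.2],
                "CQ": [0.4, 0.5, 0.6],
                "CSV": [0.01, 0.02, 0.03],
            }
        )
        cohort = Cohort(features=df, pairing={"mut": "ctl"})
        with pytest.raises(ValueError, match="at least 3"):
            feature_selection_report(cohort, "mut")
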