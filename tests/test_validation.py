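"""Marker validation statistics: Pearson, Steiger, regression, LOO, Kruskal."""

import numpy as np
import pandas as pd
import pytest

from rvatlas.validation import (
    compare_errors_kruskal,
    compare_models,
    covariate_regression,
    loo_predict,
    pearson,
    steiger_test,
    validate_markers,
)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_orthogonalised_input_zero_correlation(self):
        rng = np.random.default_rng(0)
        xc = rng.normal(size=50)
        xc -= xc.mean()
        y = rng.normal(size=50)
        yc = y - y.mean()
        y_perp = yc - (yc @ xc) / (xc @ xc) * xc
        r, _ = pearson(xc, y_perp)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_matches_explicit_formula_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, _ = pearson(x, y)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(10), np.arange(10.0))


class TestSteiger:
    def test_equal_correlations_give_zero(self):
        z, p = steiger_test(0.4, 0.4, 0.5, 100)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry_under_swap(self):
        z1, p1 = steiger_test(0.5, 0.3, 0.4, 80)
        z2, p2 = steiger_test(0.3, 0.5, 0.4, 80)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            steiger_test(1.0, 0.3, 0.2, 50)

    def test_null_type_i_error_calibrated(self):
        """Empirical size at n=100 over 5000 simulated null triples."""
        rng = np.random.default_rng(42)
        C = np.array([[1, 0.4, 0.4], [0.4, 1, 0.5], [0.4, 0.5, 1.0]])
        L = np.linalg.cholesky(C)
        rej = 0
        for _ in range(5000):
            X = rng.standard_normal((100, 3)) @ L.T
            R = np.corrcoef(X, rowvar=False)
            _, p = steiger_test(R[0, 1], R[0, 2], R[1, 2], 100)
            rej += p < 0.05
        assert 0.04 <= rej / 5000 <= 0.06


class TestCovariateRegression:
    def test_marker_equal_to_rvef_dominates_variance(self, tiny_covariates):
        rng = np.random.default_rng(2)
        rvef = rng.normal(57, 7, 12)
        res = covariate_regression(rvef, tiny_covariates, rvef, n_boot=0)
        assert res.variance_fractions["marker"] == pytest.approx(1.0, abs=0.05)

    def test_independent_marker_explains_nothing(self, null_generator):
        ds = null_generator.generate(seed=1)
        marker = np.random.default_rng(3).normal(size=ds.n_subjects)
        res = covariate_regression(marker, ds.covariates, ds.rvef, n_boot=0)
        assert res.variance_fractions["marker"] < 0.05

    def test_coefficients_match_normal_equations_oracle(self, tiny_covariates):
        from rvatlas.massuni import build_design

        rng = np.random.default_rng(4)
        rvef = rng.normal(57, 7, 12)
        marker = 0.5 * rvef + rng.normal(0, 3, 12)
        res = covariate_regression(marker, tiny_covariates, rvef, n_boot=0)
        Z = build_design(tiny_covariates)
        ms = (marker - marker.mean()) / marker.std()
        X = np.column_stack([Z[:, :1], ms, Z[:, 1:]])
        y = (rvef - rvef.mean()) / rvef.std()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.coefficients, beta, atol=1e-10)

    def test_variance_fractions_bounded(self, desk_cohort):
        res = covariate_regression(
            desk_cohort.markers["SPM-O"].to_numpy(),
            desk_cohort.covariates, desk_cohort.rvef, n_boot=0,
        )
        fr = res.variance_fractions
        assert all(0 <= v <= 1 for v in fr.values())
        assert sum(fr.values()) <= 1 + 1e-9


class TestCompareModels:
    def test_identical_markers_zero_interaction(self, tiny_covariates):
        rng = np.random.default_rng(5)
        rvef = rng.normal(57, 7, 12)
        m = 0.5 * rvef + rng.normal(0, 3, 12)
        coef, _ = compare_models(m, m, tiny_covariates, rvef)
        assert coef == pytest.approx(0.0, abs=1e-10)

    def test_pure_noise_addition_rarely_significant(self, desk_generator):
        hits = 0
        for rep in range(10):
            ds = desk_generator.generate(seed=500 + rep)
            a = ds.markers["SPM-O"].to_numpy()
            b = a + np.random.default_rng(rep).normal(0, 0.3, a.shape)
            _, p = compare_models(a, b, ds.covariates, ds.rvef)
            hits += p < 0.05
        assert hits <= 1

    def test_planted_slope_difference_detected(self, desk_generator):
        detected = 0
        for rep in range(10):
            ds = desk_generator.generate(seed=900 + rep)
            rng = np.random.default_rng(rep)
            y = (ds.rvef - ds.rvef.mean()) / ds.rvef.std()
            a = 0.6 * y + rng.normal(0, np.sqrt(1 - 0.36), ds.n_subjects)
            b = 0.2 * y + rng.normal(0, np.sqrt(1 - 0.04), ds.n_subjects)
            _, p = compare_models(a, b, ds.covariates, ds.rvef)
            detected += p < 0.05
        assert detected >= 8


class TestLeaveOneOut:
    def test_marker_equal_to_rvef_perfect_prediction(self, null_generator):
        ds = null_generator.generate(seed=2)
        loo = loo_predict(ds.rvef, ds.covariates, ds.rvef, ds.edv)
        assert loo["abs_error_ef"].max() < 1e-8

    def test_matches_hat_matrix_deletion_formula(self, null_generator):
        from rvatlas.massuni import build_design, _zscore
        from rvatlas.validation import _design_with_marker

        ds = null_generator.generate(seed=3)
        marker = ds.markers["TAPSE"].to_numpy()
        loo = loo_predict(marker, ds.covariates, ds.rvef, ds.edv)
        X, _, _ = _design_with_marker(marker, ds.covariates)
        y = _zscore(ds.rvef)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        yhat = X @ beta
        H = X @ np.linalg.pinv(X.T @ X) @ X.T
        h = np.diag(H)
        e = y - yhat
        pred_loo = yhat - h * e / (1 - h)
        pred_ef = ds.rvef.mean() + ds.rvef.std() * pred_loo
        np.testing.assert_allclose(loo["predicted_rvef"], pred_ef, atol=1e-8)

    def test_null_marker_no_better_than_covariates_only(self, desk_generator):
        ds = desk_generator.generate(seed=77)
        rng = np.random.default_rng(0)
        null_marker = rng.normal(size=ds.n_subjects)
        med_null = np.median(
            loo_predict(null_marker, ds.covariates, ds.rvef, ds.edv)["abs_error_ef"]
        )
        med_real = np.median(
            loo_predict(ds.markers["SPM-O"].to_numpy(), ds.covariates, ds.rvef,
                        ds.edv)["abs_error_ef"]
        )
        assert med_real < med_null * 1.05

    def test_too_few_subjects_rejected(self, tiny_covariates):
        rng = np.random.default_rng(6)
        rvef = rng.normal(57, 7, 12)
        with pytest.raises(ValueError):
            loo_predict(rvef, tiny_covariates, rvef, np.full(12, 140.0))


class TestKruskal:
    def test_identical_groups_h_zero(self):
        g = {"a": np.ones(5), "b": np.ones(5), "c": np.ones(5)}
        h, p = compare_errors_kruskal(g)
        assert h == 0.0 and p == 1.0

    def test_hand_computed_three_groups_with_ties(self):
        groups = {
            "a": np.array([1.0, 2.0, 3.0]),
            "b": np.array([2.0, 4.0, 5.0]),
            "c": np.array([6.0, 7.0, 8.0]),
        }
        h, p = compare_errors_kruskal(groups)
        # hand computation: ranks of 1,2,2,3,4,5,6,7,8 with the tie at 2
        ranks = {1.0: 1, 2.0: 2.5, 3.0: 4, 4.0: 5, 5.0: 6, 6.0: 7, 7.0: 8, 8.0: 9}
        n, k = 9, 3
        R = [sum(ranks[v] for v in groups[g]) for g in groups]
        h_raw = 12 / (n * (n + 1)) * sum(r**2 / 3 for r in R) - 3 * (n + 1)
        tie = 1 - (2**3 - 2) / (n**3 - n)
        assert h == pytest.approx(h_raw / tie, abs=1e-10)

    def test_label_permutation_null_p_roughly_uniform(self):
        rng = np.random.default_rng(7)
        pool = rng.normal(size=60)
        ps = []
        for _ in range(300):
            perm = rng.permutation(pool)
            g = {"a": perm[:20], "b": perm[20:40], "c": perm[40:]}
            ps.append(compare_errors_kruskal(g)[1])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_errors_kruskal({"a": np.ones(3), "b": np.array([])})


class TestValidateMarkers:
    def test_report_schema_complete(self, desk_cohort):
        rep = validate_markers(
            desk_cohort.markers, desk_cohort.covariates, desk_cohort.rvef,
            desk_cohort.edv, n_boot=50, seed=0,
        )
        assert set(rep.correlations) == {"SPM-O", "SFD-F", "TAPSE-F", "TAPSE", "SFD"}
        assert set(rep.steiger) == {"SFD-F", "TAPSE-F", "TAPSE", "SFD"}
        assert np.isfinite(rep.kruskal_p)
        for m, s in rep.loo_errors_ml.items():
            assert s["iqr_low"] <= s["median"] <= s["iqr_high"]

    def test_missing_reference_rejected(self, desk_cohort):
        with pytest.raises(KeyError):
            validate_markers(
                desk_cohort.markers.drop(columns=["SPM-O"]),
                desk_cohort.covariates, desk_cohort.rvef, desk_cohort.edv,
            )
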