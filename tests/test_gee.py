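"""The GEE engine: estimating equations, sandwich inference, QIC,
PRESS-based predictive R^2 and stratified slope contrasts."""

import numpy as np
import pandas as pd
import pytest

import nephromorph as nm
from nephromorph.errors import (
    InvalidParameterError,
    SingularDesignError,
    StratificationError,
    UndefinedResultError,
)
from nephromorph.gee import GEEModel
from nephromorph.longitudinal import (
    ModelSpec,
    fit_gee,
    loo_press_r2,
    stratified_slope_test,
)


def _clustered_data(rng, m=30, nper=5, p=4, rho=0.5):
    X = rng.normal(size=(m * nper, p))
    X[:, 0] = 1.0
    groups = np.repeat(np.arange(m), nper)
    beta = rng.normal(size=p)
    shared = np.repeat(rng.normal(0, 1, m), nper)
    e = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(0, 1, m * nper)
    return X, groups, beta, X @ beta + e


class TestEstimation:
    def test_independence_equals_ols_oracle(self, rng):
        """Closed-form normal equations are the oracle for the
        independence working correlation."""
        for _ in range(20):
            X, groups, beta, y = _clustered_data(rng)
            fit = GEEModel(y, X, groups).fit()
            ols = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.max(np.abs(fit.params - ols)) < 1e-8

    def test_toy_two_cluster_slope(self):
        """Hand-computed OLS on {(0,1),(1,2),(2,3)} and {(0,2),(1,3),(2,4)}."""
        t = np.array([0.0, 1, 2, 0, 1, 2])
        y = np.array([1.0, 2, 3, 2, 3, 4])
        X = np.column_stack([np.ones(6), t])
        fit = GEEModel(y, X, np.array([1, 1, 1, 2, 2, 2])).fit()
        assert fit.params[1] == pytest.approx(1.0, abs=1e-10)
        assert fit.params[0] == pytest.approx(1.5, abs=1e-10)

    def test_exchangeable_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(5):
            X, groups, beta, y = _clustered_data(rng)
            fit = GEEModel(y, X, groups, working_correlation="exchangeable").fit(
                cov_type="robust"
            )
            oracle = sm.GEE(
                y, X, groups=groups, cov_struct=sm.cov_struct.Exchangeable()
            ).fit()
            assert np.max(np.abs(fit.params - oracle.params)) < 1e-6
            assert np.max(np.abs(fit.bse - oracle.bse)) < 1e-6

    def test_rank_deficient_design_names_offender(self, rng):
        X, groups, beta, y = _clustered_data(rng)
        X2 = np.column_stack([X, X[:, 1] * 2.0])
        with pytest.raises(SingularDesignError):
            GEEModel(y, X2, groups, exog_names=["a", "b", "c", "d", "dup"])

    def test_sandwich_approaches_model_based_for_singleton_clusters(self, rng):
        """With one observation per cluster, independence working
        correlation and homoscedastic errors, the sandwich converges to
        the model-based covariance (they differ at finite n because the
        sandwich uses per-observation squared residuals)."""
        n = 5000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(size=n)
        fit = GEEModel(y, X, np.arange(n)).fit(cov_type="robust")
        rel = np.abs(np.diag(fit.robust_cov) / np.diag(fit.model_cov) - 1.0)
        assert rel.max() < 0.05

    def test_robust_wald_coverage_exchangeable(self, rng):
        """95% robust Wald intervals cover each true coefficient at
        nominal rate (+-3%) over 200 exchangeable-noise replicates."""
        m, nper, p = 150, 5, 4
        beta = np.array([1.0, -0.5, 0.25, 2.0])
        reps = 200
        cover = np.zeros(p)
        for _ in range(reps):
            X = rng.normal(size=(m * nper, p))
            X[:, 0] = 1.0
            groups = np.repeat(np.arange(m), nper)
            shared = np.repeat(rng.normal(0, 1, m), nper)
            e = np.sqrt(0.5) * shared + np.sqrt(0.5) * rng.normal(0, 1, m * nper)
            y = X @ beta + e
            fit = GEEModel(y, X, groups, working_correlation="exchangeable").fit()
            ci = fit.conf_int()
            cover += (ci[:, 0] <= beta) & (beta <= ci[:, 1])
        cover /= reps
        assert np.all(cover >= 0.92) and np.all(cover <= 0.98)


class TestQIC:
    def test_trace_near_parameter_count_under_independence(self, rng):
        """On truly independent data the QIC penalty trace approaches
        the parameter count."""
        n, p = 500, 5
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        fit = GEEModel(y, X, np.arange(n)).fit(cov_type="robust")
        assert fit.qic_trace() == pytest.approx(p, rel=0.10)

    def test_trace_positive(self, rng):
        X, groups, beta, y = _clustered_data(rng)
        fit = GEEModel(y, X, groups).fit()
        assert fit.qic_trace() > 0

    def test_invariant_to_covariate_reordering(self, study_dataset):
        spec = ModelSpec.clinical(structural=("FIA", "FATA"))
        fit = fit_gee(study_dataset, spec)
        reordered = ModelSpec(
            covariates=tuple(reversed(spec.covariates)), name="reordered"
        )
        fit2 = fit_gee(study_dataset, reordered)
        assert fit.qic() == pytest.approx(fit2.qic(), rel=1e-10)


class TestPressR2:
    def test_arithmetic_identity(self):
        from nephromorph.longitudinal import FitQuality

        q = FitQuality(qic=0.0, press=5.0, ssr=10.0, r2_pred=1 - 5.0 / 10.0)
        assert q.r2_pred == 0.5

    def test_candidate_equal_to_reference_gains_nothing(self, rng):
        """When the candidate IS the time-only model, PRESS >= SSR in
        expectation so the predictive R^2 is at most slightly positive."""
        visits = []
        for i in range(40):
            times = np.arange(0, 30, 5.0)
            y = 90 - 0.3 * times + rng.normal(0, 5, len(times))
            visits += [(f"s{i}", t, v) for t, v in zip(times, y)]
        visits = pd.DataFrame(visits, columns=["subject_id", "time", "egfr"])
        subjects = pd.DataFrame(index=pd.Index([f"s{i}" for i in range(40)],
                                               name="subject_id"))
        ds = nm.AnalysisDataset(subjects=subjects, visits=visits)
        q = loo_press_r2(ds, ModelSpec.time_only())
        assert q.r2_pred <= 0.02

    def test_r2_improves_when_true_covariate_added(self, study_dataset):
        """Adding baseline eGFR (a dominant true effect) to a time-only
        model raises predictive R^2."""
        weak = ModelSpec(covariates=("age", "time"), name="weak")
        strong = ModelSpec(covariates=("age", "time", "baseline_egfr"), name="strong")
        q_weak = loo_press_r2(study_dataset, weak)
        q_strong = loo_press_r2(study_dataset, strong)
        assert q_strong.r2_pred > q_weak.r2_pred

    def test_zero_reference_ssr_is_undefined(self):
        visits = []
        for i in range(5):
            for t in (0.0, 6.0, 12.0):
                visits.append((f"s{i}", t, 100.0 - t))  # exact time trend
        visits = pd.DataFrame(visits, columns=["subject_id", "time", "egfr"])
        subjects = pd.DataFrame(index=pd.Index([f"s{i}" for i in range(5)],
                                               name="subject_id"))
        ds = nm.AnalysisDataset(subjects=subjects, visits=visits)
        with pytest.raises(UndefinedResultError):
            loo_press_r2(ds, ModelSpec.time_only())


class TestStratifiedSlopes:
    def _dataset(self, rng, n=200, top_effect=0.0, noise=0.0):
        ids = [f"s{i}" for i in range(n)]
        fata = rng.uniform(0, 1, n)
        cut = np.quantile(fata, 0.75)
        subjects = pd.DataFrame({"FATA": fata},
                                index=pd.Index(ids, name="subject_id"))
        rows = []
        for i, sid in enumerate(ids):
            slope = -0.05 + (top_effect if fata[i] > cut else 0.0)
            for t in np.arange(0, 45, 5.0):
                rows.append((sid, t, 90 + slope * t + rng.normal(0, noise)))
        visits = pd.DataFrame(rows, columns=["subject_id", "time", "egfr"])
        return nm.AnalysisDataset(subjects=subjects, visits=visits)

    def test_equal_slopes_give_zero_contrasts(self, rng):
        ds = self._dataset(rng, n=80, top_effect=0.0, noise=0.0)
        result = stratified_slope_test(ds)
        assert np.allclose(result.contrasts, 0.0, atol=1e-10)

    def test_quartile_counts_balanced(self, rng):
        ds = self._dataset(rng, n=200, noise=1.0)
        result = stratified_slope_test(ds)
        assert max(result.counts) - min(result.counts) <= 1

    def test_power_to_detect_top_quartile_decline(self, rng):
        """A -0.1/month extra slope confined to the top quartile is
        detected (p < 0.01) in at least 90% of replicates."""
        detected = 0
        reps = 60
        for _ in range(reps):
            ds = self._dataset(rng, n=200, top_effect=-0.1, noise=4.0)
            result = stratified_slope_test(ds)
            detected += result.contrast_p[-1] < 0.01
        assert detected / reps >= 0.90

    def test_missing_stratifier_is_an_error(self, study_dataset):
        with pytest.raises(InvalidParameterError):
            stratified_slope_test(study_dataset, stratifier="nonexistent")

    def test_constant_stratifier_gives_empty_stratum(self, rng):
        ds = self._dataset(rng, n=40, noise=1.0)
        ds.subjects["FATA"] = 0.5
        with pytest.raises(StratificationError):
            stratified_slope_test(ds)
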