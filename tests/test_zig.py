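"""The combined two-part model: likelihood factoring, predictions, reports."""

import numpy as np
import pandas as pd
import pytest

import zigreg as zg

from conftest import intercept_only


@pytest.fixture()
def six_point_fit():
    """The worked intercept-only example: half zeros, positives 100/200/300."""
    y = np.array([0.0, 0.0, 0.0, 100.0, 200.0, 300.0])
    dm = intercept_only(6)
    return zg.fit_zig(dm, dm, y), y, dm


class TestWorkedExample:
    def test_closed_form_parts(self, six_point_fit):
        fit, _, _ = six_point_fit
        # p-hat = 0.5 -> zero log-odds intercept; gamma intercept = mean of positives
        assert fit.logistic.params[0] == pytest.approx(0.0, abs=1e-9)
        assert fit.gamma.params[0] == pytest.approx(200.0, rel=1e-9)
        assert fit.n == 6 and fit.n_zero == 3 and fit.n_positive == 3

    def test_predicted_marginal_mean(self, six_point_fit):
        fit, _, _ = six_point_fit
        assert fit.predict_mean_time([1.0], [1.0]) == pytest.approx(100.0, rel=1e-9)

    def test_total_is_sum_of_parts(self, six_point_fit):
        fit, _, _ = six_point_fit
        assert fit.total_loglik == pytest.approx(
            fit.logistic.loglik + fit.gamma.loglik, abs=1e-12
        )


class TestFactoredLikelihood:
    def test_zig_loglik_matches_fit_at_optimum(self, simulated_cohort):
        df, dm = simulated_cohort
        y = df["weekly_minutes"].to_numpy()
        fit = zg.ZeroInflatedGamma(y, dm).fit()
        ll = zg.zig_loglik(
            fit.logistic.params, fit.gamma.params, fit.gamma.nu, dm, dm, y
        )
        assert ll == pytest.approx(fit.total_loglik, rel=1e-12)

    def test_fitted_point_is_local_maximum(self, six_point_fit, rng):
        fit, y, dm = six_point_fit
        base = fit.total_loglik
        for _ in range(20):
            da = rng.normal(scale=1e-3)
            db = rng.normal(scale=1e-1)
            dn = rng.normal(scale=1e-3)
            ll = zg.zig_loglik(
                fit.logistic.params + da, fit.gamma.params + db,
                max(fit.gamma.nu + dn, 1e-3), dm, dm, y,
            )
            assert ll <= base + 1e-9

    def test_reduces_to_pure_gamma_when_no_zeros_possible(self, rng):
        y = rng.gamma(2.0, 40.0, 50)
        dm = intercept_only(50)
        from zigreg.gamma import gamma_cv_loglik

        mu = np.full(50, y.mean())
        # with p == 1 (huge logistic intercept) only the gamma factor remains
        ll = zg.zig_loglik([500.0], [y.mean()], 0.7, dm, dm, y)
        assert ll == pytest.approx(gamma_cv_loglik(y, mu, 0.7), rel=1e-12)

    def test_nonpositive_mu_on_positive_row_rejected(self, six_point_fit):
        _, y, dm = six_point_fit
        with pytest.raises(ValueError, match="non-positive"):
            zg.zig_loglik([0.0], [-5.0], 1.0, dm, dm, y)


class TestFitContracts:
    def test_gamma_part_sees_exactly_positive_rows(self, simulated_cohort):
        df, dm = simulated_cohort
        y = df["weekly_minutes"].to_numpy()
        fit = zg.ZeroInflatedGamma(y, dm).fit()
        assert fit.n_positive == int((y > 0).sum())
        assert fit.gamma.n_positive == fit.n_positive
        assert fit.logistic.n == fit.n == len(y)
        assert fit.n == fit.n_zero + fit.n_positive

    def test_parts_may_use_different_designs(self, simulated_cohort):
        df, dm = simulated_cohort
        y = df["weekly_minutes"].to_numpy()
        W = zg.DesignMatrix(
            columns=("intercept", "male"), values=dm.values[:, :2]
        )
        fit = zg.fit_zig(dm, W, y)
        assert len(fit.logistic.params) == dm.p
        assert len(fit.gamma.params) == 2

    def test_degenerate_outcomes_rejected(self):
        dm = intercept_only(4)
        with pytest.raises(ValueError, match="zeros and positive"):
            zg.ZeroInflatedGamma(np.zeros(4), dm)
        with pytest.raises(ValueError, match="zeros and positive"):
            zg.ZeroInflatedGamma(np.full(4, 10.0), dm)

    def test_from_dataframe_complete_cases(self, small_table):
        df = pd.concat([small_table] * 10, ignore_index=True)
        model = zg.ZeroInflatedGamma.from_dataframe(df)
        fit_y = model.y
        assert len(fit_y) == 30  # one of four rows is incomplete


class TestPrediction:
    def test_monotone_in_each_factor(self, six_point_fit, simulated_cohort):
        fit, _, _ = six_point_fit
        base = fit.predict_mean_time([1.0], [1.0])
        assert base == pytest.approx(100.0, rel=1e-6)
        # monotone in mu at fixed p (same x profile, scaled w)
        assert zg.predict_mean_time(fit, [1.0], [237.0 / fit.gamma.params[0]]) > base
        # monotone in p at fixed mu (profiles differing only in the x row)
        df, dm = simulated_cohort
        cfit = zg.ZeroInflatedGamma(df["weekly_minutes"].to_numpy(), dm).fit()
        female = np.array([1.0, 0.0, 0, 0, 0, 5.2, 6.5])
        male = np.array([1.0, 1.0, 0, 0, 0, 5.2, 6.5])
        w = np.array([1.0, 0.0, 0, 0, 0, 5.2, 6.5])
        p_f = cfit.logistic.predict_proba(female[None, :])[0]
        p_m = cfit.logistic.predict_proba(male[None, :])[0]
        pred_f = cfit.predict_mean_time(female, w)
        pred_m = cfit.predict_mean_time(male, w)
        assert (pred_m > pred_f) == (p_m > p_f)

    def test_infeasible_profile_rejected(self, six_point_fit):
        fit, _, _ = six_point_fit
        with pytest.raises(ValueError, match="non-positive"):
            fit.predict_mean_time([1.0], [-1.0])


class TestComparisonReport:
    def test_aligned_terms_and_no_information_criteria(self, simulated_cohort):
        df, dm = simulated_cohort
        y = df["weekly_minutes"].to_numpy()
        zfit = zg.ZeroInflatedGamma(y, dm).fit()
        mfit = zg.fit_multinomial(dm, zg.categorize_minutes(y))
        report = zg.compare_models(zfit, mfit)
        assert list(report.odds_ratio_table["term"]) == list(dm.columns)
        assert {"multinomial_lt150", "multinomial_ge150", "zig_logistic"} <= set(
            report.odds_ratio_table.columns
        )
        text = report.to_text().lower()
        assert "aic" not in text.replace("aic/bic are not reported", "")
        assert "aic/bic are not reported" in text
        assert "same response variable" in text

    def test_row_set_mismatch_rejected(self, simulated_cohort):
        df, dm = simulated_cohort
        y = df["weekly_minutes"].to_numpy()
        zfit = zg.ZeroInflatedGamma(y, dm).fit()
        sub = zg.DesignMatrix(columns=dm.columns, values=dm.values[:-10])
        mfit = zg.fit_multinomial(sub, zg.categorize_minutes(y[:-10]))
        with pytest.raises(ValueError, match="different row sets"):
            zg.compare_models(zfit, mfit)
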