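import numpy as np
import pandas as pd
import pytest

from coldwater import (
    DailyTemperatureSeries,
    GeneratorConfig,
    LinearModelSpec,
    LogisticModelSpec,
    Scenario,
    classify_observed,
    classify_predicted,
    confusion_summary,
    estimate_beta,
    fit_beta_model,
    fit_logistic,
    project_future,
)
from coldwater.synthetic_data import generate_daily_series, generate_network

# published slope-model coefficients for the air-water coupling slope
BETA_COEFS = {
    "BFI": -0.0051, "WSAREA": 0.0006, "LITHSIL": -0.0011,
    "TWI": 0.0721, "LITHCAR": -0.0024,
}


def make_series(mdat, mdst, site_id=0):
    dates = pd.date_range("2012-06-01", periods=len(mdat), freq="D")
    return DailyTemperatureSeries(site_id, dates, np.asarray(mdat, float),
                                  np.asarray(mdst, float))


class TestEstimateBeta:
    def test_exact_linear_relation(self):
        mdat = np.linspace(15, 35, 20)
        assert estimate_beta(make_series(mdat, 0.5 * mdat + 3)) == pytest.approx(0.5)

    def test_constant_stream_temperature_gives_zero(self):
        mdat = np.linspace(15, 35, 20)
        assert estimate_beta(make_series(mdat, np.full(20, 12.0))) == pytest.approx(0.0)

    def test_matches_covariance_over_variance(self, rng):
        mdat = rng.normal(25, 4, 10)
        mdst = rng.normal(18, 3, 10)
        expected = np.cov(mdat, mdst, ddof=1)[0, 1] / np.var(mdat, ddof=1)
        assert estimate_beta(make_series(mdat, mdst)) == pytest.approx(
            expected, abs=1e-10
        )

    def test_constant_air_temperature_rejected(self):
        with pytest.raises(ValueError, match="distinct MDAT"):
            estimate_beta(make_series(np.full(10, 20.0), np.arange(10.0)))


class TestClassifyObserved:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.275, "high"), (0.274999, "low"), (0.96, "high"), (0.02, "low")],
    )
    def test_boundary_inclusive_threshold(self, beta, expected):
        assert classify_observed(beta) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_observed(float("nan"))


class TestFitLogistic:
    def test_symmetric_balanced_data_zero_intercept(self):
        # P(1 | x=1) = 0.75 and P(1 | x=-1) = 0.25: mirror-symmetric
        # classes, so the ML intercept is exactly zero
        X = pd.DataFrame({"x": [1.0] * 40 + [-1.0] * 40})
        y = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30)
        model = fit_logistic(y, X, ["x"])
        assert model.intercept == pytest.approx(0.0, abs=1e-6)

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=200)})
        y = (X["x"] + rng.normal(size=200) > 0).astype(int)
        model = fit_logistic(y.to_numpy(), X, ["x"])
        p = model.predict_p(X)
        assert np.all(p > 0) and np.all(p < 1)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.ones(10), X, ["x"])

    def test_complete_separation_flagged(self):
        X = pd.DataFrame({"x": np.concatenate([np.arange(20.0), 30 + np.arange(20.0)])})
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.warns(UserWarning, match="separation"):
            model = fit_logistic(y, X, ["x"])
        assert model.separation_flag

    def test_orientation_flag_flips_probability(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=300)})
        y_high = (X["x"] + rng.normal(scale=0.5, size=300) > 0).astype(int).to_numpy()
        m_high = fit_logistic(y_high, X, ["x"], orientation="high")
        m_low = fit_logistic(1 - y_high, X, ["x"], orientation="low")
        np.testing.assert_allclose(
            m_high.predict_p(X), m_low.predict_p(X), atol=1e-5
        )


class TestClassifyPredicted:
    def test_zero_linear_predictor_is_high(self):
        model = LogisticModelSpec(intercept=0.0, coefficients={"x": 0.0})
        out = classify_predicted(model, pd.DataFrame({"x": [5.0]}))
        assert out["p_high"].iloc[0] == pytest.approx(0.5)
        assert out["sensitivity_class"].iloc[0] == "high"

    def test_large_negative_predictor_is_low(self):
        model = LogisticModelSpec(intercept=-30.0, coefficients={"x": 0.0})
        out = classify_predicted(model, pd.DataFrame({"x": [0.0]}))
        assert out["sensitivity_class"].iloc[0] == "low"

    def test_confusion_matches_counting_oracle(self, rng):
        model = LogisticModelSpec(intercept=0.3, coefficients={"x": 1.2})
        X = pd.DataFrame({"x": rng.normal(size=150)})
        true = np.where(rng.random(150) < 0.6, "high", "low")
        pred = classify_predicted(model, X)["sensitivity_class"].to_numpy()
        summary = confusion_summary(true, pred)
        # brute-force counting
        for cls in ("high", "low"):
            mask = true == cls
            expected = 100.0 * np.sum(pred[mask] == cls) / mask.sum()
            assert summary.per_class_pct[cls] == pytest.approx(expected)
        assert summary.overall_pct == pytest.approx(100.0 * np.mean(true == pred))

    def test_missing_term_rejected(self):
        model = LogisticModelSpec(intercept=0.0, coefficients={"WSAREA": 1.0})
        with pytest.raises(KeyError, match="WSAREA"):
            classify_predicted(model, pd.DataFrame({"BFI": [1.0]}))


class TestConfusionSummary:
    def test_published_classification_rates(self):
        """157/160 high and 10/31 low correct give 98.1%, 32.3%, and an
        overall rate of 87.4%."""
        true = np.array(["high"] * 160 + ["low"] * 31)
        pred = np.array(
            ["high"] * 157 + ["low"] * 3 + ["low"] * 10 + ["high"] * 21
        )
        s = confusion_summary(true, pred)
        assert round(s.per_class_pct["high"], 1) == 98.1
        assert round(s.per_class_pct["low"], 1) == 32.3
        assert round(s.overall_pct, 1) == 87.4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_summary([1, 0], [1])


class TestBetaModel:
    def test_published_twi_contrast(self):
        """A +1 difference in topographic wetness index shifts the
        predicted coupling slope by the published 0.0721."""
        model = LinearModelSpec(intercept=0.0, coefficients=dict(BETA_COEFS))
        base = {t: 10.0 for t in BETA_COEFS}
        bumped = dict(base, TWI=11.0)
        assert model.predict(bumped) - model.predict(base) == pytest.approx(0.0721)

    def test_low_sensitivity_site_rejected(self, rng):
        X = pd.DataFrame({"TWI": rng.normal(8, 2, 20)})
        beta = np.full(20, 0.5)
        beta[3] = 0.1
        with pytest.raises(ValueError, match="low-sensitivity"):
            fit_beta_model(beta, X, ["TWI"])

    def test_noiseless_construction_r2_one(self, rng):
        X = pd.DataFrame({"TWI": rng.normal(8, 2, 30), "BFI": rng.normal(55, 10, 30)})
        beta = 0.4 + 0.01 * X["TWI"].to_numpy() - 0.001 * X["BFI"].to_numpy()
        assert beta.min() >= 0.275
        spec = fit_beta_model(beta, X, ["TWI", "BFI"])
        assert spec.r2 == pytest.approx(1.0)
        assert spec.coefficients["TWI"] == pytest.approx(0.01, abs=1e-10)


class TestProjection:
    def test_mean_network_slope_gives_published_increase(self):
        """beta = 0.42 with a +4 C air scenario warms streams by 1.68 C,
        the ~1.7 C network mean response."""
        future = project_future([20.0], ["high"], [0.42], Scenario(4.0))
        assert future[0] - 20.0 == pytest.approx(1.68)

    def test_low_sensitivity_reach_does_not_warm(self):
        future = project_future([18.0], ["low"], [np.nan], Scenario(4.0))
        assert future[0] == 18.0

    def test_linear_in_delta(self, rng):
        n = 500
        now = rng.uniform(14, 24, n)
        beta = rng.uniform(0, 0.96, n)
        cls = np.where(rng.random(n) < 0.7, "high", "low")
        inc2 = project_future(now, cls, beta, Scenario(2.0)) - now
        inc4 = project_future(now, cls, beta, Scenario(4.0)) - now
        np.testing.assert_allclose(inc4, 2 * inc2)

    def test_monotone_under_warming(self, rng):
        n = 200
        now = rng.uniform(14, 24, n)
        beta = rng.normal(0.4, 0.2, n)  # may include negatives -> clipped
        cls = np.where(rng.random(n) < 0.8, "high", "low")
        future = project_future(now, cls, beta, Scenario(3.0))
        assert np.all(future >= now)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            Scenario(-1.0)

    def test_high_reach_without_beta_rejected(self):
        with pytest.raises(ValueError, match="without predicted beta"):
            project_future([20.0], ["high"], [np.nan], Scenario(2.0))


class TestEndToEndBetaRecovery:
    def test_recovery_error_shrinks_with_noise(self):
        """Mean absolute error of slope estimates against the generator's
        true slopes shrinks as stream-temperature noise goes to zero."""
        maes = []
        for noise in (2.0, 0.5, 0.0):
            cfg = GeneratorConfig(
                seed=21, n_headwaters=40, n_sites=30,
                noise_sd_stream_temp_C=noise,
            )
            net = generate_network(cfg)
            series, truth = generate_daily_series(net, cfg)
            est = np.array([estimate_beta(s) for s in series])
            maes.append(np.mean(np.abs(est - truth["beta_true"].to_numpy())))
        assert maes[0] > maes[1] > maes[2]
        assert maes[2] == pytest.approx(0.0, abs=1e-10)
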