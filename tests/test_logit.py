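"""Binary logit MLE, Wald/odds-ratio table, risk prediction and curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from walkrisk.logit import (
    CALIBRATED_COEFFICIENTS,
    COEF_NAMES,
    LogitFit,
    SeparationError,
    classify_states,
    fit_logit,
    predict_risk,
    risk_curves,
    simulate_from_model,
    wald_and_or,
)


def grid_search_loglik(X, y, lo=-5.0, hi=5.0):
    """Independent oracle: iteratively refined dense grid search over coefficients."""
    Xd = np.column_stack([np.ones(len(y)), X])
    p = Xd.shape[1]

    def ll(beta):
        eta = Xd @ beta
        return np.sum(y * eta - np.logaddexp(0.0, eta))

    centre = np.zeros(p)
    half = (hi - lo) / 2.0
    step = half / 5.0
    while step > 1e-3 / 2:
        axes = [centre[j] + np.arange(-5, 6) * step for j in range(p)]
        grids = np.meshgrid(*axes, indexing="ij")
        cand = np.stack([g.ravel() for g in grids], axis=1)
        lls = np.array([ll(b) for b in cand])
        centre = cand[np.argmax(lls)]
        step /= 2.0
    return ll(centre)


class TestFitLogit:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        y = (rng.random(500) < 0.3).astype(float)
        fit = fit_logit(np.empty((500, 0)), y, names=("intercept",))
        ybar = y.mean()
        assert fit.beta[0] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-8)
        assert fit.converged

    def test_two_by_two_table_log_odds_ratio(self):
        a, b, c, d = 30, 10, 15, 45  # (x=1,y=1), (x=1,y=0), (x=0,y=1), (x=0,y=0)
        x = np.concatenate([np.ones(a + b), np.zeros(c + d)])[:, None]
        y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        fit = fit_logit(x, y, names=("intercept", "x"))
        assert fit.beta[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)
        assert fit.beta[0] == pytest.approx(np.log(c / d), abs=1e-6)

    def test_score_equation_holds(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = int(rng.integers(50, 400))
            X, y = simulate_from_model(CALIBRATED_COEFFICIENTS, n, rng)
            fit = fit_logit(X, y)
            p = special.expit(fit.beta[0] + X @ fit.beta[1:])
            assert p.sum() == pytest.approx(y.sum(), abs=1e-6)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        X, y = simulate_from_model(CALIBRATED_COEFFICIENTS, 800, rng)
        fit = fit_logit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-5)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        for p_cov in (1, 2):
            X = rng.normal(0, 1, size=(40, p_cov))
            eta = 0.4 + X @ np.linspace(0.8, -0.6, p_cov)
            y = (rng.random(40) < special.expit(eta)).astype(float)
            fit = fit_logit(X, y, names=["intercept"] + [f"x{j}" for j in range(p_cov)])
            assert abs(fit.loglik - grid_search_loglik(X, y)) < 1e-4
            assert fit.loglik >= grid_search_loglik(X, y) - 1e-9

    def test_separation_raises_naming_covariate(self):
        # perfectly separated covariate: the coefficient diverges while the
        # likelihood keeps improving, tripping the escape bound
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])[:, None]
        y = (x.ravel() > 0).astype(float)
        with pytest.raises(SeparationError, match="x1"):
            fit_logit(x, y, names=("intercept", "x1"), separation_bound=5.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_logit(np.random.default_rng(0).normal(size=(20, 1)), np.ones(20))

    def test_constant_covariate_rejected(self):
        y = np.tile([0.0, 1.0], 10)
        X = np.column_stack([np.ones(20), np.random.default_rng(0).normal(size=20)])
        with pytest.raises(ValueError, match="constant"):
            fit_logit(X, y, names=("intercept", "c", "x"))


class TestWaldAndOddsRatios:
    def _fit(self, beta, se=None):
        beta = np.asarray(beta, dtype=float)
        se = np.ones_like(beta) if se is None else np.asarray(se, dtype=float)
        return LogitFit(beta=beta, se=se, loglik=0.0, converged=True, iterations=1,
                        n=10, names=COEF_NAMES[: len(beta)])

    def test_calibrated_odds_ratios_to_3dp(self):
        table = wald_and_or(self._fit(CALIBRATED_COEFFICIENTS)).set_index("variable")
        assert round(table.loc["pm25", "odds_ratio"], 3) == 1.058
        assert round(table.loc["male", "odds_ratio"], 3) == 0.768
        assert round(table.loc["youth", "odds_ratio"], 3) == 0.675
        assert round(table.loc["bmi_healthy", "odds_ratio"], 3) == 0.721
        assert round(table.loc["hr_percent", "odds_ratio"], 3) == 1.114

    def test_both_wald_conventions(self):
        table = wald_and_or(self._fit([0.5, -1.0], se=[0.25, 0.5]))
        np.testing.assert_allclose(table["wald_z"], [2.0, -2.0])
        np.testing.assert_allclose(table["wald_chisq"], [4.0, 4.0])
        assert (table["df"] == 1).all()

    def test_zero_coefficient(self):
        row = wald_and_or(self._fit([0.0])).iloc[0]
        assert row["wald_chisq"] == 0.0
        assert row["p_value"] == pytest.approx(1.0)
        assert row["odds_ratio"] == 1.0

    def test_requires_convergence(self):
        fit = self._fit([0.1])
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            wald_and_or(fit)


class TestPredictRisk:
    def test_all_zero_covariates(self):
        p = predict_risk(CALIBRATED_COEFFICIENTS, np.zeros(5))
        assert p == pytest.approx(special.expit(-6.323), abs=1e-12)
        assert p == pytest.approx(0.001787, abs=5e-6)

    def test_logistic_symmetry(self):
        # choose γ so the linear predictor vanishes
        coef = np.array([-1.0, 0.5, 0, 0, 0, 0])
        assert predict_risk(coef, [2.0, 0, 0, 0, 0]) == pytest.approx(0.5)

    def test_worked_example(self):
        gamma = np.array([150.0, 1.0, 1.0, 1.0, 35.0])
        eta = -6.323 + 0.056 * 150 - 0.264 - 0.393 - 0.327 + 0.108 * 35
        assert eta == pytest.approx(4.873)
        assert predict_risk(CALIBRATED_COEFFICIENTS, gamma) == pytest.approx(
            special.expit(4.873), abs=1e-12
        )
        assert predict_risk(CALIBRATED_COEFFICIENTS, gamma) == pytest.approx(0.99239, abs=1e-4)

    def test_evaluation_paths_agree(self):
        rng = np.random.default_rng(4)
        g = np.column_stack([
            rng.uniform(0, 300, 200),
            rng.integers(0, 2, 200),
            rng.integers(0, 2, 200),
            rng.integers(0, 2, 200),
            rng.uniform(0, 50, 200),
        ])
        a = predict_risk(CALIBRATED_COEFFICIENTS, g, method="logistic")
        b = predict_risk(CALIBRATED_COEFFICIENTS, g, method="odds")
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_monotone_in_pm25_and_hr(self):
        lo = predict_risk(CALIBRATED_COEFFICIENTS, [100.0, 0, 0, 0, 30.0])
        hi_pm = predict_risk(CALIBRATED_COEFFICIENTS, [150.0, 0, 0, 0, 30.0])
        hi_hr = predict_risk(CALIBRATED_COEFFICIENTS, [100.0, 0, 0, 0, 40.0])
        assert hi_pm > lo and hi_hr > lo

    def test_input_validation(self):
        with pytest.raises(ValueError):
            predict_risk(CALIBRATED_COEFFICIENTS[:4], np.zeros(5))
        with pytest.raises(ValueError):
            predict_risk(CALIBRATED_COEFFICIENTS, np.zeros(4))


class TestRiskCurves:
    def test_group_ordering_everywhere(self):
        curves = risk_curves()
        wide = curves.pivot(index="pm25_ugm3", columns="group", values="probability")
        assert (wide["female_middle_aged"] > wide["male_middle_aged"]).all()
        assert (wide["male_middle_aged"] > wide["female_youth"]).all()
        assert (wide["female_youth"] > wide["male_youth"]).all()

    def test_zero_pm_slope_gives_flat_curves(self):
        coef = CALIBRATED_COEFFICIENTS.copy()
        coef[1] = 0.0
        curves = risk_curves(coef)
        assert curves.groupby("group")["probability"].nunique().eq(1).all()

    def test_consistent_with_predict_risk_at_zero(self):
        curves = risk_curves(hr_percent=35.0, bmi_healthy=True)
        row = curves[(curves["group"] == "male_youth") & (curves["pm25_ugm3"] == 0.0)]
        expected = predict_risk(CALIBRATED_COEFFICIENTS, [0.0, 1, 1, 1, 35.0])
        assert row["probability"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing_when_beta1_positive(self):
        curves = risk_curves()
        for _, sub in curves.groupby("group"):
            assert (np.diff(sub["probability"]) > 0).all()

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            risk_curves(pm_grid=np.array([]))
        with pytest.raises(ValueError):
            risk_curves(pm_grid=np.array([10.0, 5.0]))


class TestClassifyStates:
    def _frames(self):
        intervals = pd.DataFrame(
            {
                "volunteer_id": ["A", "A", "A", "B", "B", "B"],
                "hr_percent": [0.10, 0.30, 0.50, 0.20, 0.35, 0.40],
                "mean_pm25": [50.0] * 6,
            }
        )
        thresholds = pd.DataFrame(
            {"volunteer_id": ["A", "B"], "hr_threshold": [0.30, 0.40]}
        )
        return intervals, thresholds

    def test_hand_enumeration(self):
        intervals, thresholds = self._frames()
        out = classify_states(intervals, thresholds)
        # A: 0.10<0.30→0, 0.30>=0.30→1 (boundary is risk), 0.50→1; B: only 0.40→1
        assert out["y"].tolist() == [0, 1, 1, 0, 0, 1]

    def test_all_below_thresholds(self):
        intervals, thresholds = self._frames()
        thresholds["hr_threshold"] = 0.9
        assert classify_states(intervals, thresholds)["y"].eq(0).all()

    def test_missing_threshold_drops_records(self):
        intervals, thresholds = self._frames()
        out = classify_states(intervals, thresholds.iloc[:1])
        assert set(out["volunteer_id"]) == {"A"}


def test_simulate_from_model_is_deterministic():
    X1, y1 = simulate_from_model(CALIBRATED_COEFFICIENTS, 100, np.random.default_rng(9))
    X2, y2 = simulate_from_model(CALIBRATED_COEFFICIENTS, 100, np.random.default_rng(9))
    np.testing.assert_array_equal(X1, X2)
    np.testing.assert_array_equal(y1, y2)
    assert X1.shape == (100, 5) and set(np.unique(y1)) <= {0.0, 1.0}
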