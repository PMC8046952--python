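"""Maximum-likelihood logistic fitting, Wald inference and odds ratios."""

import math

import numpy as np
import pandas as pd
import pytest

from wbconform.logit import (
    MODEL_SPECS,
    BinaryLogit,
    ModelSpec,
    SeparationWarning,
    odds_ratio,
)

statsmodels_api = pytest.importorskip("statsmodels.api")


def make_logistic_data(rng, n, beta):
    """Simulate from a known logistic model; beta[0] is the intercept."""
    k = len(beta) - 1
    X = rng.normal(size=(n, k))
    eta = beta[0] + X @ beta[1:]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return y, np.column_stack([np.ones(n)] + [X[:, j] for j in range(k)])


class TestClosedForms:
    def test_intercept_only_is_marginal_log_odds(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        res = BinaryLogit(y, np.ones((100, 1)), ["const"]).fit()
        assert res.params["const"] == pytest.approx(math.log(30 / 70), abs=1e-6)

    def test_two_by_two_log_odds_ratio(self):
        # x=1: 20 yes / 10 no; x=0: 5 yes / 35 no -> beta = log(14)
        x = np.r_[np.ones(30), np.zeros(40)]
        y = np.r_[np.ones(20), np.zeros(10), np.ones(5), np.zeros(35)]
        res = BinaryLogit(y, np.column_stack([np.ones(70), x])).fit()
        assert res.params.iloc[1] == pytest.approx(math.log(14.0), abs=1e-6)
        assert res.params.iloc[0] == pytest.approx(math.log(5 / 35), abs=1e-6)


class TestFitQuality:
    def test_parameter_recovery_within_three_ses(self):
        rng = np.random.default_rng(42)
        truth = np.array([-1.0, 0.8, -0.5])
        y, X = make_logistic_data(rng, 5000, truth)
        res = BinaryLogit(y, X).fit()
        err = np.abs(res.params.to_numpy() - truth)
        assert (err < 3.0 * res.bse.to_numpy()).all()

    def test_agrees_with_reference_optimizer(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 20:
            n = int(rng.integers(40, 120))
            k = int(rng.integers(1, 4))
            beta = rng.normal(scale=0.8, size=k + 1)
            y, X = make_logistic_data(rng, n, beta)
            if y.sum() in (0, len(y)):
                continue
            ours = BinaryLogit(y, X).fit()
            if not ours.converged:  # rare separated draw: no ML optimum
                continue
            ref = statsmodels_api.Logit(y, X).fit(disp=0)
            np.testing.assert_allclose(
                ours.params.to_numpy(), ref.params, atol=1e-6
            )
            np.testing.assert_allclose(ours.bse.to_numpy(), ref.bse, atol=1e-5)
            checked += 1

    def test_gradient_vanishes_at_optimum(self):
        rng = np.random.default_rng(5)
        y, X = make_logistic_data(rng, 400, np.array([-0.5, 1.0, 0.3]))
        model = BinaryLogit(y, X)
        res = model.fit()
        assert np.abs(model.score(res.params.to_numpy())).max() < 1e-6

    def test_location_invariance_of_slopes(self):
        rng = np.random.default_rng(9)
        y, X = make_logistic_data(rng, 300, np.array([-0.8, 1.2]))
        res0 = BinaryLogit(y, X).fit()
        Xs = X.copy()
        Xs[:, 1] += 10.0
        res1 = BinaryLogit(y, Xs).fit()
        beta = res0.params.iloc[1]
        assert res1.params.iloc[1] == pytest.approx(beta, abs=1e-8)
        assert res1.params.iloc[0] == pytest.approx(
            res0.params.iloc[0] - 10.0 * beta, abs=1e-7
        )
        np.testing.assert_allclose(
            res1.predict(Xs[:, 1:]), res0.predict(X[:, 1:]), atol=1e-8
        )


class TestPathologies:
    def test_complete_separation_flagged_not_hidden(self):
        x = np.linspace(-2, 2, 60)
        y = (x > 0).astype(float)
        with pytest.warns(SeparationWarning):
            res = BinaryLogit(y, np.column_stack([np.ones(60), x])).fit()
        assert not res.converged
        assert res.separation

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(2)
        y, X = make_logistic_data(rng, 200, np.array([0.0, 1.0]))
        X2 = np.column_stack([X, 2.0 * X[:, 1]])
        with pytest.raises(ValueError, match="collinear|singular"):
            BinaryLogit(y, X2).fit()

    def test_constant_predictor_rejected(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        X = np.column_stack([np.ones(20), np.full(20, 3.0)])
        with pytest.raises(ValueError, match="constant"):
            BinaryLogit(y, X)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            BinaryLogit(np.ones(20), np.ones((20, 1)))


class TestPrediction:
    def test_zero_linear_predictor_gives_half(self, cohort):
        spec = ModelSpec("m", ("M1",))
        res = BinaryLogit.from_dataframe(cohort, spec).fit()
        x_at_zero = -res.params["const"] / res.params["M1"]
        p = res.predict(pd.DataFrame({"M1": [x_at_zero]}))
        assert p[0] == pytest.approx(0.5, abs=1e-12)

    def test_extreme_eta_saturates_without_overflow(self, cohort):
        res = BinaryLogit.from_dataframe(cohort, MODEL_SPECS["model5"]).fit()
        with np.errstate(over="raise"):
            p = res.predict(pd.DataFrame({"M1": [1e5, -1e5], "M9": [1e5, -1e5]}))
        assert p[0] == 1.0 and p[1] == 0.0

    def test_missing_predictor_rejected(self, cohort):
        res = BinaryLogit.from_dataframe(cohort, MODEL_SPECS["model1"]).fit()
        with pytest.raises(ValueError, match="M3"):
            res.predict(pd.DataFrame({"M1": [15.0], "M2": [4.5]}))

    def test_fitted_probabilities_separate_true_classes(self, cohort):
        res = BinaryLogit.from_dataframe(cohort, MODEL_SPECS["model1"]).fit()
        p = res.predict(cohort)
        yes = cohort["wb_binary"].to_numpy() == 1
        assert p[yes].mean() > p[~yes].mean()


class TestOddsRatios:
    def test_printed_caudal_width_cell(self):
        assert round(odds_ratio(1.83).odds_ratio, 2) == 6.23

    def test_zero_beta_identity(self):
        st = odds_ratio(0.0)
        assert st.odds_ratio == 1.0
        assert st.percent_change == 0.0
        assert st.direction == "no change"

    def test_printed_percent_reduction(self):
        assert round(odds_ratio(-7.55).percent_change, 2) == 99.95
        assert "99.95% smaller" in odds_ratio(-7.55).statement

    def test_nonfinite_beta_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(float("inf"))

    def test_results_or_equals_exp_beta(self, cohort):
        res = BinaryLogit.from_dataframe(cohort, MODEL_SPECS["model1"]).fit()
        np.testing.assert_array_equal(
            res.odds_ratios.to_numpy(), np.exp(res.params.to_numpy())
        )
        assert res.llf >= res.llnull


class TestRoundTripAndSummary:
    def test_serialisation_preserves_coefficients_exactly(self, cohort, tmp_path):
        from wbconform.io import read_fit, write_fit

        res = BinaryLogit.from_dataframe(cohort, MODEL_SPECS["model4"]).fit()
        path = tmp_path / "fit.json"
        write_fit(res, path)
        back = read_fit(path)
        assert (back.params == res.params).all()
        assert back.llf == res.llf
        np.testing.assert_array_equal(
            back.cov_params.to_numpy(), res.cov_params.to_numpy()
        )

    def test_summary_lists_every_parameter(self, cohort):
        res = BinaryLogit.from_dataframe(cohort, MODEL_SPECS["model1"]).fit()
        text = res.summary()
        for name in ("const", "M1", "M2", "M3"):
            assert name in text
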