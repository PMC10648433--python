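"""Box-Cox random-intercept model: fit correctness against independent
oracles (closed-form GLS, statsmodels MixedLM), distribution estimation,
and DRI threshold fractions."""

import numpy as np
import pandas as pd
import pytest

from dietswap.core import DRIReference
from dietswap.simulate import SimulationConfig, default_dri, generate_cohort
from dietswap.cohort import apply_exclusions
from dietswap.usual_intake import (
    CovariateDesign,
    boxcox,
    boxcox_inverse,
    estimate_distribution,
    fit_amount_model,
    floor_amounts,
    persondays_frame,
    threshold_fractions,
    usual_intake_values,
    prediction_frame,
)


def _toy_frame(rng, n_persons=300, sigma_u=0.3, sigma_e=0.5, lam=0.0,
               mu=3.0, both_days=True):
    """Covariate-free two-day data from the generating model."""
    rows = []
    for i in range(n_persons):
        u = rng.normal(0, sigma_u)
        days = (1, 2) if both_days or rng.random() < 0.8 else (1,)
        for d in days:
            z = mu + u + rng.normal(0, sigma_e)
            rows.append({"person_id": f"p{i}", "day": d, "weekday": True,
                         "age_cat": 3, "gender": "male", "race": "nh_white",
                         "energy": 2000.0,
                         "amount": float(boxcox_inverse(np.array(z), lam))})
    return pd.DataFrame(rows)


class TestFit:
    def test_lambda_zero_data_recovers_parameters(self):
        rng = np.random.default_rng(10)
        df = _toy_frame(rng, n_persons=1000)
        m = fit_amount_model(df)
        assert m.lam in (0.0, 0.05)
        assert m.sigma_u2 == pytest.approx(0.09, rel=0.2)
        assert m.sigma_e2 == pytest.approx(0.25, rel=0.2)

    def test_zero_between_person_variance_detected(self):
        rng = np.random.default_rng(11)
        df = _toy_frame(rng, n_persons=500, sigma_u=0.0)
        m = fit_amount_model(df, lambda_grid=[0.0])
        assert m.sigma_u2 < 0.01 * m.sigma_e2

    def test_lambda_one_matches_closed_form_gls_on_balanced_toy(self):
        # sigma_u = 0 and lambda = 1: the fit must equal OLS on raw amounts
        rng = np.random.default_rng(12)
        n = 400
        rows = []
        for i in range(n):
            for d in (1, 2):
                energy = rng.uniform(1500, 2500)
                amount = 50 + 5 * (energy - 2000) / 1000 + rng.normal(0, 2)
                rows.append({"person_id": f"p{i}", "day": d, "weekday": d == 1,
                             "age_cat": 3, "gender": "male", "race": "nh_white",
                             "energy": energy, "amount": amount})
        df = pd.DataFrame(rows)
        m = fit_amount_model(df, lambda_grid=[1.0])
        X = CovariateDesign().matrix(df.sort_values(["person_id", "day"]))
        z = boxcox(df.sort_values(["person_id", "day"])["amount"].to_numpy(), 1.0)
        beta_ols, *_ = np.linalg.lstsq(X, z, rcond=None)
        np.testing.assert_allclose(m.beta, beta_ols, atol=0.15)

    def test_matches_statsmodels_mixedlm_at_fixed_lambda(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        df = _toy_frame(rng, n_persons=400, both_days=False).sort_values(
            ["person_id", "day"]).reset_index(drop=True)
        m = fit_amount_model(df, lambda_grid=[0.0])
        X = pd.DataFrame({
            "intercept": 1.0,
            "seq": (df["day"] == 2).astype(float),
        })
        sm_fit = sm.MixedLM(np.log(df["amount"]), X, groups=df["person_id"]).fit(
            reml=False)
        assert m.sigma_u2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), abs=2e-3)
        assert m.sigma_e2 == pytest.approx(float(sm_fit.scale), abs=2e-3)
        # coefficients are only identified through predictions on this
        # constant-covariate toy; compare fitted values for both day levels
        Xm = CovariateDesign().matrix(df)
        lp = Xm @ m.beta
        day1 = lp[(df["day"] == 1).to_numpy()][0]
        day2 = lp[(df["day"] == 2).to_numpy()][0]
        assert day1 == pytest.approx(sm_fit.params["intercept"], abs=5e-3)
        assert day2 - day1 == pytest.approx(sm_fit.params["seq"], abs=5e-3)

    def test_single_day_only_data_rejected(self):
        rng = np.random.default_rng(14)
        df = _toy_frame(rng, n_persons=50)
        df = df[df["day"] == 1]
        with pytest.raises(ValueError, match="single day"):
            fit_amount_model(df)

    def test_nonpositive_amounts_rejected_and_floorable(self):
        rng = np.random.default_rng(15)
        df = _toy_frame(rng, n_persons=50)
        df.loc[0, "amount"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_amount_model(df)
        floored = floor_amounts(df)
        assert floored["amount"].min() > 0
        fit_amount_model(floored)  # now fits


class TestDistribution:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(20)
        df = _toy_frame(rng, n_persons=800, sigma_u=0.3, sigma_e=0.5, mu=3.0)
        model = fit_amount_model(df, lambda_grid=[0.0])
        return df, model

    def test_lognormal_closed_form_mean(self, fitted):
        df, model = fitted
        pred = df[df["day"] == 1].reset_index(drop=True)
        T = usual_intake_values(model, pred, n_pseudo=200, seed=1)
        # quadrature + MC correctness: E[T] = exp(mu + sigma_e^2/2 + sigma_u^2/2)
        # evaluated at the fitted parameters (covariate-free fixture)
        lp = CovariateDesign().matrix(pred) @ model.beta
        fitted_form = np.mean(np.exp(lp + model.sigma_e2 / 2 + model.sigma_u2 / 2))
        assert T.mean() == pytest.approx(fitted_form, rel=0.01)
        # and against the generating parameters, within fixture sampling noise
        true_form = np.exp(3.0 + 0.25 / 2 + 0.09 / 2)
        assert T.mean() == pytest.approx(true_form, rel=0.08)

    def test_usual_intake_less_variable_than_single_day(self, fitted):
        df, model = fitted
        pred = df[df["day"] == 1].reset_index(drop=True)
        T = usual_intake_values(model, pred, n_pseudo=100, seed=2)
        assert np.var(T) < np.var(df["amount"].to_numpy())

    def test_degenerate_variances_collapse_to_point(self):
        rng = np.random.default_rng(21)
        df = _toy_frame(rng, n_persons=100, sigma_u=0.0, sigma_e=0.3)
        model = fit_amount_model(df, lambda_grid=[0.0])
        model.sigma_u2 = 0.0
        model.sigma_e2 = 0.0
        pred = df[df["day"] == 1].reset_index(drop=True)
        T = usual_intake_values(model, pred, n_pseudo=10, seed=3)
        lp = CovariateDesign().matrix(pred) @ model.beta
        np.testing.assert_allclose(T, np.tile(np.exp(lp)[:, None], (1, 10)),
                                   rtol=1e-10)

    def test_percentiles_nondecreasing_and_seed_stable(self, included_cohort):
        included, _, design = included_cohort
        df = persondays_frame(included, "magnesium")
        model = fit_amount_model(df)
        d1 = estimate_distribution(model, included, design, "magnesium",
                                   n_pseudo=100, seed=1)
        d2 = estimate_distribution(model, included, design, "magnesium",
                                   n_pseudo=100, seed=2)
        assert np.all(np.diff(d1.percentiles) >= 0)
        np.testing.assert_allclose(d1.percentiles, d2.percentiles, rtol=0.05)
        assert d1.mean.lower <= d1.mean.point <= d1.mean.upper


class TestThresholdFractions:
    @pytest.fixture(scope="class")
    def dist(self, included_cohort):
        included, _, design = included_cohort
        df = persondays_frame(included, "magnesium")
        model = fit_amount_model(df)
        return included, design, estimate_distribution(
            model, included, design, "magnesium", n_pseudo=100, seed=1)

    def test_ear_below_first_percentile_gives_near_zero(self, dist):
        included, design, d = dist
        tiny = DRIReference(pd.DataFrame([{
            "nutrient": "magnesium", "gender": "any", "age_min": 0,
            "age_max": 200, "kind": "EAR", "value": 1e-6}]))
        fr = threshold_fractions(d, tiny, "magnesium", included)
        assert fr["fraction_below"].point == pytest.approx(0.0, abs=1e-6)

    def test_fraction_at_estimated_median_is_half(self, dist):
        included, design, d = dist
        med = float(d.percentiles[49])
        at_median = DRIReference(pd.DataFrame([{
            "nutrient": "magnesium", "gender": "any", "age_min": 0,
            "age_max": 200, "kind": "EAR", "value": med}]))
        fr = threshold_fractions(d, at_median, "magnesium", included)
        assert fr["fraction_below"].point == pytest.approx(0.5, abs=0.02)

    def test_below_and_at_or_above_are_complementary(self, dist):
        included, design, d = dist
        dri = default_dri()
        fr_below = threshold_fractions(d, dri, "magnesium", included)
        # complement computed directly from the same pseudo-persons
        thr = {p.person_id: dri.lookup("magnesium", p.gender, p.age_years)[0]
               for p in included}
        t = np.array([thr[pid] for pid in d.person_ids])
        below = (d.usual_intakes < t[:, None]).mean(axis=1)
        w = d.design.base_weights
        total = float(np.sum(w * below) / np.sum(w)) \
            + float(np.sum(w * (1 - below)) / np.sum(w))
        assert total == pytest.approx(1.0)
        assert 0.0 <= fr_below["fraction_below"].point <= 1.0
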