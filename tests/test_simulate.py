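"""Generator contracts: determinism, missingness rate, variance moments,
truth-record consistency, and price construction."""

import numpy as np
import pytest

from dietswap.cost import inflation_adjust
from dietswap.simulate import (
    SEQ_DAY2_EFFECT,
    WEEKDAY_EFFECT,
    SimulationConfig,
    generate_cohort,
    generate_design,
    generate_prices,
)


class TestDeterminism:
    def test_same_seed_identical_cohorts(self):
        a, da, ta = generate_cohort(SimulationConfig(seed=42, n_persons=60))
        b, db, tb = generate_cohort(SimulationConfig(seed=42, n_persons=60))
        for p, q in zip(a, b):
            assert p.person_id == q.person_id and p.age_years == q.age_years
            for dp, dq in zip(p.days, q.days):
                np.testing.assert_array_equal(dp.nutrients.as_array(),
                                              dq.nutrients.as_array())
        np.testing.assert_array_equal(da.replicate_weights, db.replicate_weights)
        assert ta.pop_mean == tb.pop_mean

    def test_different_seed_differs(self):
        a, _, _ = generate_cohort(SimulationConfig(seed=1, n_persons=40))
        b, _, _ = generate_cohort(SimulationConfig(seed=2, n_persons=40))
        assert any(p.days[0].nutrients.fiber != q.days[0].nutrients.fiber
                   for p, q in zip(a, b))

    def test_amounts_independent_of_food_partitioning(self):
        # separate streams: turning food records off must not move amounts
        full, _, _ = generate_cohort(SimulationConfig(seed=3, n_persons=50))
        light, _, _ = generate_cohort(SimulationConfig(
            seed=3, n_persons=50, include_foods=False,
            truth_nutrients=("fiber",)))
        for p, q in zip(full, light):
            np.testing.assert_array_equal(p.days[0].nutrients.as_array(),
                                          q.days[0].nutrients.as_array())


class TestStructure:
    def test_day2_completion_near_target(self, sim_bundle):
        config, persons, _, _ = sim_bundle
        frac = np.mean([p.n_days == 2 for p in persons])
        p = config.day2_completion_prob
        bound = 3 * np.sqrt(p * (1 - p) / len(persons))
        assert abs(frac - p) < bound

    def test_transformed_moments_match_generating_variances(self):
        # residuals against the known fixed effects isolate sigma_u / sigma_e
        cfg = SimulationConfig(seed=9, n_persons=2000, include_foods=False,
                               truth_nutrients=("vitamin_b12",))
        persons, _, truth = generate_cohort(cfg)
        p = cfg.nutrient_params["vitamin_b12"]
        two_day = [q for q in persons if q.n_days == 2]
        z = np.array([[np.log(d.nutrients.vitamin_b12) for d in q.days]
                      for q in two_day])
        # strip the known day-level effects so only u and e remain
        for j, q in enumerate(two_day):
            for k, d in enumerate(q.days):
                z[j, k] -= (SEQ_DAY2_EFFECT * (d.day == 2)
                            + WEEKDAY_EFFECT * d.weekday_indicator
                            + p.gamma_energy_log * (d.nutrients.energy - 2000) / 1000)
        within = 0.5 * np.var(z[:, 0] - z[:, 1])
        between = np.var(z.mean(axis=1)) - within / 2
        # between-person variance still contains demographic fixed effects;
        # subtract their empirical variance via the known age/gender/race lp
        from dietswap.simulate import AGE_EFFECTS, MALE_EFFECT, RACE_EFFECTS
        from dietswap.usual_intake import age_category
        lp = np.array([AGE_EFFECTS[age_category(min(max(q.age_years, 4), 85))]
                       + (MALE_EFFECT if q.gender == "male" else 0.0)
                       + RACE_EFFECTS[q.race] for q in two_day])
        between -= np.var(lp)
        assert within == pytest.approx(p.sigma_e ** 2, rel=0.15)
        assert between == pytest.approx(p.sigma_u ** 2, rel=0.15)

    def test_truth_mean_matches_observed_day_mean_analytically(self):
        # lognormal identity: E[observed day amount] = E[usual intake]
        cfg = SimulationConfig(seed=5, n_persons=2000, include_foods=False,
                               truth_nutrients=("vitamin_b12",))
        persons, design, truth = generate_cohort(cfg)
        w = design.base_weights
        obs = np.array([p.day_record(1).nutrients.vitamin_b12 for p in persons])
        observed_mean = float(np.sum(w * obs) / np.sum(w))
        assert truth.pop_mean["vitamin_b12"] == pytest.approx(observed_mean, rel=0.05)

    def test_truth_fractions_in_unit_interval(self, sim_bundle):
        _, _, _, truth = sim_bundle
        for k, v in truth.frac_below_ear.items():
            assert 0.0 <= v <= 1.0
            assert truth.frac_above_ai[k] == pytest.approx(1.0 - v)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(day2_completion_prob=1.5)
        from dietswap.simulate import NutrientParams
        with pytest.raises(ValueError):
            SimulationConfig(nutrient_params={"fiber": NutrientParams(1.5, 15.0)})


class TestDesign:
    def test_replicate_weights_shape_and_positivity(self, sim_bundle):
        _, _, design, _ = sim_bundle
        assert design.replicate_weights.shape == (len(design.person_ids), 16)
        assert (design.base_weights > 0).all()
        assert (design.replicate_weights >= 0).all()

    def test_standalone_design_reproducible(self):
        ids = [f"x{i}" for i in range(100)]
        d1 = generate_design(ids, 7)
        d2 = generate_design(ids, 7)
        np.testing.assert_array_equal(d1.replicate_weights, d2.replicate_weights)


class TestPrices:
    def test_configured_per_oz_prices_stored_exactly(self):
        cfg = SimulationConfig(seed=1)
        prices, _ = generate_prices(cfg)
        assert prices.meat_price_per_oz == 0.38
        assert prices.walnut_price_per_oz == 0.26
        meat_rows = prices.table[prices.table["category"] == "meat"]
        np.testing.assert_allclose(meat_rows["price_per_100g"],
                                   0.38 / 28.35 * 100.0)

    def test_same_year_cpi_adjustment_is_identity(self):
        cfg = SimulationConfig(seed=2)
        prices, cpi = generate_prices(cfg)
        adj = inflation_adjust(prices, cpi, 2005, 2005)
        np.testing.assert_allclose(adj.table["price_per_100g"],
                                   prices.table["price_per_100g"])

    def test_price_table_reproducible(self):
        a, ca = generate_prices(SimulationConfig(seed=3))
        b, cb = generate_prices(SimulationConfig(seed=3))
        np.testing.assert_array_equal(a.table["price_per_100g"],
                                      b.table["price_per_100g"])
        np.testing.assert_array_equal(ca.table["index"], cb.table["index"])
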