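import numpy as np
import pandas as pd
import pytest

from saltgrad import inference, synth
from saltgrad.inference import (
    CANDIDATE_TERMS,
    ModelSpec,
    akaike_weights,
    compare_polynomial,
    fit_lmm,
    fit_ols,
    lag_covariates,
    model_selection,
    pearson_ci,
    r2_mixed,
    random_structure_choice,
    refit_excluding,
    vif,
)


class TestFitOls:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = fit_ols(x, 2 * x + 1)
        assert fit.coef("x").estimate == pytest.approx(2.0)
        assert fit.coef("intercept").estimate == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_duplicated_points_same_estimates(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.3, 1.1, 2.2, 2.8])
        single = fit_ols(x, y)
        doubled = fit_ols(np.tile(x, 2), np.tile(y, 2))
        assert doubled.coef("x").estimate == pytest.approx(single.coef("x").estimate)
        # doubled df shrinks the CI
        assert (doubled.coef("x").upper - doubled.coef("x").lower) < (
            single.coef("x").upper - single.coef("x").lower
        )

    def test_slope_ci_coverage_under_null(self):
        """With y independent of x, the 95% CI should cover 0 ~95% of the time."""
        rng = np.random.default_rng(12)
        x = np.linspace(0, 1, 20)
        covered = 0
        n_sims = 400
        for _ in range(n_sims):
            y = rng.normal(size=20)
            c = fit_ols(x, y).coef("x")
            covered += c.lower <= 0 <= c.upper
        rate = covered / n_sims
        assert 0.92 <= rate <= 0.98

    def test_constant_x_raises(self):
        with pytest.raises(inference.DegenerateDesignError):
            fit_ols([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_raises(self):
        with pytest.raises(inference.DegenerateDesignError):
            fit_ols([1.0, 2.0], [1.0, 2.0])


class TestComparePolynomial:
    def test_strongly_quadratic_data(self):
        x = np.linspace(-3, 3, 20)
        y = 1 + 0.5 * x + 2 * x**2
        check = compare_polynomial(x, y + np.random.default_rng(0).normal(0, 0.05, 20))
        assert check.decision == "quadratic"

    def test_exactly_linear_data(self):
        x = np.linspace(0, 10, 20)
        check = compare_polynomial(x, 3 * x + 1)
        assert check.decision == "linear"

    def test_f_statistic_matches_hand_computation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.1, 1.2, 1.9, 3.3, 3.8, 5.3])
        check = compare_polynomial(x, y)
        import statsmodels.api as sm

        X1 = sm.add_constant(np.column_stack([x]))
        X2 = sm.add_constant(np.column_stack([x, x**2]))
        rss1 = sm.OLS(y, X1).fit().ssr
        rss2 = sm.OLS(y, X2).fit().ssr
        f_hand = (rss1 - rss2) / (rss2 / (len(x) - 3))
        assert check.f_stat == pytest.approx(f_hand)

    def test_rarely_quadratic_on_linear_low_noise(self):
        """On truly linear data the joint AIC+F rule fires ~4.5% of the time
        (the chi-square tail of the likelihood ratio); the observed rate over
        400 simulations must stay within sampling error of that."""
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 50)
        quad = 0
        n_sims = 400
        for _ in range(n_sims):
            y = 2 * x + rng.normal(0, 0.1 * np.ptp(2 * x) / 10, 50)
            if compare_polynomial(x, y).decision == "quadratic":
                quad += 1
        assert quad / n_sims <= 0.065


class TestRefitExcluding:
    def test_exclude_nothing_identical(self):
        x = np.arange(6.0)
        y = np.array([0.2, 1.3, 1.9, 3.1, 4.2, 4.8])
        full, reduced = refit_excluding(x, y, [])
        assert full.coef("x").estimate == reduced.coef("x").estimate

    def test_high_leverage_point_flips_slope(self):
        # 5 points trending up plus one far-out point dragging the slope down
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 20.0])
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0, -10.0])
        full, reduced = refit_excluding(x, y, [5])
        assert full.coef("x").estimate < 0
        assert reduced.coef("x").estimate > 0

    def test_on_line_exclusion_keeps_slope(self):
        x = np.arange(6.0)
        full, reduced = refit_excluding(x, 2 * x, [3])
        assert reduced.coef("x").estimate == pytest.approx(full.coef("x").estimate)

    def test_too_small_remainder_raises(self):
        with pytest.raises(inference.DegenerateDesignError):
            refit_excluding([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0])


class TestPearsonCi:
    def test_identity_degenerate(self):
        a = np.arange(10.0)
        r, lo, hi = pearson_ci(a, a)
        assert (r, hi) == (1.0, 1.0)

    def test_negation(self):
        a = np.arange(10.0)
        r, lo, hi = pearson_ci(a, -a)
        assert r == -1.0

    def test_matches_hand_computation(self):
        a = np.array([1.2, 2.1, 2.9, 4.2, 4.8, 6.1, 7.3, 8.0, 9.2, 10.1])
        b = np.array([0.8, 2.5, 2.2, 4.9, 4.1, 6.8, 6.9, 8.8, 8.7, 10.9])
        r, lo, hi = pearson_ci(a, b)
        r_hand = float(
            np.sum((a - a.mean()) * (b - b.mean()))
            / (a.std(ddof=1) * b.std(ddof=1) * (len(a) - 1))
        )
        assert r == pytest.approx(r_hand)
        z = np.arctanh(r_hand)
        half = 1.959963985 / np.sqrt(len(a) - 3)
        assert lo == pytest.approx(np.tanh(z - half), abs=1e-6)
        assert hi == pytest.approx(np.tanh(z + half), abs=1e-6)

    def test_zero_variance_raises(self):
        with pytest.raises(inference.DomainError):
            pearson_ci([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])


class TestVif:
    def test_orthogonal_predictors(self):
        n = 40
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        out = vif(pd.DataFrame({"a": a, "b": b}))
        assert np.allclose(out.values, 1.0)

    def test_duplicate_predictor_infinite(self):
        a = np.arange(10.0)
        out = vif(pd.DataFrame({"a": a, "b": a}))
        assert np.isinf(out).all()

    def test_known_correlation_closed_form(self):
        # r = 0.6 exactly between two standardised predictors
        rng = np.random.default_rng(1)
        n = 2000
        a = rng.normal(size=n)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.normal(size=n)
        # force exact sample correlation via Gram-Schmidt
        a = (a - a.mean()) / a.std()
        e = b - np.polyval(np.polyfit(a, b, 1), a)
        e = (e - e.mean()) / e.std()
        b = 0.6 * a + np.sqrt(1 - 0.36) * e
        out = vif(pd.DataFrame({"a": a, "b": b}))
        assert np.allclose(out.values, 1 / (1 - 0.36), atol=1e-9)


class TestFitLmm:
    def test_zero_station_variance_matches_ols(self):
        df = synth.simulate_mixed_model_data(
            {"intercept": 1.0, "salinity": 0.05, "ln_din": 0.3},
            n_stations=12,
            n_obs_per_station=40,
            sigma_station=0.0,
            sigma_resid=0.5,
            seed=3,
        )
        spec = ModelSpec("response", ("salinity", "ln_din"), random_intercept="station_id")
        lmm = fit_lmm(spec, df)
        import statsmodels.formula.api as smf

        ols = smf.ols("response ~ salinity + ln_din", df).fit()
        for term, sm_name in [("salinity", "salinity"), ("ln_din", "ln_din")]:
            assert lmm.coef(term).estimate == pytest.approx(
                float(ols.params[sm_name]), abs=1e-3
            )

    def test_wald_ci_coverage(self):
        """CIs from the global model cover the true coefficients ~95%."""
        beta = {
            "intercept": 1.0,
            "salinity": 0.05,
            "ln_din": 0.3,
            "sqrt_silicate": -0.1,
            "ln_din:salinity": -0.01,
        }
        covered = {t: 0 for t in ("salinity", "ln_din", "sqrt_silicate", "ln_din:salinity")}
        n_sims = 60
        spec = ModelSpec(
            "response",
            ("salinity", "ln_din", "sqrt_silicate", "ln_din:salinity"),
            random_intercept="station_id",
        )
        for s in range(n_sims):
            df = synth.simulate_mixed_model_data(
                beta, n_stations=15, n_obs_per_station=30,
                sigma_station=0.4, sigma_resid=0.5, seed=100 + s,
            )
            fit = fit_lmm(spec, df)
            for t in covered:
                c = fit.coef(t)
                covered[t] += c.lower <= beta[t] <= c.upper
        for t, k in covered.items():
            # binomial(60, 0.95): central mass well above 0.85
            assert k / n_sims >= 0.85, (t, k / n_sims)

    def test_variance_components_recovered(self):
        df = synth.simulate_mixed_model_data(
            {"intercept": 1.0, "salinity": 0.05},
            n_stations=30,
            n_obs_per_station=60,
            sigma_station=1.0,
            sigma_resid=0.5,
            seed=7,
        )
        fit = fit_lmm(
            ModelSpec("response", ("salinity",), random_intercept="station_id"), df
        )
        assert fit.sigma2_random == pytest.approx(1.0, rel=0.5)
        assert fit.sigma2_resid == pytest.approx(0.25, rel=0.15)

    def test_singleton_groups_flagged(self):
        df = pd.DataFrame(
            {
                "station_id": [f"S{i}" for i in range(12)],
                "salinity": np.linspace(3, 35, 12),
                "response": np.linspace(3, 35, 12) * 0.1
                + np.random.default_rng(0).normal(0, 0.1, 12),
            }
        )
        fit = fit_lmm(
            ModelSpec("response", ("salinity",), random_intercept="station_id"), df
        )
        assert fit.diagnostics["singleton_groups"]

    def test_interaction_without_main_effect_rejected(self):
        with pytest.raises(inference.DomainError):
            ModelSpec("y", ("salinity", "ln_din:salinity"))


class TestRandomStructureChoice:
    def _spec(self):
        return ModelSpec(
            "response", ("salinity", "ln_din"), random_intercept="station_id"
        )

    def test_strong_station_effects_keep_intercept(self):
        df = synth.simulate_mixed_model_data(
            {"intercept": 1.0, "salinity": 0.05, "ln_din": 0.3},
            sigma_station=1.0,
            sigma_resid=0.5,
            n_stations=15,
            n_obs_per_station=40,
            seed=11,
        )
        assert random_structure_choice(self._spec(), df).decision == "with_station"

    def test_zero_station_effects_drop_intercept(self):
        df = synth.simulate_mixed_model_data(
            {"intercept": 1.0, "salinity": 0.05, "ln_din": 0.3},
            sigma_station=0.0,
            sigma_resid=0.5,
            n_stations=15,
            n_obs_per_station=40,
            seed=12,
        )
        assert random_structure_choice(self._spec(), df).decision == "without_station"

    def test_threshold_rule_on_small_delta(self):
        df = synth.simulate_mixed_model_data(
            {"intercept": 1.0, "salinity": 0.05, "ln_din": 0.3},
            sigma_station=0.0,
            sigma_resid=0.5,
            n_stations=15,
            n_obs_per_station=40,
            seed=13,
        )
        choice = random_structure_choice(self._spec(), df, delta_threshold=2.0)
        if choice.aic_with < choice.aic_without - 2:
            assert choice.decision == "with_station"
        else:
            assert choice.decision == "without_station"


class TestModelSelection:
    def test_weights_equal_aic_split(self):
        w = akaike_weights([100.0, 100.0])
        assert np.allclose(w, [0.5, 0.5])

    def test_weights_delta_two(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=5e-4)
        assert w[1] == pytest.approx(0.269, abs=5e-4)

    def test_weights_sum_to_one_and_order(self):
        rng = np.random.default_rng(2)
        aics = rng.uniform(50, 150, 6)
        w = akaike_weights(aics)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.argsort(w) == np.argsort(-aics))

    def test_candidate_set_is_six_hierarchical_models(self):
        assert len(CANDIDATE_TERMS) == 6
        for terms in CANDIDATE_TERMS:
            assert "salinity" in terms
            if "ln_din:salinity" in terms:
                assert "ln_din" in terms

    def test_true_interaction_selected(self):
        df = synth.simulate_mixed_model_data(
            {
                "intercept": 1.0,
                "salinity": 0.05,
                "ln_din": 0.3,
                "ln_din:salinity": -0.02,
            },
            n_stations=19,
            n_obs_per_station=105,
            sigma_station=0.3,
            sigma_resid=0.4,
            seed=21,
        )
        fits = model_selection(df, "response")
        assert "ln_din:salinity" in fits[0].spec.fixed_terms
        assert fits[0].aic_weight == max(f.aic_weight for f in fits)


class TestR2Mixed:
    def test_constructed_components(self):
        assert r2_mixed(1.0, 1.0, 2.0) == pytest.approx((0.25, 0.50))

    def test_zero_random_equalises(self):
        m, c = r2_mixed(2.0, 0.0, 1.0)
        assert m == c

    def test_null_model_zero(self):
        m, c = r2_mixed(0.0, 1.0, 1.0)
        assert m == 0.0

    def test_ordering_invariant(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            f, u, e = rng.uniform(0, 5, 3)
            m, c = r2_mixed(f, u, e + 1e-6)
            assert 0 <= m <= c <= 1


class TestLagCovariates:
    def _frame(self):
        rows = []
        for year in (2010, 2011):
            for month in range(12):
                rows.append(
                    {
                        "station_id": "S1",
                        "year": year,
                        "month": month,
                        "din": float(year * 100 + month),
                        "y": 1.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_previous_month_value_used(self):
        lagged, unlagged = lag_covariates(self._frame(), ["din"], lag=1)
        row = lagged[(lagged.year == 2011) & (lagged.month == 1)]  # February 2011
        assert row["din"].iloc[0] == 201100.0  # January 2011 value

    def test_year_wrap(self):
        lagged, _ = lag_covariates(self._frame(), ["din"], lag=1)
        jan_2011 = lagged[(lagged.year == 2011) & (lagged.month == 0)]
        assert jan_2011["din"].iloc[0] == 201011.0  # December 2010

    def test_first_month_dropped_from_both(self):
        lagged, unlagged = lag_covariates(self._frame(), ["din"], lag=1)
        assert len(lagged) == len(unlagged) == 23
        assert not (
            (lagged.year == 2010) & (lagged.month == 0)
        ).any()
        pd.testing.assert_frame_equal(
            lagged[["station_id", "year", "month"]],
            unlagged[["station_id", "year", "month"]],
        )

    def test_lag_zero_identity(self):
        frame = self._frame()
        lagged, unlagged = lag_covariates(frame, ["din"], lag=0)
        pd.testing.assert_frame_equal(lagged, frame)
        pd.testing.assert_frame_equal(unlagged, frame)
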