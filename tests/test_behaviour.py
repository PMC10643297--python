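import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from massai.behaviour import (CoefficientTable, assemble_context,
                              draw_coefficients, fit_double_hurdle,
                              hurdle_decision, decide_all, predict_yield,
                              winsorise_drift_adjust)
from massai.ecology import Param
from massai.synth import gen_behavioural_truth


def toy_ctx(n=1, **cols):
    base = {"const": 1.0, "subsidy": 0.3, "education": 6.0, "livestock": 1.0}
    base.update(cols)
    return pd.DataFrame({k: np.full(n, v) for k, v in base.items()})


def table(name="adopt", link="logit", bounds=(0.0, 1.0), **coefs):
    return CoefficientTable(name, {k: Param(v, v, v) for k, v in coefs.items()},
                            link=link, bounds=bounds)


class TestDrawCoefficients:
    def test_degenerate_interval_returns_estimate(self):
        t = table(const=1.25)
        rng = np.random.default_rng(0)
        assert draw_coefficients(t, rng)["const"] == 1.25

    def test_draws_stay_within_bounds(self):
        t = CoefficientTable("m", {"b": Param(1.0, 0.5, 1.5)})
        rng = np.random.default_rng(1)
        draws = [draw_coefficients(t, rng)["b"] for _ in range(10_000)]
        assert min(draws) >= 0.5 and max(draws) <= 1.5

    def test_empirical_mean_near_estimate(self):
        # CI half-width 0.49 -> implied SE = 0.25; mean of 10k draws within 3 SE/sqrt(n)
        t = CoefficientTable("m", {"b": Param(2.0, 1.51, 2.49)})
        rng = np.random.default_rng(2)
        draws = np.array([draw_coefficients(t, rng)["b"] for _ in range(10_000)])
        se = 0.98 / (2 * 1.96)
        assert abs(draws.mean() - 2.0) < 3 * se / np.sqrt(len(draws))

    def test_uniform_mode_covers_interval(self):
        t = CoefficientTable("m", {"b": Param(1.0, 0.0, 2.0)})
        rng = np.random.default_rng(3)
        draws = np.array([draw_coefficients(t, rng, "uniform")["b"]
                          for _ in range(2000)])
        assert draws.min() < 0.2 and draws.max() > 1.8


class TestHurdle:
    def test_zero_linear_predictor_gives_half_probability(self):
        adopt = table(const=0.0)
        qty = table("qty", link="log", bounds=(0, 1e6), const=0.0)
        _, _, p = hurdle_decision(toy_ctx(), adopt, qty, np.random.default_rng(0))
        assert p[0] == pytest.approx(0.5)

    def test_large_negative_intercept_suppresses_adoption(self):
        adopt = table(const=-30.0)
        qty = table("qty", link="log", bounds=(0, 1e6), const=3.0)
        amount, adopted, _ = hurdle_decision(toy_ctx(10_000), adopt, qty,
                                             np.random.default_rng(0))
        assert adopted.sum() == 0
        assert np.all(amount == 0)

    def test_hand_evaluated_toy_table(self):
        # p = logistic(0.5 + 2*0.3) = logistic(1.1); amount = exp(3 + 1*0.3)
        adopt = table(const=0.5, subsidy=2.0)
        qty = table("qty", link="log", bounds=(0, 1e6), const=3.0, subsidy=1.0)
        amount, adopted, p = hurdle_decision(toy_ctx(20_000), adopt, qty,
                                             np.random.default_rng(4))
        assert p[0] == pytest.approx(expit(1.1))
        assert amount[adopted][0] == pytest.approx(np.exp(3.3))
        # Bernoulli gate matches p in expectation
        assert adopted.mean() == pytest.approx(expit(1.1), abs=0.02)

    def test_missing_predictor_named_in_error(self):
        adopt = table(const=0.0, rainfall_dance=1.0)
        qty = table("qty", link="log", const=0.0)
        with pytest.raises(KeyError, match="rainfall_dance"):
            hurdle_decision(toy_ctx(), adopt, qty, np.random.default_rng(0))


@pytest.fixture(scope="module")
def world_tables():
    tables, _ = gen_behavioural_truth(0)
    return tables


@pytest.fixture(scope="module")
def hh_plots():
    from massai.synth import gen_survey
    hh, plots, _ = gen_survey(40, seed=0)
    return hh, plots


class TestDecideAll:
    def test_positive_subsidy_coefficient_monotonicity(self, world_tables, hh_plots):
        hh, plots = hh_plots
        ctx0 = assemble_context(hh, plots, 0.0)
        ctx7 = assemble_context(hh, plots, 0.7)
        t = world_tables["adopt_fert"]
        p0 = expit(t.linear_predictor(ctx0))
        p7 = expit(t.linear_predictor(ctx7))
        assert np.all(p7 > p0)

    def test_fixed_seed_reproduces_decisions(self, world_tables, hh_plots):
        hh, plots = hh_plots
        d1 = decide_all(hh, plots, 0.28, world_tables, np.random.default_rng(9))
        d2 = decide_all(hh, plots, 0.28, world_tables, np.random.default_rng(9))
        pd.testing.assert_frame_equal(d1, d2)

    def test_all_zero_tables_give_zero_amounts_half_gates(self, hh_plots):
        hh, plots = hh_plots
        tables = {
            "adopt_fert": table("adopt_fert", const=0.0),
            "qty_fert": table("qty_fert", link="identity", bounds=(0, 100), const=0.0),
        }
        d = decide_all(hh, plots, 0.5, tables, np.random.default_rng(0))
        assert np.all(d["fert_kg_ha"] == 0.0)


class TestYield:
    def test_identity_link_zero_coefficients_clamp_at_zero(self):
        t = table("yield", link="identity", bounds=(0.0, 5000.0), const=0.0)
        assert predict_yield(toy_ctx(), t)[0] == 0.0

    def test_clamp_engages_at_upper_bound(self):
        t = table("yield", link="log", bounds=(0.0, 5000.0), const=20.0)
        assert predict_yield(toy_ctx(), t)[0] == 5000.0

    def test_hand_case_four_predictors(self):
        t = table("yield", link="log", bounds=(0.0, 1e5),
                  const=6.0, subsidy=0.5, education=0.02, livestock=0.1)
        eta = 6.0 + 0.5 * 0.3 + 0.02 * 6.0 + 0.1 * 1.0
        assert predict_yield(toy_ctx(), t)[0] == pytest.approx(np.exp(eta))


class TestWinsorise:
    def test_identity_predictions_unchanged_with_full_limits(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        adj, drift = winsorise_drift_adjust(base, base, limits=(0, 100))
        assert drift == pytest.approx(1.0)
        np.testing.assert_allclose(adj, base)

    def test_outlier_clipped_to_upper_percentile(self):
        base = np.linspace(0, 10, 101)
        pred = np.array([5.0, 500.0])
        adj, _ = winsorise_drift_adjust(pred, base, limits=(1, 99),
                                        predictions_t0=base)
        assert adj[1] == pytest.approx(np.percentile(base, 99))

    def test_doubled_predictions_drift_half(self):
        base = np.linspace(0, 10, 50)
        adj, drift = winsorise_drift_adjust(2 * base, base, limits=(0, 100))
        assert drift == pytest.approx(0.5)
        # adjusted values never exceed the winsorised-and-rescaled ceiling
        assert adj.max() <= base.max() * drift + 1e-12


class TestFitDoubleHurdle:
    def test_recovers_generating_coefficients(self):
        tables, data = gen_behavioural_truth(seed=10, n=4000)
        adopt, qty = fit_double_hurdle(
            data, ["const", "subsidy", "education", "livestock"])
        for pred, truth in tables["adopt_fert"].coef.items():
            est = adopt.coef[pred]
            assert est.lo <= truth.estimate <= est.hi, f"adopt {pred}"
        for pred, truth in tables["qty_fert"].coef.items():
            est = qty.coef[pred]
            assert est.lo <= truth.estimate <= est.hi, f"qty {pred}"

    def test_perfect_separation_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        data = pd.DataFrame({"const": 1.0, "x": x,
                             "amount": np.where(x > 0, np.exp(rng.normal(3, 1, 200)), 0.0)})
        with pytest.raises(ValueError):
            fit_double_hurdle(data, ["const", "x"])

    def test_too_few_observations_rejected(self):
        data = pd.DataFrame({"const": np.ones(20), "amount": np.ones(20)})
        with pytest.raises(ValueError, match="at least 50"):
            fit_double_hurdle(data, ["const"])
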