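import numpy as np
import pytest
from scipy.integrate import quad

from zvasc.growth import (
    MODELS,
    _numeric_peak,
    compare_models,
    fit_growth_model,
    model_rate,
    model_value,
    peak_growth_time,
)
from zvasc.synthetic_data import GrowthSeriesSpec, generate_growth_series

REFERENCE_PARAMS = {
    "log_logistic": {"A": 2.0, "V_L": 10.0, "alpha": 30.0, "beta": 3.0},
    "log_normal": {"A": 2.0, "V_L": 10.0, "mu": 3.4, "sigma": 0.5},
    "gompertz": {"A": 2.0, "V_L": 10.0, "k": 0.15, "t_i": 30.0},
    "logistic": {"A": 2.0, "V_L": 10.0, "k": 0.2, "t_i": 30.0},
    "weibull": {"A": 2.0, "V_L": 10.0, "lam": 35.0, "k": 2.5},
    "richards": {"A": 2.0, "V_L": 10.0, "k": 0.2, "t_i": 30.0, "nu": 0.7},
}
ALL_MODELS = sorted(MODELS)


class TestModelValue:
    def test_log_logistic_half_rise_at_alpha(self):
        p = REFERENCE_PARAMS["log_logistic"]
        assert model_value("log_logistic", p, p["alpha"]) == pytest.approx(
            p["A"] + p["V_L"] / 2
        )

    def test_log_normal_half_rise_at_exp_mu(self):
        p = REFERENCE_PARAMS["log_normal"]
        assert model_value("log_normal", p, np.exp(p["mu"])) == pytest.approx(
            p["A"] + p["V_L"] / 2
        )

    @pytest.mark.parametrize("model_id", ALL_MODELS)
    def test_upper_asymptote(self, model_id):
        p = REFERENCE_PARAMS[model_id]
        assert model_value(model_id, p, 1e6) == pytest.approx(
            p["A"] + p["V_L"], abs=1e-6
        )

    @pytest.mark.parametrize("model_id", ALL_MODELS)
    def test_non_decreasing_in_time(self, model_id):
        t = np.linspace(1.0, 200.0, 500)
        v = model_value(model_id, REFERENCE_PARAMS[model_id], t)
        assert np.all(np.diff(v) >= -1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            model_value("log_normal", {"A": 0, "V_L": 1, "mu": 3, "sigma": 0}, 10.0)
        with pytest.raises(ValueError, match="t > 0"):
            model_value("log_logistic", REFERENCE_PARAMS["log_logistic"], -1.0)
        with pytest.raises(ValueError, match="unknown"):
            model_value("exponential", {}, 1.0)


class TestModelRate:
    @pytest.mark.parametrize("model_id", ALL_MODELS)
    def test_rate_non_negative(self, model_id):
        t = np.linspace(0.5, 300.0, 400)
        assert np.all(model_rate(model_id, REFERENCE_PARAMS[model_id], t) >= 0)

    @pytest.mark.parametrize("model_id", ALL_MODELS)
    def test_matches_central_difference_of_value(self, model_id):
        rng = np.random.default_rng(hash(model_id) % 2**31)
        p = REFERENCE_PARAMS[model_id]
        for t in rng.uniform(5.0, 120.0, 20):
            h = 1e-5 * t
            numeric = (
                model_value(model_id, p, t + h) - model_value(model_id, p, t - h)
            ) / (2 * h)
            analytic = model_rate(model_id, p, t)
            # abs floor covers cancellation where the rate underflows the
            # central difference (deep in the saturated tail)
            assert analytic == pytest.approx(numeric, rel=1e-6, abs=1e-8)

    def test_log_logistic_shallow_shape_is_monotone_decreasing(self):
        p = {"A": 0.0, "V_L": 10.0, "alpha": 30.0, "beta": 0.8}
        t = np.linspace(0.5, 200.0, 300)
        r = model_rate("log_logistic", p, t)
        assert np.all(np.diff(r) < 0)

    @pytest.mark.parametrize("model_id", ALL_MODELS)
    def test_rate_integrates_to_scale_factor(self, model_id):
        # integrate over the model's support: t > 0 for the log-time and
        # Weibull laws, the whole axis for the inflection-shifted laws
        # (their sigmoids carry a little mass at t < 0)
        p = REFERENCE_PARAMS[model_id]
        # 60/k time constants to the left of the inflection bounds the
        # missed mass by e^-60 while keeping the integrand finite
        lo = p["t_i"] - 60.0 / p["k"] if "t_i" in p else 1e-9
        mid = 30.0  # near the growth peak, so quad cannot step over the bump
        rate = lambda t: float(model_rate(model_id, p, t))
        total = quad(rate, lo, mid, limit=200)[0] + quad(rate, mid, np.inf,
                                                         limit=200)[0]
        assert total == pytest.approx(p["V_L"], rel=1e-4)


class TestPeakGrowthTime:
    def test_log_logistic_closed_form(self):
        t_star = peak_growth_time(
            "log_logistic", {"A": 0.0, "V_L": 1.0, "alpha": 30.0, "beta": 3.0}
        )
        assert t_star == pytest.approx(30.0 * 0.5 ** (1.0 / 3.0))
        assert t_star == pytest.approx(23.81, abs=0.01)

    def test_log_normal_closed_form(self):
        t_star = peak_growth_time(
            "log_normal", {"A": 0.0, "V_L": 1.0, "mu": 3.3, "sigma": 0.5}
        )
        assert t_star == pytest.approx(np.exp(3.05))
        assert t_star == pytest.approx(21.11, abs=0.01)

    def test_gompertz_and_logistic_peak_at_inflection(self):
        for model_id in ("gompertz", "logistic"):
            p = REFERENCE_PARAMS[model_id]
            assert peak_growth_time(model_id, p) == p["t_i"]

    def test_shallow_log_logistic_has_no_interior_maximum(self):
        p = {"A": 0.0, "V_L": 1.0, "alpha": 30.0, "beta": 0.9}
        assert peak_growth_time("log_logistic", p) is None

    @pytest.mark.parametrize("model_id", ALL_MODELS)
    def test_closed_form_equals_numeric_argmax(self, model_id):
        rng = np.random.default_rng(20)
        for _ in range(20 // len(ALL_MODELS) + 1):
            p = dict(REFERENCE_PARAMS[model_id])
            p["V_L"] = rng.uniform(5, 20)
            if model_id == "log_logistic":
                p["alpha"], p["beta"] = rng.uniform(15, 60), rng.uniform(1.3, 6)
            elif model_id == "log_normal":
                p["mu"], p["sigma"] = rng.uniform(2.5, 4), rng.uniform(0.2, 1.0)
            elif model_id in ("gompertz", "logistic", "richards"):
                p["k"], p["t_i"] = rng.uniform(0.1, 0.5), rng.uniform(20, 50)
            else:
                p["lam"], p["k"] = rng.uniform(20, 60), rng.uniform(1.5, 5)
            t_star = peak_growth_time(model_id, p)
            numeric = _numeric_peak(model_id, p)
            assert t_star == pytest.approx(numeric, rel=1e-4)


class TestFitting:
    @pytest.mark.parametrize("model_id", ALL_MODELS)
    def test_noise_free_round_trip(self, model_id):
        p = REFERENCE_PARAMS[model_id]
        series = generate_growth_series(
            GrowthSeriesSpec(model_id=model_id, params=p, n_points=60,
                             noise_sigma=0.0)
        )
        fit = fit_growth_model(series, model_id)
        assert fit.converged
        for name, truth in p.items():
            assert fit.params[name] == pytest.approx(truth, rel=1e-4)

    def test_noisy_recovery_median_error_within_five_percent(self):
        p = {"A": 2.0e6, "V_L": 1.2e7, "alpha": 32.0, "beta": 3.0}
        errors = []
        for seed in range(20):
            series = generate_growth_series(
                GrowthSeriesSpec(model_id="log_logistic", params=p, n_points=100,
                                 noise_sigma=0.02 * p["V_L"], seed=seed)
            )
            fit = fit_growth_model(series, "log_logistic", seed=seed)
            errors.extend(
                abs(fit.params[k] - p[k]) / abs(p[k]) for k in p
            )
        assert np.median(errors) <= 0.05

    def test_constant_series_flags_scale_boundary(self):
        from zvasc.quantify import VolumeSeries

        series = VolumeSeries("f", "whole", np.linspace(17, 90, 30),
                              np.full(30, 5.0e6))
        fit = fit_growth_model(series, "log_logistic")
        assert "V_L_boundary" in fit.flags

    def test_too_few_observations_rejected(self):
        from zvasc.quantify import VolumeSeries

        series = VolumeSeries("f", "whole", np.array([17.0, 20.0, 25.0]),
                              np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="observations"):
            fit_growth_model(series, "log_logistic")


class TestModelComparison:
    def test_log_logistic_data_prefers_log_logistic_over_gompertz(self):
        p = {"A": 2.0e6, "V_L": 1.2e7, "alpha": 32.0, "beta": 3.0}
        wins = 0
        for seed in range(20):
            series = generate_growth_series(
                GrowthSeriesSpec(model_id="log_logistic", params=p, n_points=100,
                                 noise_sigma=0.01 * p["V_L"], seed=100 + seed)
            )
            fits = {f.model_id: f for f in compare_models(
                series, ["log_logistic", "gompertz"], seed=seed)}
            wins += fits["log_logistic"].rss < fits["gompertz"].rss
        assert wins >= 18  # >= 90% of seeds

    def test_log_time_models_best_on_log_normal_data(self):
        # data simulated from the log-normal law: both log-time models beat
        # the four non-log-time models at low noise in most runs
        p = {"A": 2.0e6, "V_L": 1.2e7, "mu": np.log(26) + 0.36, "sigma": 0.6}
        ok = 0
        for seed in range(10):
            series = generate_growth_series(
                GrowthSeriesSpec(model_id="log_normal", params=p, n_points=100,
                                 noise_sigma=0.002 * p["V_L"], seed=seed)
            )
            fits = {f.model_id: f.rss for f in compare_models(
                series, ALL_MODELS, seed=seed)}
            log_worst = max(fits["log_normal"], fits["log_logistic"])
            other_best = min(fits["gompertz"], fits["logistic"],
                             fits["weibull"], fits["richards"])
            ok += log_worst < other_best
        assert ok >= 8

    def test_nested_richards_at_least_as_good_as_logistic(self):
        p = REFERENCE_PARAMS["logistic"]
        series = generate_growth_series(
            GrowthSeriesSpec(model_id="logistic", params=p, n_points=50,
                             noise_sigma=0.05, seed=4)
        )
        fits = {f.model_id: f for f in compare_models(
            series, ["logistic", "richards"], seed=0)}
        assert fits["richards"].rss <= fits["logistic"].rss * (1 + 1e-6) + 1e-9

    def test_duplicate_model_gives_identical_rss(self):
        series = generate_growth_series(GrowthSeriesSpec(noise_sigma=1e5, seed=1))
        fits = compare_models(series, ["log_logistic", "log_logistic"], seed=0)
        assert fits[0].rss == fits[1].rss

    def test_results_sorted_by_rss(self):
        series = generate_growth_series(GrowthSeriesSpec(noise_sigma=2e5, seed=2))
        fits = compare_models(series, ALL_MODELS, seed=0)
        rss = [f.rss for f in fits]
        assert rss == sorted(rss)

    def test_single_model_rejected(self):
        series = generate_growth_series(GrowthSeriesSpec(noise_sigma=0.0))
        with pytest.raises(ValueError, match="at least 2"):
            compare_models(series, ["log_logistic"])
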