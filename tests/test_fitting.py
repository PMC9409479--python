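"""Linear estimators, multi-start nonlinear least squares, and rate extraction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from seedwasp import rate_models, tables
from seedwasp.errors import PreconditionError, SingularDesignError
from seedwasp.fitting import (DurationRecord, RateObservation, fit_all_models,
                              fit_ikemoto, fit_nonlinear, fit_ordinary_linear,
                              rates_from_records, read_durations_csv,
                              write_durations_csv)
from seedwasp.rate_models import RateModelSpec, evaluate_rate

VIABLE = tables.VIABLE_TEMPERATURES


class TestOrdinaryLinear:
    def test_exact_line(self):
        fit = fit_ordinary_linear([(15.0, 0.01), (25.0, 0.03), (20.0, 0.02)])
        assert fit.params == pytest.approx([0.002, -0.02])
        assert fit.traits.LT == pytest.approx(10.0)
        assert fit.traits.DD == pytest.approx(500.0)

    def test_published_adult_exit_threshold(self):
        """Mean exit rates at 14.5-27.0 degC give LT = 7.3 degC to 1 dp."""
        df = tables.exit_rates()
        sub = df[df.temperature_c <= 27.0]
        fit = fit_ordinary_linear(zip(sub.temperature_c, sub.rate_per_day))
        assert round(fit.traits.LT, 1) == 7.3
        assert fit.traits.LT == pytest.approx(7.297, abs=5e-3)

    def test_published_adult_emergence_thermal_constant(self):
        """Mean emergence rates at all six temperatures give DD near 246.9."""
        df = tables.emergence_rates()
        fit = fit_ordinary_linear(zip(df.temperature_c, df.rate_per_day))
        assert fit.traits.DD == pytest.approx(246.9, rel=0.01)

    def test_identical_temperatures_rejected(self):
        with pytest.raises(SingularDesignError):
            fit_ordinary_linear([(20.0, 0.01), (20.0, 0.02), (20.0, 0.03)])

    @given(st.lists(
        st.tuples(st.floats(5, 35), st.floats(1e-3, 0.2)),
        min_size=4, max_size=30))
    def test_matches_normal_equations(self, pts):
        """OLS agrees with the closed-form normal-equation solution."""
        T = np.array([p[0] for p in pts])
        if np.ptp(T) < 1e-3:
            return
        y = np.array([p[1] for p in pts])
        X = np.column_stack([T, np.ones_like(T)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_ordinary_linear(pts)
        np.testing.assert_allclose(fit.params, beta, atol=1e-12)


class TestIkemoto:
    def test_exact_two_plus_one_points(self):
        # durations from D = K/(T - Tmin) with K = 100, Tmin = 10
        fit = fit_ikemoto([(20.0, 10.0), (30.0, 5.0), (25.0, 100.0 / 15.0)])
        assert fit.traits.LT == pytest.approx(10.0)
        assert fit.traits.DD == pytest.approx(100.0)

    def test_noiseless_inversion_is_exact(self):
        K, tmin = 250.0, 8.0
        temps = np.linspace(12.0, 30.0, 8)
        fit = fit_ikemoto([(t, K / (t - tmin)) for t in temps])
        assert fit.traits.DD == pytest.approx(K, abs=1e-9)
        assert fit.traits.LT == pytest.approx(tmin, abs=1e-9)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(42)
        K, tmin = 250.0, 8.0
        temps = rng.uniform(12.0, 30.0, 300)
        D = K / (temps - tmin) * (1 + rng.normal(0, 0.02, 300))
        fit = fit_ikemoto(zip(temps, D))
        assert fit.traits.DD == pytest.approx(K, rel=0.05)
        assert fit.traits.LT == pytest.approx(tmin, abs=0.4)


class TestNonlinear:
    def test_noiseless_self_consistency(self):
        truth = (0.12, 34.3, 6.0)
        obs = [(t, evaluate_rate("lactin1", truth, t))
               for t in (14.5, 18.8, 21.3, 24.0, 27.0, 30.2, 33.0)]
        fit = fit_nonlinear("lactin1", obs)
        assert fit.rss < 1e-16
        np.testing.assert_allclose(fit.params, truth, atol=1e-6)

    def test_n_equal_p_is_a_precondition_error(self):
        obs = [(15.0, 0.02), (20.0, 0.04), (25.0, 0.05)]
        with pytest.raises(PreconditionError):
            fit_nonlinear("lactin1", obs)

    def test_solution_beats_dense_grid_oracle(self):
        """On a tiny dataset the optimiser matches brute-force enumeration."""
        spec = RateModelSpec(
            "expo2", ("a", "b"), ((1e-4, 0.1), (0.01, 0.2)),
            lambda T, a, b: a * np.exp(b * T))
        obs = [(15.0, 0.012), (22.0, 0.034), (28.0, 0.061)]
        fit = fit_nonlinear(spec, obs)
        T = np.array([o[0] for o in obs])
        y = np.array([o[1] for o in obs])
        grid_rss = min(
            float(np.sum((a * np.exp(b * T) - y) ** 2))
            for a, b in itertools.product(np.linspace(1e-4, 0.1, 200),
                                          np.linspace(0.01, 0.2, 200)))
        assert fit.rss <= grid_rss + 1e-10

    def test_briere1_threshold_recovery_from_its_own_data(self):
        truth = (1.2e-4, 10.5, 35.0)
        rng = np.random.default_rng(20220722)
        obs = []
        for t in VIABLE:
            r = evaluate_rate("briere1", truth, t)
            obs.extend((t, max(r * (1 + e), 1e-6))
                       for e in rng.normal(0, 0.02, 20))
        fit = fit_nonlinear("briere1", obs)
        assert fit.traits.LT == pytest.approx(10.5, abs=0.5)

    @pytest.mark.parametrize("name", rate_models.NONLINEAR_NAMES)
    def test_each_model_recovers_its_own_curve(self, name):
        """Refitting 1%-noise data simulated from a model's own fit to the
        published mean rates reproduces that curve within 5%."""
        means = tables.exit_rates()
        truth_fit = fit_nonlinear(name, list(zip(means.temperature_c,
                                                 means.rate_per_day)))
        truth = truth_fit.params
        rng = np.random.default_rng(123)
        obs = []
        for t in list(VIABLE) + [34.3]:
            r = evaluate_rate(name, truth, t)
            if r <= 1e-4:
                continue  # no completed development to observe there
            obs.extend((t, r * (1 + e)) for e in rng.normal(0, 0.01, 40))
        refit = fit_nonlinear(name, obs)
        grid = np.linspace(14.5, 30.2, 40)
        np.testing.assert_allclose(
            evaluate_rate(name, refit.params, grid),
            evaluate_rate(name, truth, grid), rtol=0.05)


def test_fit_all_models_covers_every_candidate():
    means = tables.exit_rates()
    obs = list(zip(means.temperature_c, means.rate_per_day))
    durations = list(zip(tables.EXIT_MEANS.temperature_c,
                         tables.EXIT_MEANS.total_days))
    fits = fit_all_models(obs, durations=durations)
    assert {f.model for f in fits} == set(rate_models.MODEL_NAMES)
    for f in fits:
        assert f.rss >= 0 and f.p < f.n


class TestRecordsAndCsv:
    def make_records(self):
        return [
            DurationRecord("a", 20.0, total_days=20.0, sex="male",
                           fate="exited", kind="exit"),
            DurationRecord("b", 20.0, total_days=25.0, sex="female",
                           fate="exited", kind="exit"),
            DurationRecord("c", 20.0, sex="female", fate="prolonged", kind="exit"),
            DurationRecord("d", 20.0, larva_days=5.0, pupa_days=12.0,
                           total_days=17.0, sex="male", fate="emerged",
                           kind="emergence"),
            DurationRecord("e", 20.0, sex="male", fate="dead", kind="emergence"),
        ]

    def test_prolonged_and_dead_are_excluded_from_rates(self):
        obs = rates_from_records(self.make_records(), stage="larva_to_exit")
        assert [o.rate for o in obs] == pytest.approx([1 / 20.0, 1 / 25.0])

    def test_cohorts_do_not_mix(self):
        obs = rates_from_records(self.make_records(), stage="larva_to_emergence")
        assert [o.rate for o in obs] == pytest.approx([1 / 17.0])

    def test_sex_filter(self):
        obs = rates_from_records(self.make_records(), stage="larva_to_exit",
                                 group="female")
        assert [o.rate for o in obs] == pytest.approx([1 / 25.0])

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "durations.csv"
        recs = self.make_records()
        write_durations_csv(recs, path)
        back = read_durations_csv(path)
        assert len(back) == len(recs)
        by_id = {r.id: r for r in back}
        assert by_id["d"].larva_days == 5.0
        assert by_id["d"].kind == "emergence"
        assert by_id["c"].fate == "prolonged"
        assert by_id["a"].total_days == 20.0 and by_id["a"].kind == "exit"

    def test_invalid_durations_rejected(self):
        with pytest.raises(ValueError):
            DurationRecord("x", 20.0, total_days=-1.0)
        with pytest.raises(ValueError):
            DurationRecord("x", 20.0, larva_days=5.0, pupa_days=12.0,
                           total_days=10.0)
        with pytest.raises(ValueError):
            RateObservation(20.0, 0.0)
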