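import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from valsize import measures
from valsize.measures import (
    KAPPA,
    SIGMA2,
    CoxDivergenceError,
    brier_score,
    calibration_curve,
    calibration_slope,
    cox_fit_single,
    d_statistic,
    explained_randomness,
    harrell_c,
    km_censoring,
    normal_order_scores,
    r2_from_d,
)
from valsize._cox import CoxFit

from conftest import random_censored_data
from oracles import efron_loglik_oracle, grid_max_beta, harrell_c_oracle


# ---------------------------------------------------------------------------
# Cox fit
# ---------------------------------------------------------------------------


class TestCoxFit:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit_single([1.0, 1.0, 1.0], [1, 2, 3], [1, 1, 0])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit_single([1.0, 2.0], [1, 2], [0, 0])

    def test_monotone_likelihood_flagged_divergent(self):
        # the x=1 subject fails first, the other is censored later: the
        # score equation pushes beta to +infinity
        fit = cox_fit_single([1.0, 0.0], [1.0, 2.0], [1, 0])
        assert not fit.converged
        assert math.isnan(fit.se_beta)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(20):
            pi, time, event = random_censored_data(rng, 20)
            if np.ptp(pi) == 0 or event.sum() < 2:
                continue
            fit = cox_fit_single(pi, time, event)
            if not fit.converged:
                continue
            assert abs(fit.beta - grid_max_beta(pi, time, event)) < 1e-4

    def test_loglik_values_match_direct_formula(self, rng):
        pi, time, event = random_censored_data(rng, 30)
        fit = cox_fit_single(pi, time, event)
        assert fit.loglik == pytest.approx(
            efron_loglik_oracle(fit.beta, pi, time, event), abs=1e-8
        )
        assert fit.loglik_null == pytest.approx(
            efron_loglik_oracle(0.0, pi, time, event), abs=1e-8
        )

    def test_fitted_loglik_dominates_probed_betas(self, rng):
        pi, time, event = random_censored_data(rng, 40)
        fit = cox_fit_single(pi, time, event)
        for beta in np.linspace(-3, 3, 25):
            assert fit.loglik >= efron_loglik_oracle(beta, pi, time, event) - 1e-9
        assert fit.loglik >= fit.loglik_null

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        pi, time, event = random_censored_data(rng, 300)
        fit = cox_fit_single(pi, time, event)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"x": pi, "T": time, "E": event}), "T", "E"
        )
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se_beta == pytest.approx(cph.standard_errors_["x"], rel=1e-4)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)


# ---------------------------------------------------------------------------
# censoring Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKmCensoring:
    def test_all_events_gives_unity(self):
        G = km_censoring([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.all(G([0.5, 1.0, 2.5, 10.0]) == 1.0)

    def test_all_censored_closed_form(self):
        n = 6
        times = np.arange(1.0, n + 1)
        G = km_censoring(times, np.zeros(n, dtype=int))
        expected = np.cumprod([1.0 - 1.0 / (n - j) for j in range(n)])
        assert np.allclose(G(times), expected)

    def test_hand_calculation_mixed(self):
        # censorings at t=2 (4 at risk), t=4 (2 at risk), t=5 (1 at risk)
        time = [1.0, 2.0, 3.0, 4.0, 5.0]
        event = [1, 0, 1, 0, 0]
        G = km_censoring(time, event)
        assert G(1.0) == 1.0
        assert G(2.0) == pytest.approx(0.75)
        assert G(3.5) == pytest.approx(0.75)
        assert G(4.0) == pytest.approx(0.375)
        assert G(5.0) == pytest.approx(0.0)

    def test_left_limit(self):
        G = km_censoring([1.0, 2.0], [0, 0])
        assert G.left(1.0) == 1.0
        assert G(1.0) == pytest.approx(0.5)
        assert G.left(2.0) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# c-index
# ---------------------------------------------------------------------------


class TestHarrellC:
    def test_perfect_ordering(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        pi = np.array([4.0, 3.0, 2.0, 1.0])  # higher risk fails earlier
        est = harrell_c(pi, time, np.ones(4, dtype=int))
        assert est.estimate == 1.0

    def test_all_predictions_equal(self):
        est = harrell_c(np.zeros(5), np.arange(1.0, 6.0), np.ones(5, dtype=int))
        assert est.estimate == 0.5

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 120))
            pi, time, event = random_censored_data(rng, n)
            try:
                expected = harrell_c_oracle(pi, time, event)
            except ValueError:
                with pytest.raises(ValueError):
                    harrell_c(pi, time, event)
                continue
            assert harrell_c(pi, time, event).estimate == expected

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            harrell_c([1.0, 2.0], [3.0, 1.0], [1, 0])  # earlier member censored

    def test_ci_bracket(self, rng):
        pi, time, event = random_censored_data(rng, 80)
        est = harrell_c(pi, time, event)
        assert est.ci_low <= est.estimate <= est.ci_high
        assert 0.0 <= est.estimate <= 1.0


# ---------------------------------------------------------------------------
# normal order scores and the D statistic
# ---------------------------------------------------------------------------


class TestNormalOrderScores:
    def test_two_values_blom_by_hand(self):
        from scipy.stats import norm

        scores = normal_order_scores([3.0, -1.0])
        expected = norm.ppf((2 - 0.375) / 2.25) / KAPPA
        assert scores[0] == pytest.approx(expected)
        assert scores[1] == pytest.approx(-expected)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(
            st.floats(-50, 50, allow_nan=False).map(lambda v: round(v, 1)),
            min_size=2,
            max_size=60,
        )
    )
    def test_scores_sum_to_zero(self, values):
        assert abs(normal_order_scores(values).sum()) < 1e-10

    def test_rank_invariance(self, rng):
        pi = rng.normal(size=40)
        transformed = np.exp(3.0 * pi) - 5.0  # strictly monotone
        assert np.allclose(normal_order_scores(pi), normal_order_scores(transformed))

    def test_ties_averaged(self):
        scores = normal_order_scores([1.0, 1.0, 2.0])
        assert scores[0] == scores[1]
        assert abs(scores.sum()) < 1e-12

    def test_all_tied_gives_zeros(self):
        assert np.allclose(normal_order_scores([2.0, 2.0, 2.0]), 0.0)


class TestDStatistic:
    def test_constant_pi_rejected(self, rng):
        with pytest.raises(ValueError):
            d_statistic(np.ones(10), np.arange(1.0, 11.0), np.ones(10, dtype=int))

    def test_monotone_transform_invariance(self, rng):
        pi, time, event = random_censored_data(rng, 120)
        a = d_statistic(pi, time, event)
        b = d_statistic(np.tanh(pi) * 7.0, time, event)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-10)
        assert a.se == pytest.approx(b.se, abs=1e-10)


class TestR2FromD:
    @pytest.mark.parametrize(
        "d, expected",
        [(1.650, 0.394), (1.530, 0.359), (1.872, 0.456), (1.435, 0.330),
         (1.452, 0.335), (1.760, 0.425), (0.0, 0.0)],
    )
    def test_reference_values(self, d, expected):
        assert round(r2_from_d(d), 3) == pytest.approx(expected)

    def test_constants(self):
        assert round(KAPPA, 3) == 1.596
        assert round(SIGMA2, 3) == 1.645

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0, 100, allow_nan=False), st.floats(0.001, 10))
    def test_monotone_and_bounded(self, d, eps):
        lo, hi = r2_from_d(d), r2_from_d(d + eps)
        assert 0.0 <= lo < 1.0 and 0.0 <= hi < 1.0
        assert hi > lo
        assert r2_from_d(-d) == pytest.approx(r2_from_d(d))

    def test_delta_se_matches_numerical_derivative(self):
        d, se = 1.4, 0.2
        h = 1e-6
        num = (r2_from_d(d + h) - r2_from_d(d - h)) / (2 * h)
        assert measures.r2_se_from_d(d, se) == pytest.approx(abs(num) * se, rel=1e-6)


# ---------------------------------------------------------------------------
# explained randomness
# ---------------------------------------------------------------------------


class TestExplainedRandomness:
    def test_null_likelihood_gives_zero(self):
        fit = CoxFit(0.0, 1.0, -10.0, -10.0, True, 1)
        est = explained_randomness(
            [1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1, 1, 0], n_boot=0, _fit=fit
        )
        assert est.estimate == 0.0

    def test_halved_events_gain_formula(self):
        # l_beta - l_0 = k/2  ->  rho2 = 1 - exp(-1)
        k = 2
        fit = CoxFit(0.5, 1.0, -9.0 + k / 2.0, -9.0, True, 3)
        est = explained_randomness(
            [1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1, 1, 0], n_boot=0, _fit=fit
        )
        assert est.estimate == pytest.approx(1.0 - math.exp(-1.0))

    def test_unrelated_pi_near_zero(self, rng):
        time = rng.exponential(size=400)
        event = (rng.uniform(size=400) < 0.7).astype(int)
        pi = rng.normal(size=400)  # independent of outcome
        est = explained_randomness(pi, time, event, n_boot=0)
        assert abs(est.estimate) < 0.03

    def test_increases_with_effect_size(self, rng):
        vals = []
        for effect in (0.3, 0.9, 1.8):
            pi = rng.normal(size=800)
            T = rng.exponential(np.exp(-effect * pi))
            C = rng.exponential(2.0, size=800)
            t, d = np.minimum(T, C), (T <= C).astype(int)
            vals.append(explained_randomness(pi, t, d, n_boot=0).estimate)
        assert vals[0] < vals[1] < vals[2]

    def test_bootstrap_se_positive(self, rng):
        pi, time, event = random_censored_data(rng, 150)
        est = explained_randomness(pi, time, event, n_boot=50, rng=rng)
        assert est.se > 0


# ---------------------------------------------------------------------------
# Brier score
# ---------------------------------------------------------------------------


class TestBrierScore:
    def test_reduces_to_mse_without_censoring(self, rng):
        n = 60
        risk = rng.uniform(0.05, 0.95, n)
        time = rng.uniform(0.1, 9.0, n)
        event = np.ones(n, dtype=int)
        est = brier_score(risk, time, event, t=10.0, n_boot=0)
        assert est.estimate == pytest.approx(np.mean((1.0 - risk) ** 2), abs=1e-14)

    def test_all_followed_beyond_horizon_is_mse(self, rng):
        # censoring occurs, but only after t: G(t) = 1 and IPCW is inert
        n = 50
        risk = rng.uniform(0.05, 0.95, n)
        event = rng.integers(0, 2, n)
        time = np.where(event == 1, rng.uniform(0.5, 9.5, n), rng.uniform(10.5, 20.0, n))
        est = brier_score(risk, time, event, t=10.0, n_boot=0)
        status = ((time <= 10) & (event == 1)).astype(float)
        assert est.estimate == pytest.approx(np.mean((status - risk) ** 2), abs=1e-14)

    def test_perfect_foresight_zero(self):
        risk = np.array([0.999999999999, 1e-12, 0.999999999999, 1e-12])
        time = np.array([1.0, 11.0, 2.0, 12.0])
        event = np.array([1, 0, 1, 0])
        assert brier_score(risk, time, event, t=10.0, n_boot=0).estimate < 1e-12

    def test_hand_computed_censored_example(self):
        time = np.array([2.0, 4.0, 6.0, 11.0, 12.0, 8.0])
        event = np.array([1, 0, 1, 0, 1, 0])
        risk = np.array([0.8, 0.5, 0.9, 0.3, 0.7, 0.4])
        est = brier_score(risk, time, event, t=10.0, n_boot=0)
        # G: 1 before 4, 0.8 on [4,8), 0.5333 on [8,11), 0.2667 after
        # BS = (0.2^2/1 + 0.1^2/0.8 + (0.3^2 + 0.7^2)/0.53333) / 6 = 0.19
        assert est.estimate == pytest.approx(0.19, abs=1e-12)

    def test_zero_censoring_weight_rejected(self):
        with pytest.raises(ValueError, match="t=10"):
            brier_score([0.4, 0.5], [3.0, 5.0], [0, 0], t=10.0, n_boot=0)


# ---------------------------------------------------------------------------
# calibration slope and curve
# ---------------------------------------------------------------------------


class TestCalibrationSlope:
    def test_rescaled_pi_rescales_slope_exactly(self, rng):
        pi, time, event = random_censored_data(rng, 200)
        a = calibration_slope(pi, time, event)
        b = calibration_slope(2.0 * pi, time, event)
        assert b.estimate == pytest.approx(a.estimate / 2.0, rel=1e-6)
        assert b.se == pytest.approx(a.se / 2.0, rel=1e-6)

    def test_constant_pi_rejected(self):
        with pytest.raises(ValueError):
            calibration_slope(np.ones(6), np.arange(1.0, 7.0), np.ones(6, dtype=int))


class TestCalibrationCurve:
    @staticmethod
    def _self_calibrated(rng, n, scale=1.0):
        from valsize import cohort

        spec = cohort.default_covariate_spec()
        truth = cohort.TrueDataModel(
            beta_true=cohort.beta_for_pi_sd(spec, 0.9), baseline_rate=0.006
        )
        validated = cohort.make_validation_model(truth, shrinkage=scale)
        return cohort.generate_population(
            spec, truth, n, seed=int(rng.integers(1 << 31)), validated=validated
        )

    def test_self_calibrated_model_near_diagonal(self, rng):
        pop = self._self_calibrated(rng, 40_000)
        curve = calibration_curve(pop.risk10, pop.time, pop.event)
        assert curve.method == "spline_cox"
        assert np.max(np.abs(curve.observed - curve.predicted)) < 0.02

    def test_inflated_model_overestimates_high_risk(self, rng):
        pop = self._self_calibrated(rng, 40_000, scale=2.0)
        curve = calibration_curve(pop.risk10, pop.time, pop.event)
        top = curve.predicted >= np.quantile(curve.predicted, 0.8)
        assert np.all(curve.observed[top] < curve.predicted[top])

    def test_few_events_falls_back_and_logs(self, rng, caplog):
        pop = self._self_calibrated(rng, 150)
        with caplog.at_level("WARNING", logger="valsize.measures"):
            curve = calibration_curve(pop.risk10, pop.time, pop.event)
        assert curve.method == "decile_km"
        assert any("falling back" in r.message for r in caplog.records)

    def test_single_risk_value_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            calibration_curve([0.3, 0.3], [1.0, 2.0], [1, 0])


# ---------------------------------------------------------------------------
# bootstrap-vs-empirical agreement (scaled-down invariant)
# ---------------------------------------------------------------------------


def test_d_model_se_tracks_empirical_se_under_normal_pi(rng):
    """With an exactly normal PI the model-based SE of D is close to the
    empirical SE across replicates (within ~10% at ~100 events)."""
    n = 2000
    ests, ses = [], []
    for _ in range(150):
        pi = rng.normal(size=n)
        T = rng.exponential(np.exp(-pi) * 10.0)
        C = rng.exponential(8.0, size=n)
        t, d = np.minimum(T, C), (T <= C).astype(int)
        est = d_statistic(pi, t, d)
        ests.append(est.estimate)
        ses.append(est.se)
    ratio = np.mean(ses) / np.std(ests, ddof=1)
    assert 0.85 < ratio < 1.15
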