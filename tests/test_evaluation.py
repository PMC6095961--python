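"""Correlation, drop-time accuracy, critical-point and t-test statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mmgtorque import evaluation
from mmgtorque.errors import EvaluationError, InputError, ParameterError
from mmgtorque.evaluation import (
    NOT_REACHED,
    StandingSession,
    accuracy_pct,
    detect_critical_point,
    evaluate_prediction,
    gradient_pre_post,
    hypothesis_battery,
    pearson_r,
    time_to_fraction_drop,
    ttest_two_tailed,
)


class TestPearson:
    def test_identity(self, rng):
        x = rng.standard_normal(50)
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_negation(self, rng):
        x = rng.standard_normal(50)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        x = rng.standard_normal(200)
        y = 0.3 * x + rng.standard_normal(200)
        expected = stats.pearsonr(x, y).statistic
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(EvaluationError):
            pearson_r(np.ones(10), np.arange(10.0))


class TestTimeToDrop:
    def test_first_crossing(self):
        series = [1.0, 0.9, 0.6, 0.45, 0.4]
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert time_to_fraction_drop(series, t, 0.5) == 4.0

    def test_never_reached(self):
        series = np.linspace(1.0, 0.8, 10)
        assert time_to_fraction_drop(series, np.arange(1.0, 11.0), 0.5) is NOT_REACHED

    def test_monotone_in_fraction(self, rng):
        series = np.sort(rng.uniform(0.05, 1.0, 60))[::-1]
        series = series / series.max()
        t = np.arange(1.0, 61.0)
        times = []
        for frac in (0.7, 0.5, 0.3):
            ti = time_to_fraction_drop(series, t, frac)
            times.append(np.inf if ti is NOT_REACHED else ti)
        assert times[0] <= times[1] <= times[2]

    def test_noisy_crossing_with_smoothing(self, quick_session):
        truth = quick_session.truth
        T = np.array(truth["torque_norm_per_epoch"])
        t = np.arange(1.0, T.size + 1)
        rng = np.random.default_rng(0)
        noisy = np.clip(T + rng.normal(0, 0.02, T.size), 0, None)
        noisy = noisy / noisy.max()
        detected = time_to_fraction_drop(noisy, t, 0.5, smooth_s=5.0)
        assert detected == pytest.approx(truth["t_50_s"], abs=5.0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ParameterError):
            time_to_fraction_drop([1.0, 0.4], [1.0, 2.0], 1.5)


class TestAccuracy:
    def test_exact_match(self):
        assert accuracy_pct(120.0, 120.0) == pytest.approx(100.0)

    def test_hand_case(self):
        assert accuracy_pct(90.0, 100.0) == pytest.approx(90.0)

    def test_admits_negative(self):
        assert accuracy_pct(250.0, 100.0) == pytest.approx(-50.0)

    def test_not_reached_propagates(self):
        assert accuracy_pct(NOT_REACHED, 100.0) is None
        assert accuracy_pct(100.0, NOT_REACHED) is None

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(ParameterError):
            accuracy_pct(10.0, 0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    t_pred=st.floats(1.0, 500.0),
    t_actual=st.floats(1.0, 500.0),
    c=st.floats(0.01, 100.0),
)
def test_accuracy_scale_invariant(t_pred, t_actual, c):
    a = accuracy_pct(t_pred, t_actual)
    b = accuracy_pct(c * t_pred, c * t_actual)
    assert a == pytest.approx(b, abs=1e-6)


def brute_hinge_sse(t, y, tb):
    X = np.column_stack([np.ones(len(t)), t, np.maximum(0.0, t - tb)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


class TestCriticalPoint:
    def test_exact_piecewise_break(self):
        t = np.arange(1.0, 51.0)
        knee = 20.0  # 40% of 50 s
        y = np.where(t <= knee, 1.0, 1.0 - 0.02 * (t - knee))
        cp = detect_critical_point(y, t)
        assert cp.time_norm == pytest.approx(40.0, abs=100.0 / 50)
        assert not cp.degenerate
        assert cp.sse < 1e-20

    def test_linear_series_degenerate_earliest(self):
        t = np.arange(1.0, 31.0)
        y = 1.0 - 0.01 * t
        cp = detect_critical_point(y, t)
        assert cp.degenerate
        assert cp.break_index == 3  # earliest candidate

    def test_sse_optimal_over_all_breakpoints(self, rng):
        t = np.arange(1.0, 41.0)
        y = np.clip(1 - 0.03 * np.maximum(0, t - 15), 0, 1)
        y = y + rng.normal(0, 0.02, t.size)
        cp = detect_critical_point(y, t)
        all_sse = [brute_hinge_sse(t, y, t[b]) for b in range(3, t.size - 3)]
        assert cp.sse == pytest.approx(min(all_sse), rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(EvaluationError):
            detect_critical_point(np.ones(7), np.arange(1.0, 8.0))


class TestGradient:
    def test_exact_line_same_slopes(self):
        t = np.arange(1.0, 41.0)
        y = 1.0 - 0.01 * t
        pre, post = gradient_pre_post(y, t, 20.5)
        assert pre == pytest.approx(-0.01, abs=1e-12)
        assert post == pytest.approx(-0.01, abs=1e-12)

    def test_piecewise_slopes(self):
        t = np.arange(1.0, 41.0)
        y = np.where(t <= 20, 1.0 - 0.02 * t, 1.0 - 0.02 * 20)
        pre, post = gradient_pre_post(y, t, 20.5)
        assert pre == pytest.approx(-0.02, abs=1e-12)
        assert post == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        t = np.arange(1.0, 31.0)
        y = rng.standard_normal(30)
        split = 15.5
        pre, post = gradient_pre_post(y, t, split)
        for mask, slope in ((t < split, pre), (t >= split, post)):
            A = np.column_stack([np.ones(mask.sum()), t[mask]])
            beta = np.linalg.solve(A.T @ A, A.T @ y[mask])
            assert slope == pytest.approx(beta[1], abs=1e-10)

    def test_short_side_rejected(self):
        t = np.arange(1.0, 11.0)
        with pytest.raises(ParameterError):
            gradient_pre_post(np.ones(10) - 0.01 * t, t, 2.5)


class TestTTest:
    def test_identical_pairs_rejected(self):
        a = np.arange(10.0)
        with pytest.raises(EvaluationError, match="identical pairs"):
            ttest_two_tailed(a, a)

    def test_large_shift_significant(self, rng):
        a = rng.normal(0, 0.1, 10)
        b = a + 5.0 + rng.normal(0, 0.1, 10)
        assert ttest_two_tailed(a, b) < 0.001

    def test_matches_t_cdf_oracle(self, rng):
        for _ in range(20):
            a = rng.standard_normal(12)
            b = a + rng.standard_normal(12) * 0.5 + 0.2
            d = a - b
            tstat = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
            p_expected = 2 * stats.t.sf(abs(tstat), df=d.size - 1)
            assert ttest_two_tailed(a, b) == pytest.approx(p_expected, abs=1e-9)


class TestEvaluatePrediction:
    def test_perfect_prediction(self, rng):
        t = np.arange(1.0, 101.0)
        actual = np.clip(1 - 0.008 * np.maximum(0, t - 20), 0.3, 1)
        report = evaluate_prediction(actual, actual, t, smooth_s=0.0)
        assert report.pearson_r == pytest.approx(1.0)
        assert report.accuracy_pct == pytest.approx(100.0)
        assert not report.negative_accuracy


def _toy_sessions(n, rng, identical=False):
    sessions = []
    for i in range(n):
        t = np.arange(1.0, 61.0)
        decline = np.clip(1 - 0.02 * np.maximum(0, t - 15 - i), 0.2, 1)
        noise = rng.normal(0, 0.01, t.size)
        pred_rms = decline + noise
        pred_zc = pred_rms if identical else decline + rng.normal(0, 0.01, t.size)
        sessions.append(StandingSession(
            label=f"s{i}", t=t,
            rms_norm=np.clip(decline + rng.normal(0, 0.01, t.size), 0, None),
            zc_norm=np.clip(1 - decline + rng.normal(0, 0.01, t.size), 0, None),
            pred={"rms": pred_rms, "rms_zc": pred_zc},
        ))
    return sessions


class TestBattery:
    def test_structure(self, rng):
        out = hypothesis_battery(_toy_sessions(6, rng))
        hyp = out["hypotheses"]
        assert len(hyp) == 8  # 4 hypothesis rows x 2 models
        assert set(hyp["model"]) == {"rms", "rms_zc"}
        assert len(out["consistency"]) == 2

    def test_identical_predictions_give_na(self, rng):
        out = hypothesis_battery(_toy_sessions(5, rng, identical=True))
        assert (out["consistency"]["p_value"] == "n/a").all()

    def test_missing_variant_rejected(self, rng):
        sessions = _toy_sessions(3, rng)
        del sessions[1].pred["rms_zc"]
        with pytest.raises(InputError):
            hypothesis_battery(sessions)

    def test_strong_fatigue_initial_vs_final(self, rng):
        out = hypothesis_battery(_toy_sessions(10, rng))
        hyp = out["hypotheses"]
        rows = hyp[hyp["hypothesis"] == "initial_vs_final_torque"]
        assert (rows["p_value"].astype(float) < 0.01).all()
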