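import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pumpwatch import (
    BaselineProfile,
    DetectorConfig,
    DetectorState,
    Event,
    PressureSample,
    PumpScenario,
    SimConfig,
    conventional_step,
    fit_logistic,
    logistic_output,
    run_detector,
    simulate_run,
    sweep_window_sizes,
    vote,
    window_sd,
    window_slope,
)
from pumpwatch.baseline import BaselineEntry

CFG = DetectorConfig()

finite_pressures = st.lists(
    st.floats(min_value=-500, max_value=500, allow_nan=False), min_size=2, max_size=40
)


def flat_profile(rate: float, sd: float, mean: float = 10.0) -> BaselineProfile:
    return BaselineProfile({rate: BaselineEntry(rate, mean, sd, 100, float("nan"))})


class TestLogisticOutput:
    def test_decision_boundary_at_Q0(self):
        # root of -1.345 + 0.040 * P
        assert logistic_output(0.0, 1.345 / 0.040) == pytest.approx(0.5, abs=1e-12)

    def test_saturates_at_high_pressure(self):
        assert logistic_output(1.0, 1e6) == 1.0

    def test_printed_formula_value(self):
        assert logistic_output(1.0, 20.0) == pytest.approx(0.3269527, abs=1e-6)

    @given(
        q=st.floats(0, 100, allow_nan=False),
        p=st.floats(0, 800, allow_nan=False),
        dq=st.floats(0.01, 10),
        dp=st.floats(0.01, 10),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_increasing_in_P_decreasing_in_Q(self, q, p, dq, dp):
        assert logistic_output(q, p + dp) > logistic_output(q, p)
        assert logistic_output(q + dq, p) < logistic_output(q, p)


class TestWindowStatistics:
    def test_constant_window_slope_zero(self):
        assert window_slope([7.0] * 15, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        p = 3.0 + 0.2 * 2.0 * np.arange(15)
        assert window_slope(p, 2.0) == pytest.approx(0.2, rel=1e-12)

    @given(finite_pressures)
    @settings(derandomize=True, max_examples=100)
    def test_slope_matches_ols_oracle(self, p):
        t = 2.0 * np.arange(len(p))
        oracle = np.polyfit(t, p, 1)[0] if np.ptp(p) > 0 else 0.0
        assert window_slope(p, 2.0) == pytest.approx(oracle, abs=1e-9)

    @given(finite_pressures)
    @settings(derandomize=True, max_examples=100)
    def test_sd_matches_two_pass_oracle(self, p):
        m = sum(p) / len(p)
        oracle = math.sqrt(sum((x - m) ** 2 for x in p) / (len(p) - 1))
        assert window_sd(p) == pytest.approx(oracle, abs=1e-9)


class TestVote:
    def test_equivalent_to_brute_force_over_all_histories(self):
        for bits in itertools.product([False, True], repeat=10):
            assert vote(list(bits), CFG) == (sum(bits) >= 6)

    def test_boundary_five_of_ten_is_negative(self):
        assert not vote([True] * 5 + [False] * 5, CFG)

    def test_short_history_padded_with_negatives(self):
        assert not vote([True] * 5, CFG)
        assert vote([True] * 6, CFG)


class TestConventionalStep:
    def test_threshold_boundary(self):
        state = DetectorState(CFG)
        assert not conventional_step(state, PressureSample(0, 0.0, 1.0, 399.9), CFG)
        assert conventional_step(state, PressureSample(0, 2.0, 1.0, 400.0), CFG)
        assert state.alarm_t == 2.0

    def test_never_reaching_threshold_never_alarms(self, make_log):
        log = make_log(np.linspace(10, 399, 200))
        alarm, trace = run_detector(log, "conventional")
        assert alarm is None and not trace["final"].any()


class TestRegressionDetector:
    def test_flat_low_pressure_never_alarms(self, make_log):
        log = make_log(np.full(300, 20.0), rate=1.0)
        alarm, trace = run_detector(log, "regression")
        assert alarm is None and not trace["preliminary"].any()

    def test_decreasing_pressure_never_preliminary(self, make_log):
        # pressure far above the decision boundary, but falling
        log = make_log(np.linspace(300.0, 100.0, 200), rate=1.0)
        _, trace = run_detector(log, "regression")
        assert not trace["preliminary"].any()

    def test_boundary_crossing_trace_matches_hand_stepped_oracle(self, make_log):
        # noiseless ramp at Q=0 crossing the decision boundary P* = 1.345/0.040
        dt, n_flat = 2.0, 60
        p = np.concatenate([np.full(n_flat, 20.0),
                            20.0 + 1.0 * dt * np.arange(1, 121)])
        log = make_log(p, dt=dt, rate=0.0)
        _, trace = run_detector(log, "regression")

        # oracle: independent replay of the published decision rule
        slope_n, stat_n = CFG.slope_window_n, CFG.stat_window
        prelim_oracle = []
        for i in range(len(p)):
            if i + 1 < max(slope_n, stat_n):
                prelim_oracle.append(False)
                continue
            win = p[i + 1 - slope_n: i + 1]
            slope = np.polyfit(dt * np.arange(slope_n), win, 1)[0]
            mean_p = p[i + 1 - stat_n: i + 1].mean()
            prelim_oracle.append(slope > 0 and logistic_output(0.0, mean_p) >= 0.5)
        assert trace["preliminary"].tolist() == prelim_oracle

        final_oracle = [
            sum(prelim_oracle[max(0, i - 9): i + 1]) >= 6 for i in range(len(p))
        ]
        assert trace["final"].tolist() == final_oracle

        # the vote adds exactly (vote_k - 1) ticks after the first preliminary
        first_prelim = prelim_oracle.index(True)
        first_final = final_oracle.index(True)
        assert first_final == first_prelim + (CFG.vote_k - 1)


class TestSDDetector:
    def test_constant_pressure_never_preliminary(self, make_log):
        log = make_log(np.full(200, 10.0), rate=1.0)
        _, trace = run_detector(log, "sd", flat_profile(1.0, 0.5))
        assert not trace["preliminary"].any()

    def test_steep_noiseless_ramp_alarm_latency_is_vote_k_ticks(self, make_log):
        # every post-onset tick is preliminary positive, so the alarm fires
        # exactly vote_k ticks = 12 s = 0.2 min after onset
        dt, n_flat = 2.0, 300
        slope = 4.46
        p = np.concatenate([np.full(n_flat, 25.0),
                            25.0 + slope * dt * np.arange(1, 60)])
        log = make_log(p, dt=dt, rate=32.0)
        alarm, trace = run_detector(log, "sd", flat_profile(32.0, 0.0, 25.0))
        onset_t = n_flat * dt - dt  # last flat tick; ramp starts next tick
        assert alarm is not None
        assert alarm.alarm_t - onset_t == pytest.approx(CFG.vote_k * dt)

    def test_baseline_matched_noise_never_alarms(self, rng):
        # stationary Gaussian noise at the reference SD: the 2xSD rule fires
        # with probability ~1e-12 per tick, so 20 ten-minute runs stay silent
        profile = flat_profile(4.0, 1.0, 13.0)
        for _ in range(20):
            cfg = SimConfig(
                pumps=[PumpScenario(0, 4.0, 13.0, 1.0)],
                pre_occlusion_duration=600.0, max_post_duration=10.0,
                seed=int(rng.integers(2**31)),
            )
            log = simulate_run(cfg).pumps[0]
            alarm, _ = run_detector(log, "sd", profile)
            assert alarm is None

    def test_delay_non_increasing_in_slope(self, make_log):
        delays = []
        for slope in (0.3, 0.6, 1.2, 2.4, 4.8):
            p = np.concatenate([np.full(100, 10.0),
                                10.0 + slope * 2.0 * np.arange(1, 200)])
            log = make_log(p, rate=4.0)
            alarm, _ = run_detector(log, "sd", flat_profile(4.0, 0.0))
            assert alarm is not None
            delays.append(alarm.alarm_t - 99 * 2.0)
        assert delays == sorted(delays, reverse=True)

    def test_trace_length_and_non_occluded_run(self, make_log, rng):
        log = make_log(10.0 + rng.normal(0, 0.5, 150), rate=1.0)
        alarm, trace = run_detector(log, "sd", flat_profile(1.0, 0.5))
        assert len(trace) == 150
        assert alarm is None


class TestFitLogistic:
    def test_parameter_recovery_within_3se(self, rng):
        n = 10000
        q = rng.uniform(0, 32, n)
        p = rng.uniform(0, 120, n)
        z = -1.345 - 0.177 * q + 0.040 * p
        y = rng.uniform(size=n) < 1 / (1 + np.exp(-z))
        fit = fit_logistic(np.column_stack([q, p, y]))
        assert not fit.regularized
        for est, truth, se in zip((fit.b0, fit.bQ, fit.bP), (-1.345, -0.177, 0.040), fit.se):
            assert est == pytest.approx(truth, abs=3 * se)

    def test_null_labels_give_null_coefficients(self, rng):
        n = 5000
        q = rng.uniform(0, 32, n)
        p = rng.uniform(0, 120, n)
        y = rng.uniform(size=n) < 0.5
        fit = fit_logistic(np.column_stack([q, p, y]))
        assert fit.bQ == pytest.approx(0.0, abs=3 * fit.se[1])
        assert fit.bP == pytest.approx(0.0, abs=3 * fit.se[2])

    def test_label_swap_negates_coefficients(self, rng):
        n = 2000
        q = rng.uniform(0, 32, n)
        p = rng.uniform(0, 120, n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(1.0 - 0.03 * p))).astype(float)
        a = fit_logistic(np.column_stack([q, p, y]))
        b = fit_logistic(np.column_stack([q, p, 1 - y]))
        for x, z in zip((a.b0, a.bQ, a.bP), (b.b0, b.bQ, b.bP)):
            assert x == pytest.approx(-z, abs=1e-4)

    def test_perfect_separation_falls_back_to_ridge(self, rng):
        q = np.zeros(100)
        p = np.concatenate([np.full(50, 10.0), np.full(50, 100.0)])
        y = (p > 50).astype(float)
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_logistic(np.column_stack([q, p, y]))
        assert fit.regularized and fit.bP > 0

    def test_single_label_rejected(self):
        with pytest.raises(ValueError, match="both labels"):
            fit_logistic([(1.0, 10.0, 1.0), (2.0, 20.0, 1.0)])


class TestWindowSweep:
    def test_table_shape_and_bounds(self, rng):
        cfg = SimConfig(
            pumps=[PumpScenario(0, 4.0, 13.0, 1.0, occlusion_slope=1.075)],
            pre_occlusion_duration=200.0, max_post_duration=240.0, seed=4,
        )
        runs = [simulate_run(cfg)]
        profile = flat_profile(4.0, 1.0, 13.0)
        sizes = [4, 20, 40, 60]
        acc = sweep_window_sizes(runs, sizes, profile)
        assert list(acc.index) == [4.0, 20.0, 40.0, 60.0]
        assert ((acc >= 0) & (acc <= 100)).all()
        # noise-dominated 2-sample windows must not be the best choice
        assert acc.idxmax() > 4.0

    def test_too_small_window_rejected(self, rng):
        with pytest.raises(ValueError, match="below 2 samples"):
            sweep_window_sizes([], [2], flat_profile(1.0, 1.0))
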