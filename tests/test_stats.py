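"""Statistics: OLS vs the normal-equations oracle, phase classification,
rates, binned summaries, speeds, and the phase-comparison test."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from larvagram import SimulationConfig, StatsConfig, TemperatureWaveform, generate_temperature
from larvagram.stats import (
    DegenerateRegressionError,
    classify_phases,
    first_sweep_size,
    forward_speed,
    initiation_probability_by_angle,
    phase_comparison_test,
    regress_intensity_vs_length,
    straightening_waves_by_angle,
    thermotaxis_speed,
    turn_frequency,
)
from larvagram.tracks import synthesize_population_tracks


# ---------------------------------------------------------------------------
# OLS

def test_exact_linear_fit():
    x = np.arange(5.0)
    r = regress_intensity_vs_length(x, -2.0 * x)
    assert r.slope == pytest.approx(-2.0)
    assert r.r_squared == pytest.approx(1.0)
    assert r.slope_se == pytest.approx(0.0, abs=1e-12)


def test_four_point_hand_computed_ols():
    # {(0,0),(1,1),(2,1),(3,2)}: slope 0.6, intercept 0.1, r^2 = 0.9/1.1... by hand:
    # Sxx = 5, Sxy = 3 -> slope 0.6; intercept = 1 - 0.6*1.5 = 0.1
    # SSE = 0.01+0.09+0.49... compute: fitted = 0.1,0.7,1.3,1.9; resid 0.1,0.3,-0.3,0.1
    # SSE = 0.2, SST = 2.0 -> r2 = 0.9; SE = sqrt(0.2/2)/sqrt(5)
    x = np.array([0.0, 1.0, 2.0, 3.0])
    y = np.array([0.0, 1.0, 1.0, 2.0])
    r = regress_intensity_vs_length(x, y)
    assert r.slope == pytest.approx(0.6)
    assert r.intercept == pytest.approx(0.1)
    assert r.r_squared == pytest.approx(0.9)
    assert r.slope_se == pytest.approx(np.sqrt(0.2 / 2.0) / np.sqrt(5.0))


def test_zero_variance_regressor_rejected():
    with pytest.raises(DegenerateRegressionError):
        regress_intensity_vs_length(np.ones(5), np.arange(5.0))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 10_000))
def test_ols_matches_statsmodels(seed):
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    x = rng.normal(size=n)
    y = 1.5 * x + rng.normal(size=n)
    r = regress_intensity_vs_length(x, y)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    assert r.slope == pytest.approx(fit.params[1], rel=1e-9)
    assert r.intercept == pytest.approx(fit.params[0], rel=1e-9, abs=1e-9)
    assert r.slope_se == pytest.approx(fit.bse[1], rel=1e-9)
    assert r.r_squared == pytest.approx(fit.rsquared, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# phases

def test_constant_trace_is_all_neutral():
    trace = generate_temperature(TemperatureWaveform(amplitude_C=0.0), 120.0, 4.0)
    labels = classify_phases(trace)
    assert set(labels.labels) == {"neutral"}


def test_linear_ramp_is_all_warming():
    from larvagram.temperature import TemperatureTrace

    t = np.arange(0, 300, 0.5)
    trace = TemperatureTrace(time_s=t, temp_C=15.0 + 0.01 * t)
    labels = classify_phases(trace)
    assert np.all(labels.labels[2:-2] == "warming")


def test_sine_phase_fractions_match_brute_force_oracle():
    """Label fractions on a 6-min sine equal direct thresholding of the
    analytic derivative."""
    wf = TemperatureWaveform(offset_C=20.0, amplitude_C=1.0, period_s=360.0)
    trace = generate_temperature(wf, 3 * 360.0, 4.0)
    labels = classify_phases(trace)
    # oracle: label each sample from the true derivative of the sine
    dtdt = (2 * np.pi / 360.0) * np.cos(2 * np.pi * trace.time_s / 360.0)
    oracle = np.where(dtdt > 0.001, "warming", np.where(dtdt < -0.001, "cooling", "neutral"))
    agree = np.mean(labels.labels == oracle)
    assert agree > 0.98  # smoothing blurs only the band edges


def test_phase_labels_partition_the_trace():
    wf = TemperatureWaveform(offset_C=20.0, amplitude_C=1.0, period_s=360.0)
    trace = generate_temperature(wf, 1800.0, 2.0)
    labels = classify_phases(trace)
    total = sum(labels.duration_s(p) for p in ("warming", "cooling", "neutral"))
    assert total == pytest.approx(len(trace.time_s) * labels.dt)


def test_short_trace_rejected():
    trace = generate_temperature(TemperatureWaveform(), 0.5, 2.0)
    with pytest.raises(ValueError):
        classify_phases(trace, StatsConfig(smooth_window_s=10.0))


# ---------------------------------------------------------------------------
# rates and sweep sizes

def _ramp_phases(duration=240.0):
    from larvagram.temperature import TemperatureTrace

    t = np.arange(0, duration, 0.5)
    return classify_phases(TemperatureTrace(time_s=t, temp_C=15.0 + 0.01 * t))


def test_turn_frequency_arithmetic():
    phases = _ramp_phases(120.0)  # 2 warming minutes
    out = turn_frequency(np.array([10.0, 30.0, 50.0, 70.0, 90.0, 110.0]), phases)
    assert out["warming"]["rate_per_min"] == pytest.approx(3.0, rel=0.01)
    assert out["warming"]["se_per_min"] == pytest.approx(np.sqrt(6) / 2.0, rel=0.01)
    assert "cooling" not in out  # the ramp has no cooling time: undefined


def test_zero_maneuvers_give_zero_rate():
    phases = _ramp_phases()
    out = turn_frequency(np.array([]), phases)
    assert out["warming"]["rate_per_min"] == 0.0


def test_first_sweep_size_arithmetic():
    phases = _ramp_phases()
    out = first_sweep_size(np.array([10.0, 30.0]), np.array([40.0, 60.0]), phases)
    assert out["warming"]["mean_deg"] == pytest.approx(50.0)
    assert out["warming"]["se_deg"] == pytest.approx(10.0)
    single = first_sweep_size(np.array([10.0]), np.array([53.0]), phases)
    assert single["warming"]["mean_deg"] == pytest.approx(53.0)
    assert np.isnan(single["warming"]["se_deg"])  # SE undefined for n = 1
    assert np.isnan(single["cooling"]["mean_deg"])  # empty group flagged


# ---------------------------------------------------------------------------
# binned summaries

def test_binomial_probability_and_se_formula():
    bp = initiation_probability_by_angle(
        np.array([50.0] * 10), ["within_bend"] * 3 + ["tail"] * 7, 30.0)
    assert bp.n[0] == 10 and bp.m[0] == 3
    assert bp.p[0] == pytest.approx(0.3)
    assert bp.se[0] == pytest.approx(np.sqrt(0.3 * 0.7 / 10))
    zero = initiation_probability_by_angle(np.array([50.0] * 10), ["tail"] * 10, 30.0)
    assert zero.p[0] == 0.0 and zero.se[0] == 0.0


def test_ambiguous_initiations_counted_separately():
    bp = initiation_probability_by_angle(
        np.array([50.0, 55.0, 95.0]), ["tail", "ambiguous", "within_bend"], 30.0)
    assert bp.n_ambiguous == 1
    assert bp.n.sum() == 2


def test_initiation_probability_increases_with_angle():
    rng = np.random.default_rng(0)
    angles = np.concatenate([rng.uniform(40, 80, 60), rng.uniform(95, 140, 60)])
    classes = ["tail"] * 60 + ["within_bend"] * 60
    bp = initiation_probability_by_angle(angles, classes, 30.0)
    occupied = bp.n > 0
    assert np.all(np.diff(bp.p[occupied]) >= 0)


def test_straightening_waves_binned_mean_sd():
    out = straightening_waves_by_angle(np.array([50.0, 55.0, 95.0]),
                                       np.array([3, 3, 5]), 30.0)
    assert out.mean[0] == pytest.approx(3.0)
    assert out.sd[0] == pytest.approx(0.0)
    assert out.mean[-1] == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# speeds

def test_forward_speed_static_track_is_zero():
    track = np.tile([100.0, 100.0], (50, 1))
    speed, _ = forward_speed(track, [], 0.01, 8.0)
    assert speed == pytest.approx(0.0)


def test_forward_speed_constant_drift():
    # 0.32 mm/s at 0.01 mm/px and 8 Hz -> 4 px per frame
    n = 200
    track = np.column_stack([np.arange(n) * 4.0, np.zeros(n)])
    speed, se = forward_speed(track, [], 0.01, 8.0)
    assert speed == pytest.approx(0.32, rel=1e-6)
    # excluding a maneuver interval leaves the estimate unchanged
    speed2, _ = forward_speed(track, [(50, 80)], 0.01, 8.0)
    assert speed2 == pytest.approx(0.32, rel=1e-6)


def test_forward_speed_requires_non_maneuver_frames():
    track = np.zeros((20, 2))
    with pytest.raises(ValueError):
        forward_speed(track, [(0, 19)], 0.01, 8.0)


def test_thermotaxis_speed_exact_line():
    t = np.arange(0, 600.0, 1.0)
    pos = np.vstack([0.075 * t, 0.075 * t + 1.0])
    res = thermotaxis_speed(t, pos)
    assert res.speed_mm_s == pytest.approx(0.075, rel=1e-9)


def test_thermotaxis_speed_static_population_flagged():
    t = np.arange(0, 600.0, 1.0)
    pos = np.vstack([np.ones_like(t), 2 * np.ones_like(t)])
    res = thermotaxis_speed(t, pos)
    assert res.speed_mm_s == 0.0
    assert res.stabilized_immediately


def test_thermotaxis_speed_recovers_drift_with_noise_and_plateau():
    t, pos = synthesize_population_tracks(
        n_tracks=20, duration_s=1200.0, drift_mm_s=0.075, plateau_s=900.0, seed=4)
    res = thermotaxis_speed(t, pos)
    assert abs(res.speed_mm_s - 0.075) <= max(3 * res.se_mm_s, 0.002)
    assert res.stabilization_time_s < 950.0


# ---------------------------------------------------------------------------
# phase comparison

def test_identical_constant_groups_give_p_one():
    assert phase_comparison_test(np.full(5, 3.0), np.full(7, 3.0)) == 1.0


def test_welch_symmetric_under_group_swap():
    rng = np.random.default_rng(1)
    a, b = rng.normal(53, 10, 40), rng.normal(60, 10, 35)
    assert phase_comparison_test(a, b) == pytest.approx(phase_comparison_test(b, a))


def test_power_to_separate_warming_and_cooling_sweep_sizes():
    """N(53, 10^2) vs N(60, 10^2) at n=200: p < 0.005 in >= 95% of replicates."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(53, 10, 200), rng.normal(60, 10, 200)
        if phase_comparison_test(a, b) < 0.005:
            hits += 1
    assert hits >= 19


def test_permutation_test_agrees_with_welch_on_clear_difference():
    rng = np.random.default_rng(2)
    a, b = rng.normal(53, 10, 100), rng.normal(60, 10, 100)
    p_w = phase_comparison_test(a, b, "welch")
    p_p = phase_comparison_test(a, b, "permutation", seed=0)
    assert p_w < 0.01 and p_p < 0.01
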