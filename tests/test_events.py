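"""Event detection: wave chaining, displacement, the asymmetric region,
initiation-site classification, and maneuver assembly."""
import numpy as np
import pytest

from larvagram import SEGMENT_NAMES, EventConfig
from larvagram.body import segment_index
from larvagram.events import (
    AsymmetricRegion,
    NoRegionError,
    PeristalsisWave,
    assemble_maneuvers,
    classify_wave_initiation,
    detect_waves,
    measure_asymmetric_region,
    segments_per_wave,
    straightening_regions,
    wave_displacement,
)
from larvagram.segments import build_kymograph
from larvagram.vision import HeadSweepEvent

EC = EventConfig()


def _kymo(values, metric="fractional_length", rate=8.0):
    return build_kymograph(values, list(SEGMENT_NAMES), metric, 0, rate)


def test_constant_kymograph_has_no_waves():
    assert detect_waves(_kymo(np.zeros((11, 100)))) == []


def _ridge(n_frames=60, start=0, lag=2, amp=-0.15):
    """Anti-diagonal contraction ridge: A8 first, T1 last (length metric)."""
    values = np.zeros((11, n_frames))
    for s in range(11):           # s = 0 tail (A8) ... 10 head (T1)
        row = 10 - s              # head->tail row index
        t = start + 5 + s * lag
        values[row, t - 1:t + 2] = amp / 2
        values[row, t] = amp
    return values


def test_constructed_ridge_detected_as_single_tail_to_head_wave():
    waves = detect_waves(_kymo(_ridge()))
    assert len(waves) == 1
    w = waves[0]
    assert SEGMENT_NAMES[w.initiation_segment] == "A8"
    assert SEGMENT_NAMES[w.termination_segment] == "T1"
    assert w.speed_seg_s == pytest.approx(8.0 / 2.0, rel=0.1)  # 1 seg / 2 frames


def test_run_video_waves_all_tail_initiated_and_counted(run_dataset, run_result):
    truth_complete = [w for w in run_dataset.truth.waves
                      if w.t_end_s <= run_dataset.duration_s]
    assert len(run_result.waves) == len(truth_complete)
    a8, a7 = segment_index("A8"), segment_index("A7")
    assert all(w.initiation_segment in (a8, a7) for w in run_result.waves)


def test_wave_displacement_zero_for_static_track():
    tail = np.tile([50.0, 50.0], (40, 1))
    head = np.tile([50.0, 250.0], (40, 1))
    wave = PeristalsisWave(onset_frame=5, offset_frame=20,
                           segments=[(10, 5), (5, 12), (0, 20)], frame_rate_hz=8.0)
    assert wave_displacement(tail, head, wave, 200.0) == pytest.approx(0.0)


def test_measured_displacement_scales_with_generator_setting(sim_config):
    """Doubling the generator's per-wave displacement doubles the estimate."""
    from larvagram import TemperatureWaveform, simulate_dataset
    from larvagram.behavior import BehaviorProgram
    from larvagram.pipeline import run_video_pipeline

    means = {}
    for d in (0.13, 0.26):
        cfg = sim_config.__class__(displacement_per_wave_bl=d)
        program = BehaviorProgram(duration_s=15.0, turns=[])
        ds = simulate_dataset(cfg, TemperatureWaveform(), 15.0, seed=6, program=program)
        res = run_video_pipeline(ds)
        means[d] = res.wave_displacements_bl().mean()
    assert means[0.13] == pytest.approx(0.13, rel=0.08)
    assert means[0.26] / means[0.13] == pytest.approx(2.0, rel=0.1)


# ---------------------------------------------------------------------------
# asymmetric region

def test_zero_asymmetry_raises_no_region():
    kymo = build_kymograph(np.zeros((11, 50)), list(SEGMENT_NAMES), "asymmetry", None, 8.0)
    sweep = HeadSweepEvent(10, 20, "left", 60.0, 15)
    with pytest.raises(NoRegionError):
        measure_asymmetric_region(kymo, sweep, EC)


def test_single_segment_profile_yields_point_region():
    values = np.zeros((11, 50))
    values[segment_index("A2"), :] = 0.4
    kymo = build_kymograph(values, list(SEGMENT_NAMES), "asymmetry", None, 8.0)
    region = measure_asymmetric_region(kymo, HeadSweepEvent(10, 20, "left", 60.0, 15), EC)
    assert region.anterior_extent == region.posterior_extent == region.peak_segment == "A2"


def test_sixty_degree_sweep_region_centered_on_a1(sweep_results):
    m = sweep_results[50.0].maneuvers[0]
    assert m.region is not None
    assert m.region.peak_segment == "A1"
    names = set(SEGMENT_NAMES[m.region.anterior_index:m.region.posterior_index + 1])
    assert names <= {"T3", "A1", "A2", "A3"}


@pytest.mark.parametrize("init,expected", [
    ("A8", "tail"), ("A3", "within_bend"), ("A5", "ambiguous"),
])
def test_wave_initiation_classification(init, expected):
    region = AsymmetricRegion(
        anterior_index=segment_index("T3"), posterior_index=segment_index("A3"),
        peak_index=segment_index("A1"), frame=15)
    wave = PeristalsisWave(
        onset_frame=20, offset_frame=28,
        segments=[(segment_index(init), 20), (segment_index(init) - 2, 24),
                  (segment_index(init) - 3, 26), (segment_index(init) - 4, 28)],
        frame_rate_hz=8.0)
    assert classify_wave_initiation(wave, region, EC) == expected


def test_small_sweeps_classified_tail_and_large_within_bend(sweep_results):
    assert sweep_results[50.0].maneuvers[0].init_class == "tail"
    assert sweep_results[90.0].maneuvers[0].init_class == "within_bend"
    assert sweep_results[130.0].maneuvers[0].init_class == "within_bend"


# ---------------------------------------------------------------------------
# maneuver assembly

def _sweep(onset, offset, peak, sign=1):
    return HeadSweepEvent(onset, offset, "left" if sign > 0 else "right",
                          peak, onset + 2)


def _theta_for(sweeps, n, fill=0.0):
    theta = np.full(n, fill)
    for s in sweeps:
        theta[s.onset_frame:s.offset_frame + 1] = \
            (1 if s.direction == "left" else -1) * s.peak_deg
    return theta


def test_single_sweep_single_maneuver():
    sweeps = [_sweep(20, 40, 60.0)]
    theta = _theta_for(sweeps, 100)
    maneuvers = assemble_maneuvers(sweeps, [], theta, EC, 8.0)
    assert len(maneuvers) == 1
    assert maneuvers[0].n_sweeps == 1


def test_two_sweeps_without_straightening_merge():
    sweeps = [_sweep(20, 34, 60.0, 1), _sweep(36, 50, 80.0, -1)]
    theta = _theta_for(sweeps, 120, fill=0.0)
    theta[35] = 30.0  # brief dip, never sustained below threshold
    maneuvers = assemble_maneuvers(sweeps, [], theta, EC, 8.0)
    assert len(maneuvers) == 1
    assert maneuvers[0].n_sweeps == 2
    assert maneuvers[0].accepted_sweep is sweeps[1]


def test_two_sweeps_with_sustained_straightening_split():
    sweeps = [_sweep(20, 34, 60.0, 1), _sweep(60, 74, 80.0, -1)]
    theta = _theta_for(sweeps, 140)
    maneuvers = assemble_maneuvers(sweeps, [], theta, EC, 8.0)
    assert len(maneuvers) == 2


def test_overlapping_sweeps_rejected():
    sweeps = [_sweep(20, 40, 60.0), _sweep(30, 50, 70.0)]
    with pytest.raises(ValueError):
        assemble_maneuvers(sweeps, [], np.zeros(100), EC, 8.0)


def test_straightening_waves_counted_between_peak_and_straight():
    sweeps = [_sweep(20, 60, 60.0)]
    theta = np.zeros(120)
    theta[20:60] = np.linspace(60, 10, 40)
    waves = []
    for k, onset in enumerate((25, 33, 41, 80)):
        waves.append(PeristalsisWave(
            onset_frame=onset, offset_frame=onset + 6,
            segments=[(10, onset), (7, onset + 2), (4, onset + 4), (1, onset + 6)],
            frame_rate_hz=8.0))
    maneuvers = assemble_maneuvers(sweeps, waves, theta, EC, 8.0)
    assert len(maneuvers) == 1
    # the wave at frame 80 starts after the body straightened
    assert maneuvers[0].waves_to_straighten == 3


def test_waves_to_straighten_monotone_in_amplitude(sweep_results):
    counts = [sweep_results[a].maneuvers[0].waves_to_straighten
              for a in (50.0, 90.0, 130.0)]
    assert counts == sorted(counts)
    assert counts[0] <= 4         # small sweeps: 3-4 waves suffice
    assert counts[-1] <= 6        # large sweeps: 4-6 waves


def test_head_sweeps_start_after_previous_wave(default_video_result):
    res = default_video_result
    for m in res.maneuvers:
        prior_waves = [w for w in res.waves if w.onset_frame < m.onset_frame]
        if prior_waves:
            # sweep onset follows the end of the previous peristalsis cycle
            assert m.onset_frame >= prior_waves[-1].offset_frame - 2


def test_region_progression_tracks_two_segments_per_wave(sweep_results):
    res = sweep_results[50.0]
    m = res.maneuvers[0]
    regions = straightening_regions(res.kymo_asymmetry, m, res.waves, EC)
    steps = segments_per_wave(regions)
    assert len(steps) >= 1
    assert abs(np.mean(steps) - 2.0) <= 0.75
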