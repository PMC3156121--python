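"""Event detection: peristalsis waves, per-wave displacement, the region of
asymmetric contraction, wave-initiation site, and reorientation maneuvers.

Waves are found by chaining per-segment contraction peaks that move strictly
head-ward with a bounded inter-segment lag; a maneuver groups consecutive
head sweeps that are not separated by a sustained straightened body.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .body import N_SEGMENTS, SEGMENT_NAMES
from .config import EventConfig
from .segments import Kymograph
from .vision import HeadSweepEvent

__all__ = [
    "PeristalsisWave",
    "AsymmetricRegion",
    "ReorientationManeuver",
    "detect_waves",
    "wave_displacement",
    "measure_asymmetric_region",
    "classify_wave_initiation",
    "assemble_maneuvers",
    "annotate_maneuvers",
]


class NoRegionError(RuntimeError):
    """No segment exceeds the asymmetry threshold at the sweep peak."""


class TrackGapError(RuntimeError):
    """Head/tail track is missing frames inside the wave interval."""


@dataclass
class PeristalsisWave:
    """A tail-to-head contraction wave chained across segments.

    ``segments`` holds (segment index head->tail, peak frame) pairs ordered
    from the initiation (posterior) to the termination (anterior) segment;
    indices therefore strictly decrease along the chain.
    """

    onset_frame: int
    offset_frame: int
    segments: list[tuple[int, int]]
    frame_rate_hz: float

    def __post_init__(self) -> None:
        idx = [s for s, _ in self.segments]
        if len(idx) < 2 or np.any(np.diff(idx) >= 0):
            raise ValueError("wave segments must progress strictly head-ward")

    @property
    def initiation_segment(self) -> int:
        return self.segments[0][0]

    @property
    def termination_segment(self) -> int:
        return self.segments[-1][0]

    @property
    def onset_s(self) -> float:
        return self.onset_frame / self.frame_rate_hz

    @property
    def offset_s(self) -> float:
        return self.offset_frame / self.frame_rate_hz

    @property
    def speed_seg_s(self) -> float:
        dt = max(self.offset_frame - self.onset_frame, 1) / self.frame_rate_hz
        return (len(self.segments) - 1) / dt


@dataclass
class AsymmetricRegion:
    """Extent of asymmetric contraction at the frame of peak |theta|."""

    anterior_index: int       # head->tail segment index (smaller = more anterior)
    posterior_index: int
    peak_index: int
    frame: int

    def __post_init__(self) -> None:
        if not (self.anterior_index <= self.peak_index <= self.posterior_index):
            raise ValueError("region peak must lie within [anterior, posterior]")

    @property
    def anterior_extent(self) -> str:
        return SEGMENT_NAMES[self.anterior_index]

    @property
    def posterior_extent(self) -> str:
        return SEGMENT_NAMES[self.posterior_index]

    @property
    def peak_segment(self) -> str:
        return SEGMENT_NAMES[self.peak_index]

    def contains(self, segment_index: int) -> bool:
        return self.anterior_index <= segment_index <= self.posterior_index


@dataclass
class ReorientationManeuver:
    """One or more head sweeps plus the peristalsis bookkeeping around them."""

    sweeps: list[HeadSweepEvent]
    onset_frame: int
    straightened_frame: int          # first frame of the sustained straight run
    waves_to_straighten: int
    intervening_wave_counts: list[int]
    first_wave: PeristalsisWave | None = None
    region: AsymmetricRegion | None = None
    init_class: str | None = None    # "tail" | "within_bend" | "ambiguous"
    phase: str | None = None         # thermal phase at onset

    @property
    def accepted_sweep(self) -> HeadSweepEvent:
        return self.sweeps[-1]

    @property
    def first_sweep(self) -> HeadSweepEvent:
        return self.sweeps[0]

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)


# ---------------------------------------------------------------------------
# wave detection

def _contraction_signal(kymo: Kymograph) -> np.ndarray:
    """Per-segment signal that is positive during contraction, rows T1..A8."""
    if kymo.values.shape[0] != N_SEGMENTS:
        raise ValueError("wave detection expects an 11-row per-segment kymograph")
    if kymo.metric == "fractional_length":
        return -kymo.values
    if kymo.metric == "fractional_intensity":
        return kymo.values
    raise ValueError(f"kymograph metric {kymo.metric!r} is not a contraction measure")


def detect_waves(kymo: Kymograph, config: EventConfig | None = None) -> list[PeristalsisWave]:
    """Chain per-segment contraction peaks into tail-to-head waves.

    A peak in segment s links to a peak in the next head-ward segment whose
    frame lies within [min_lag, max_lag] frames; one missing segment may be
    skipped (with a doubled lag window).  Chains shorter than
    ``min_chain_segments`` are dropped.
    """
    config = config or EventConfig()
    signal = _contraction_signal(kymo)
    # tail-based rows: s = 0 is A8, s = 10 is T1
    rows = signal[::-1]
    peaks: list[np.ndarray] = []
    for s in range(N_SEGMENTS):
        p, _ = find_peaks(rows[s], height=config.wave_amplitude_threshold, distance=3)
        peaks.append(p)
    used = [np.zeros(len(p), dtype=bool) for p in peaks]

    waves: list[PeristalsisWave] = []
    for s0 in range(N_SEGMENTS):
        for j0, f0 in enumerate(peaks[s0]):
            if used[s0][j0]:
                continue
            chain = [(s0, int(f0))]
            used_local = [(s0, j0)]
            s, f = s0, int(f0)
            while s < N_SEGMENTS - 1:
                linked = False
                for step in (1, 2):
                    if s + step > N_SEGMENTS - 1:
                        break
                    lo = f + config.min_lag_frames
                    hi = f + step * config.max_lag_frames
                    cand = np.flatnonzero(
                        (peaks[s + step] >= lo) & (peaks[s + step] <= hi)
                        & ~used[s + step])
                    if len(cand):
                        j = int(cand[0])
                        s += step
                        f = int(peaks[s][j])
                        chain.append((s, f))
                        used_local.append((s, j))
                        linked = True
                        break
                if not linked:
                    break
            if len(chain) >= config.min_chain_segments:
                for ss, jj in used_local:
                    used[ss][jj] = True
                segments = [(N_SEGMENTS - 1 - s, f) for s, f in chain]
                waves.append(PeristalsisWave(
                    onset_frame=chain[0][1], offset_frame=chain[-1][1],
                    segments=segments, frame_rate_hz=kymo.frame_rate_hz))
    waves.sort(key=lambda w: w.onset_frame)
    return waves


def wave_displacement(
    tail_xy: np.ndarray,
    head_xy: np.ndarray,
    wave: PeristalsisWave,
    body_length: float,
    end_frame: int | None = None,
) -> float:
    """Tail displacement over the wave, projected on the mean body axis.

    Positions and ``body_length`` must share units (px or mm); the result is
    in body lengths, positive for forward (tail-toward-head) movement.
    ``end_frame`` defaults to the wave's last contraction peak; passing the
    next wave's onset instead measures the full-cycle displacement (waves
    run back to back, and a chain can terminate at T2 rather than T1, so
    peak-to-peak spans undercount the cycle).
    """
    f0 = wave.onset_frame
    f1 = wave.offset_frame if end_frame is None else end_frame
    seg_tail = tail_xy[f0:f1 + 1]
    seg_head = head_xy[f0:f1 + 1]
    if np.any(~np.isfinite(seg_tail)) or np.any(~np.isfinite(seg_head)):
        raise TrackGapError("missing head/tail positions inside the wave interval")
    axes = seg_head - seg_tail
    norms = np.linalg.norm(axes, axis=1, keepdims=True)
    axis = (axes / norms).mean(axis=0)
    axis /= np.linalg.norm(axis)
    disp = seg_tail[-1] - seg_tail[0]
    return float(np.dot(disp, axis)) / body_length


def measure_asymmetric_region(
    asym_kymo: Kymograph,
    sweep: HeadSweepEvent,
    config: EventConfig | None = None,
) -> AsymmetricRegion:
    """Contiguous run of segments with |a| >= threshold at the sweep peak."""
    config = config or EventConfig()
    if asym_kymo.metric != "asymmetry":
        raise ValueError("expected an asymmetry kymograph")
    frame = sweep.peak_frame
    if frame >= asym_kymo.n_frames:
        raise ValueError("kymograph does not cover the sweep peak frame")
    a = asym_kymo.values[:, frame]
    above = np.abs(a) >= config.asym_threshold
    if not above.any():
        raise NoRegionError("no segment exceeds the asymmetry threshold")
    peak = int(np.nanargmax(np.abs(a)))
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi < N_SEGMENTS - 1 and above[hi + 1]:
        hi += 1
    return AsymmetricRegion(anterior_index=lo, posterior_index=hi,
                            peak_index=peak, frame=frame)


def classify_wave_initiation(
    wave: PeristalsisWave,
    region: AsymmetricRegion,
    config: EventConfig | None = None,
) -> str:
    """Initiation site class of the first post-sweep wave."""
    config = config or EventConfig()
    init = wave.initiation_segment
    if region.contains(init):
        return "within_bend"
    if SEGMENT_NAMES[init] in config.tail_segments:
        return "tail"
    return "ambiguous"


# ---------------------------------------------------------------------------
# maneuver assembly

def _straight_run_starts(theta_deg: np.ndarray, config: EventConfig,
                         frame_rate_hz: float) -> np.ndarray:
    """Start frames of sustained straightened runs (|theta| < thr for >= 1 s)."""
    below = np.abs(np.asarray(theta_deg)) < config.straight_threshold_deg
    need = max(1, int(round(config.straight_sustain_s * frame_rate_hz)))
    starts = []
    run = 0
    for f, b in enumerate(below):
        run = run + 1 if b else 0
        if run == need:
            starts.append(f - need + 1)
    return np.asarray(starts, dtype=int)


def assemble_maneuvers(
    sweeps: list[HeadSweepEvent],
    waves: list[PeristalsisWave],
    theta_deg: np.ndarray,
    config: EventConfig | None = None,
    frame_rate_hz: float = 8.0,
) -> list[ReorientationManeuver]:
    """Group sweeps into maneuvers and count straightening waves.

    Consecutive sweeps merge into one maneuver when no sustained straightened
    interval separates them (non-final sweeps are the rejected ones).
    ``waves_to_straighten`` counts waves initiated between the accepted
    sweep's peak and the first sustained straightened frame: the sweep event
    itself only releases once the body is nearly straight, so the count runs
    from the peak of the accepted sweep.
    """
    config = config or EventConfig()
    sweeps = sorted(sweeps, key=lambda s: s.onset_frame)
    for a, b in zip(sweeps, sweeps[1:]):
        if b.onset_frame < a.offset_frame:
            raise ValueError("overlapping head sweeps")
    straight_starts = _straight_run_starts(theta_deg, config, frame_rate_hz)
    n_frames = len(theta_deg)

    groups: list[list[HeadSweepEvent]] = []
    for sweep in sweeps:
        if groups:
            prev = groups[-1][-1]
            separated = np.any(
                (straight_starts >= prev.offset_frame)
                & (straight_starts + int(config.straight_sustain_s * frame_rate_hz)
                   <= sweep.onset_frame))
            if not separated:
                groups[-1].append(sweep)
                continue
        groups.append([sweep])

    wave_onsets = np.array([w.onset_frame for w in waves], dtype=int)
    maneuvers: list[ReorientationManeuver] = []
    for group in groups:
        accepted = group[-1]
        after = straight_starts[straight_starts >= accepted.peak_frame]
        straightened = int(after[0]) if len(after) else n_frames - 1
        in_window = (wave_onsets >= accepted.peak_frame) & (wave_onsets < straightened)
        first_idx = np.flatnonzero(in_window)
        first_wave = waves[first_idx[0]] if len(first_idx) else None
        intervening = []
        for a, b in zip(group, group[1:]):
            intervening.append(int(np.sum(
                (wave_onsets >= a.offset_frame) & (wave_onsets < b.onset_frame))))
        maneuvers.append(ReorientationManeuver(
            sweeps=list(group),
            onset_frame=group[0].onset_frame,
            straightened_frame=straightened,
            waves_to_straighten=int(np.sum(in_window)),
            intervening_wave_counts=intervening,
            first_wave=first_wave,
        ))
    return maneuvers


def straightening_regions(
    asym_kymo: Kymograph,
    maneuver: ReorientationManeuver,
    waves: list[PeristalsisWave],
    config: EventConfig | None = None,
) -> list[AsymmetricRegion | None]:
    """Asymmetric region before and after each straightening wave.

    Returns one region (or None when nothing exceeds the threshold) at the
    accepted sweep's peak frame and just after each wave initiated during
    straightening, tracking the retrograde (tail-ward) progression of the
    region as successive waves carry segments around the bend.
    """
    config = config or EventConfig()
    in_window = [w for w in waves
                 if maneuver.accepted_sweep.peak_frame <= w.onset_frame
                 < maneuver.straightened_frame]
    frames = [maneuver.accepted_sweep.peak_frame]
    frames += [min(w.offset_frame + 1, asym_kymo.n_frames - 1) for w in in_window]
    out: list[AsymmetricRegion | None] = []
    for f in frames:
        probe = HeadSweepEvent(onset_frame=f, offset_frame=f, direction="left",
                               peak_deg=0.0, peak_frame=f)
        try:
            out.append(measure_asymmetric_region(asym_kymo, probe, config))
        except NoRegionError:
            out.append(None)
    return out


def segments_per_wave(regions: list[AsymmetricRegion | None]) -> list[int]:
    """Posterior-extent advance (segments) between consecutive region fixes.

    Steps where the region vanished, or where its posterior extent had
    already reached the last segment (clamped at the tail), are excluded.
    """
    steps: list[int] = []
    for a, b in zip(regions, regions[1:]):
        if a is None or b is None or a.posterior_index >= N_SEGMENTS - 1:
            continue
        steps.append(b.posterior_index - a.posterior_index)
    return steps


def annotate_maneuvers(
    maneuvers: list[ReorientationManeuver],
    asym_kymo: Kymograph | None,
    config: EventConfig | None = None,
) -> list[ReorientationManeuver]:
    """Fill in the asymmetric region and initiation class where measurable."""
    config = config or EventConfig()
    for m in maneuvers:
        if asym_kymo is not None:
            try:
                m.region = measure_asymmetric_region(asym_kymo, m.accepted_sweep, config)
            except NoRegionError:
                m.region = None
        if m.first_wave is not None and m.region is not None:
            m.init_class = classify_wave_initiation(m.first_wave, m.region, config)
    return maneuvers
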