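"""Event-level track synthesis (no rendering): centroid runs with maneuvers
interspersed, and population drift tracks on a spatial gradient.

These emulate the coarse trajectory data behind the run-speed and
thermotaxis-speed statistics: runs at constant speed with persistent
heading, stationary pauses during maneuvers, heading changes equal to the
accepted head-sweep angle, and a population drifting up-gradient until it
reaches preferred temperature and stabilizes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import BehaviorProgram
from .config import SimulationConfig

__all__ = ["CentroidTrack", "synthesize_centroid_track", "synthesize_population_tracks"]


@dataclass
class CentroidTrack:
    time_s: np.ndarray
    xy_px: np.ndarray                       # (n, 2)
    maneuver_intervals: list[tuple[int, int]]  # frame spans [f0, f1]


def synthesize_centroid_track(
    program: BehaviorProgram,
    config: SimulationConfig | None = None,
    seed: int = 0,
    jitter_mm: float = 0.001,
) -> CentroidTrack:
    """Centroid trajectory implied by a behavior program.

    During runs the centroid advances at the configured run speed along the
    current heading; during maneuvers it stays put (plus measurement
    jitter); after each maneuver the heading turns by the accepted sweep's
    signed amplitude (leftward positive).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x545241434B]))
    rate = config.frame_rate_hz
    n = int(round(program.duration_s * rate))
    t = np.arange(n) / rate
    v = config.effective_run_speed_mm_s / rate  # mm per frame
    xy = np.zeros((n, 2))
    heading = rng.uniform(0, 2 * np.pi)
    intervals: list[tuple[int, int]] = []
    turn_ptr = 0
    turns = program.turns
    pos = np.zeros(2)
    for f in range(1, n):
        tf = t[f]
        while turn_ptr < len(turns) and tf >= turns[turn_ptr].end_s:
            acc = turns[turn_ptr].accepted_sweep
            heading += acc.direction * np.radians(acc.amplitude_deg)
            turn_ptr += 1
        in_turn = turn_ptr < len(turns) and turns[turn_ptr].onset_s <= tf
        if not in_turn:
            pos = pos + v * np.array([np.cos(heading), np.sin(heading)])
        xy[f] = pos
    for turn in turns:
        f0 = int(np.floor(turn.onset_s * rate))
        f1 = int(np.ceil(turn.end_s * rate))
        intervals.append((f0, min(f1, n - 1)))
    xy += rng.normal(0.0, jitter_mm, size=xy.shape)
    return CentroidTrack(time_s=t, xy_px=xy / config.pixel_scale_mm,
                         maneuver_intervals=intervals)


def synthesize_population_tracks(
    n_tracks: int = 20,
    duration_s: float = 1200.0,
    rate_hz: float = 1.0,
    drift_mm_s: float = 0.075,
    jitter_mm: float = 0.5,
    plateau_s: float | None = 900.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal gradient-axis positions: drift then stabilization.

    Each track climbs the gradient at ``drift_mm_s`` until ``plateau_s``
    (reaching preferred temperature), then holds, with independent
    per-sample position jitter.  Returns (time_s, positions (n_tracks, T)).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x504F5055]))
    nt = int(round(duration_s * rate_hz)) + 1
    t = np.arange(nt) / rate_hz
    if plateau_s is None:
        plateau_s = duration_s
    ramp = np.minimum(t, plateau_s)
    x0 = rng.uniform(-5.0, 5.0, size=n_tracks)
    base = x0[:, None] + drift_mm_s * ramp[None, :]
    noise = rng.normal(0.0, jitter_mm, size=base.shape)
    return t, base + noise
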