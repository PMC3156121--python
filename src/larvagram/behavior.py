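"""Behavior-program sampling: runs, turn onsets, head sweeps, straightening.

A program is a timeline of forward runs interrupted by reorientation
maneuvers.  Turn onsets follow an inhomogeneous Poisson process whose rate
depends on the sign of dT/dt (cooling raises the rate); head-sweep
amplitudes are drawn from phase-specific truncated normals; each non-final
sweep may be "rejected" (followed by another sweep) with a probability that
is logistic in dT/dt, cooling raising rejection.

Every maneuver carries a fully determined internal schedule (sweep ramps,
holds, straightening waves) shared by the event-level bend-angle series and
the rendered kinematics, so event-level and video-level timelines agree.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .body import segment_index
from .config import SimulationConfig
from .temperature import TemperatureTrace

__all__ = [
    "SweepPlan",
    "TurnPlan",
    "BehaviorProgram",
    "sample_behavior",
    "maneuver_schedule",
    "program_theta_series",
    "bend_half_width",
    "pivot_center_from_tail",
    "planned_straightening",
]

N_BOUND = 11  # boundary coordinate runs 0 (tail tip) .. 11 (head tip) here


@dataclass(frozen=True)
class SweepPlan:
    direction: int            # +1 leftward, -1 rightward
    amplitude_deg: float      # target peak |theta|
    accepted: bool


@dataclass
class TurnPlan:
    onset_s: float
    sweeps: list[SweepPlan]
    straightening_mode: str   # "tail_initiated" | "bend_initiated"
    n_straighten_waves: int
    duration_s: float
    phase: str                # "warming" | "cooling" | "neutral" (at onset)

    @property
    def accepted_sweep(self) -> SweepPlan:
        return self.sweeps[-1]

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class BehaviorProgram:
    duration_s: float
    turns: list[TurnPlan] = field(default_factory=list)

    def __post_init__(self) -> None:
        t_prev = -np.inf
        for turn in self.turns:
            if turn.onset_s < t_prev:
                raise ValueError("maneuvers overlap in time")
            if not turn.sweeps or not turn.accepted_sweep.accepted:
                raise ValueError("every maneuver's last sweep must be accepted")
            if any(s.amplitude_deg <= 0 for s in turn.sweeps):
                raise ValueError("sweep amplitudes must be positive")
            t_prev = turn.end_s

    def run_intervals(self) -> list[tuple[float, float]]:
        """(start, end) of forward runs between maneuvers."""
        out, t = [], 0.0
        for turn in self.turns:
            if turn.onset_s > t:
                out.append((t, turn.onset_s))
            t = turn.end_s
        if t < self.duration_s:
            out.append((t, self.duration_s))
        return out


# ---------------------------------------------------------------------------
# bend geometry shared with the kinematics module

def pivot_center_from_tail(config: SimulationConfig) -> float:
    """Pivot-centre position in the tail-based boundary coordinate (A1 -> 7.5)."""
    i = segment_index(config.pivot_center)
    return (10 - i) + 0.5


def bend_half_width(phi_rad: float, config: SimulationConfig) -> float:
    """Raised-cosine bend half-width (segments), widening for large bends.

    Below ~86 deg of total bend the profile keeps the narrow half-width that
    confines asymmetry to T3..A3; very large bends must spread over more
    segments to respect the geometric limit on per-segment turning.
    """
    lo, hi = config.bend_half_width_seg, config.bend_half_width_large_seg
    u = np.clip((abs(phi_rad) - 1.5) / 1.4, 0.0, 1.0)
    u = u * u * (3 - 2 * u)  # smoothstep
    return float(lo + (hi - lo) * u)


def planned_straightening(theta0_deg: float, config: SimulationConfig) -> list[float]:
    """Per-wave bend-angle schedule [theta_1, ..., theta_n] during straightening.

    Each peristalsis wave carries ``segments_per_wave_around_bend`` segments
    past the pivot; the bend angle decays linearly in the distance the bend
    centre has travelled toward the tail and the larva counts as straight
    below ``straightened_deg``.
    """
    c0 = pivot_center_from_tail(config)
    phi_rough = math.radians(theta0_deg) / 0.85
    travel_total = c0 + bend_half_width(phi_rough, config)
    step = config.segments_per_wave_around_bend
    thetas: list[float] = []
    theta = theta0_deg
    k = 0
    while theta >= config.straightened_deg and k < 10:
        k += 1
        theta = theta0_deg * max(0.0, 1.0 - step * k / travel_total)
        thetas.append(theta)
    return thetas


# ---------------------------------------------------------------------------
# amplitude sampling

def _truncnorm_ab(loc: float, sd: float, lo: float, hi: float):
    return (lo - loc) / sd, (hi - loc) / sd


def truncated_normal_location(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter so that the [lo, hi]-truncated normal has the target mean."""

    def err(loc: float) -> float:
        a, b = _truncnorm_ab(loc, sd, lo, hi)
        return float(truncnorm.mean(a, b, loc=loc, scale=sd)) - target_mean

    return float(brentq(err, lo - 8 * sd, hi, xtol=1e-6))


def _sample_amplitude(rng: np.random.Generator, loc: float, config: SimulationConfig) -> float:
    a, b = _truncnorm_ab(loc, config.sweep_sd_deg, config.min_sweep_deg, config.max_sweep_deg)
    return float(
        truncnorm.rvs(a, b, loc=loc, scale=config.sweep_sd_deg, random_state=rng)
    )


# ---------------------------------------------------------------------------
# maneuver schedule

def _build_turn(
    onset_s: float,
    sweeps: list[SweepPlan],
    phase: str,
    config: SimulationConfig,
) -> TurnPlan:
    theta0 = sweeps[-1].amplitude_deg
    mode = "tail_initiated" if theta0 < 90.0 else "bend_initiated"
    thetas = planned_straightening(theta0, config)
    turn = TurnPlan(
        onset_s=onset_s,
        sweeps=sweeps,
        straightening_mode=mode,
        n_straighten_waves=len(thetas),
        duration_s=0.0,
        phase=phase,
    )
    turn.duration_s = maneuver_schedule(turn, config)[-1][2]
    return turn


def maneuver_schedule(turn: TurnPlan, config: SimulationConfig):
    """Expand a maneuver into timed phases, relative times in seconds.

    Returns a list of tuples ``(kind, t0, t1, theta_from, theta_to, extra)``
    where ``kind`` is one of ``ramp`` (cosine sweep ramp), ``hold`` (at sweep
    peak), ``wave`` (one straightening peristalsis wave; extra = (c_from,
    c_to, s_start) in the tail-based boundary coordinate) and ``relax``
    (final settling to a straight body).
    """
    P = config.wave_period_s
    c0 = pivot_center_from_tail(config)
    phases = []
    t = 0.0
    theta = 0.0
    for i, sweep in enumerate(turn.sweeps):
        target = sweep.direction * sweep.amplitude_deg
        if i > 0 and np.sign(target) == np.sign(theta) and theta != 0.0:
            # same-direction resweep: dip below the release threshold first
            dip = float(np.sign(theta)) * 15.0
            phases.append(("ramp", t, t + 0.5 * config.sweep_rise_s, theta, dip, None))
            t += 0.5 * config.sweep_rise_s
            theta = dip
        phases.append(("ramp", t, t + config.sweep_rise_s, theta, target, None))
        t += config.sweep_rise_s
        theta = target
        phases.append(("hold", t, t + config.sweep_hold_s, theta, theta, None))
        t += config.sweep_hold_s
    # straightening waves
    sign = float(np.sign(theta))
    theta0 = abs(theta)
    thetas = planned_straightening(theta0, config)
    phi_rough = math.radians(theta0) / 0.85
    hw = bend_half_width(phi_rough, config)
    step = config.segments_per_wave_around_bend
    c = c0
    prev = theta0
    for theta_k in thetas:
        c_to = c - step
        if turn.straightening_mode == "bend_initiated":
            # start inside the visibly asymmetric region (the raised-cosine
            # tails fall below measurable asymmetry near +/- half-width)
            s_start = max(0.0, c - 0.7 * hw)
        else:
            s_start = 0.0
        dur = P * (N_BOUND - s_start) / N_BOUND
        phases.append(("wave", t, t + dur, sign * prev, sign * theta_k, (c, c_to, s_start)))
        t += dur
        c = c_to
        prev = theta_k
    phases.append(("relax", t, t + 0.75, sign * prev, 0.0, (c, c, None)))
    t += 0.75
    return phases


def _theta_in_phase(kind, t0, t1, th0, th1, rel_t):
    u = 0.0 if t1 == t0 else np.clip((rel_t - t0) / (t1 - t0), 0.0, 1.0)
    if kind in ("ramp", "relax"):
        w = 0.5 * (1.0 - np.cos(np.pi * u))
    elif kind == "hold":
        w = 0.0
    else:  # wave: linear decay while the wave propagates
        w = u
    return th0 + (th1 - th0) * w


def program_theta_series(
    program: BehaviorProgram, rate_hz: float, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Nominal bend-angle series theta(t) implied by the program schedule.

    This is the event-level counterpart of the rendered ground truth: zero
    during runs, the scheduled ramps/holds/decays during maneuvers.
    """
    n = int(round(program.duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    theta = np.zeros(n)
    for turn in program.turns:
        phases = maneuver_schedule(turn, config)
        sel = (t >= turn.onset_s) & (t <= turn.end_s)
        rel = t[sel] - turn.onset_s
        vals = np.zeros_like(rel)
        for kind, t0, t1, th0, th1, _ in phases:
            m = (rel >= t0) & (rel < t1)
            if not m.any():
                continue
            vals[m] = _theta_in_phase(kind, t0, t1, th0, th1, rel[m])
        theta[sel] = vals
    return t, theta


# ---------------------------------------------------------------------------
# sampling

def sample_behavior(
    config: SimulationConfig, temperature: TemperatureTrace, seed: int
) -> BehaviorProgram:
    """Draw a behavior program from the configured navigation statistics.

    Turn onsets: Poisson with rate ``turn_rate_warming_per_min`` while
    dT/dt > 0 and ``turn_rate_cooling_per_min`` while dT/dt < 0 (thinning).
    An onset arriving during a maneuver is deferred to its end plus a short
    straightened gap, so the count per unit total time is preserved; onsets
    are then snapped to the next peristalsis-cycle boundary so head sweeping
    starts only after the running wave completes.
    """
    rng = np.random.default_rng(seed)
    duration = temperature.duration_s
    dtdt = temperature.derivative()
    t_trace = temperature.time_s

    def dtdt_at(t: float) -> float:
        return float(np.interp(t, t_trace, dtdt))

    rate_w = config.turn_rate_warming_per_min / 60.0
    rate_c = config.turn_rate_cooling_per_min / 60.0
    rate_max = max(rate_w, rate_c)
    if rate_max <= 0:
        return BehaviorProgram(duration_s=duration, turns=[])

    loc_w = truncated_normal_location(
        config.sweep_mean_warming_deg, config.sweep_sd_deg,
        config.min_sweep_deg, config.max_sweep_deg)
    loc_c = truncated_normal_location(
        config.sweep_mean_cooling_deg, config.sweep_sd_deg,
        config.min_sweep_deg, config.max_sweep_deg)

    base_logit = math.log(config.reject_base / (1.0 - config.reject_base))
    P = config.wave_period_s

    turns: list[TurnPlan] = []
    busy_until = 0.0
    run_start = 0.0
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_max)
        if t >= duration:
            break
        local = rate_w if dtdt_at(t) > 0 else rate_c
        if rng.random() >= local / rate_max:
            continue
        onset = max(t, busy_until)
        k = math.ceil(max(0.0, onset - run_start) / P - 1e-9)
        onset = run_start + k * P
        if onset >= duration - 1.0:
            break
        d = dtdt_at(onset)
        phase = "warming" if d > 0 else ("cooling" if d < 0 else "neutral")
        loc = loc_w if d > 0 else loc_c
        sweeps: list[SweepPlan] = []
        direction = int(rng.choice([-1, 1]))
        while True:
            amp = _sample_amplitude(rng, loc, config)
            n_prev = len(sweeps)
            logit = base_logit + config.reject_slope_per_degC_s * (-dtdt_at(onset))
            p_reject = 1.0 / (1.0 + math.exp(-logit))
            accepted = (rng.random() >= p_reject) or (n_prev + 1 >= config.max_sweeps_per_turn)
            sweeps.append(SweepPlan(direction=direction, amplitude_deg=amp, accepted=accepted))
            if accepted:
                break
            direction = -direction if rng.random() < 0.8 else direction
        turn = _build_turn(onset, sweeps, phase, config)
        if turn.end_s > duration:
            break
        turns.append(turn)
        busy_until = turn.end_s + 1.5
        run_start = turn.end_s
    return BehaviorProgram(duration_s=duration, turns=turns)
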