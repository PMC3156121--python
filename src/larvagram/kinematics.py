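"""Synthesize ground-truthed body kinematics from a behavior program.

The body is a chain of 11 segments.  Each frame is described by per-segment
centerline lengths (peristalsis pulses contract them) and per-segment
heading turns (the bend profile of a head sweep, a raised cosine across the
pivot segments peaked on A1).  Left/right boundaries are normal offsets of
the subdivided centerline with a sinusoidally tapered half-width, so both
body tips are pointed.

Conventions: world coordinates are millimetres, y-up; leftward bends are
positive heading turns and positive bend angles.  Segment arrays are ordered
head to tail (T1..A8); the bend/pulse coordinate ``x`` runs 0 at the tail
tip to 11 at the head tip (waves travel in +x).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ._geom import bend_angle_from_centerline, polygon_area, resample_polyline
from .behavior import (
    BehaviorProgram,
    bend_half_width,
    maneuver_schedule,
    pivot_center_from_tail,
    _theta_in_phase,
)
from .body import N_SEGMENTS, LarvaBodyModel, default_body
from .config import SimulationConfig

NSUB = 4                      # subdivisions per segment
NPTS = N_SEGMENTS * NSUB + 1  # sub-points head..tail
PHI_MAX = 3.6                 # rad, hard cap on total bend

__all__ = ["GroundTruth", "WaveRecord", "synthesize_kinematics", "Posture"]

_X_SEG = (10 - np.arange(N_SEGMENTS)) + 0.5  # tail-based centre of each segment


def bend_profile(phi_total: float, center: float, half_width: float) -> np.ndarray:
    """Distribute a total signed bend over segments (raised cosine profile).

    Normalization uses the *full* profile mass (evaluated on an unbounded
    virtual grid), not just the on-body part: when the profile slides past
    the tail during straightening, the on-body bend decays naturally as
    segments are carried around the bend, instead of the residual bend
    being re-concentrated on the last tail segments.
    """
    d = np.abs(_X_SEG - center)
    g = np.where(d < half_width, np.cos(np.pi * d / (2 * half_width)) ** 2, 0.0)
    ext = np.arange(-25, 36) + 0.5
    d_ext = np.abs(ext - center)
    g_ext = np.where(d_ext < half_width, np.cos(np.pi * d_ext / (2 * half_width)) ** 2, 0.0)
    s = g_ext.sum()
    if s == 0:
        return np.zeros(N_SEGMENTS)
    return phi_total * g / s


@dataclass
class Posture:
    center: np.ndarray  # (NPTS, 2) head -> tail
    left: np.ndarray
    right: np.ndarray

    def segment_slice(self, i: int) -> slice:
        return slice(i * NSUB, (i + 1) * NSUB + 1)


def _sub_u(body: LarvaBodyModel) -> np.ndarray:
    """Rest arc-length fraction from the head at every sub-point."""
    cum = np.concatenate([[0.0], np.cumsum(np.repeat(body.rest_lengths_mm / NSUB, NSUB))])
    return cum / cum[-1]


def build_posture(
    body: LarvaBodyModel,
    lengths: np.ndarray,
    phis: np.ndarray,
    base_xy: np.ndarray,
    base_heading: float,
    sub_u: np.ndarray | None = None,
) -> Posture:
    """Place the body in the plane from tail position/heading and segment state."""
    pts = np.empty((NPTS, 2))
    pts[-1] = base_xy
    heading = base_heading
    idx = NPTS - 1
    for i in range(N_SEGMENTS - 1, -1, -1):  # walk tail -> head
        dphi = phis[i] / NSUB
        dl = lengths[i] / NSUB
        for _ in range(NSUB):
            heading += 0.5 * dphi
            pts[idx - 1] = pts[idx] + dl * np.array([np.cos(heading), np.sin(heading)])
            heading += 0.5 * dphi
            idx -= 1
    if sub_u is None:
        sub_u = _sub_u(body)
    hw = body.half_width_at(sub_u)
    grad = np.gradient(pts, axis=0)            # points tail-ward (head->tail order)
    tangent = -grad                            # head-ward
    norm = np.linalg.norm(tangent, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tangent /= norm
    left_n = np.column_stack([-tangent[:, 1], tangent[:, 0]])  # animal's left
    left = pts + hw[:, None] * left_n
    right = pts - hw[:, None] * left_n
    return Posture(center=pts, left=left, right=right)


def _centerline_only(body, lengths, phis) -> np.ndarray:
    pts = np.empty((NPTS, 2))
    pts[-1] = 0.0
    heading = 0.0
    idx = NPTS - 1
    for i in range(N_SEGMENTS - 1, -1, -1):
        dphi = phis[i] / NSUB
        dl = lengths[i] / NSUB
        for _ in range(NSUB):
            heading += 0.5 * dphi
            pts[idx - 1] = pts[idx] + dl * np.array([np.cos(heading), np.sin(heading)])
            heading += 0.5 * dphi
            idx -= 1
    return pts


def theta_of_bend(
    phi_total: float, center: float, body: LarvaBodyModel,
    lengths: np.ndarray, config: SimulationConfig,
) -> float:
    """Operational bend angle produced by a given total bend at a given centre."""
    hw = bend_half_width(phi_total, config)
    phis = bend_profile(phi_total, center, hw)
    pts = _centerline_only(body, lengths, phis)
    return bend_angle_from_centerline(resample_polyline(pts, 101))


def solve_phi(
    theta_target_deg: float, center: float, body: LarvaBodyModel,
    lengths: np.ndarray, config: SimulationConfig,
) -> float:
    """Total signed bend (rad) whose operational bend angle equals the target."""
    if abs(theta_target_deg) < 1e-9:
        return 0.0
    sign = 1.0 if theta_target_deg > 0 else -1.0
    target = abs(theta_target_deg)

    def f(phi: float) -> float:
        return theta_of_bend(sign * phi, center, body, lengths, config) * sign - target

    # scan for an upper bracket: theta grows with phi until the operational
    # angle saturates or wraps past 180 deg; cap there if the target is
    # unreachable for this bend centre.
    step = 0.15
    prev_phi, prev_val = 0.0, -target
    phi = step
    while phi <= PHI_MAX + 1e-9:
        val = f(phi)
        if val >= 0.0:
            return sign * brentq(f, prev_phi, phi, xtol=1e-4)
        if val < prev_val:  # past the monotone region (saturation/wrap)
            return sign * prev_phi
        prev_phi, prev_val = phi, val
        phi += step
    return sign * prev_phi


@dataclass
class WaveRecord:
    wave_id: int
    t_start_s: float
    t_end_s: float
    init_segment: int       # head->tail index (10 = A8)
    kind: str               # "run" | "straighten"
    x_start: float          # tail-based start coordinate of the pulse


@dataclass
class GroundTruth:
    """Per-frame generator truth for a rendered simulation."""

    config: SimulationConfig
    body: LarvaBodyModel
    program: BehaviorProgram
    time_s: np.ndarray
    center_mm: np.ndarray        # (n, NPTS, 2)
    left_mm: np.ndarray
    right_mm: np.ndarray
    seg_len_left_mm: np.ndarray  # (n, 11)
    seg_len_right_mm: np.ndarray
    quad_area_mm2: np.ndarray    # (n, 11, 4) order AL, AR, PL, PR
    quad_intensity: np.ndarray   # (n, 11, 4)
    theta_deg: np.ndarray
    wave_id: np.ndarray          # (n,) int, -1 where no wave active
    wave_segment: np.ndarray     # (n,) int head->tail index of pulse, -1 none
    event_label: np.ndarray      # (n,) str: run | sweep | straighten
    maneuver_id: np.ndarray      # (n,) int, -1 outside maneuvers
    waves: list[WaveRecord] = field(default_factory=list)

    QUAD_NAMES = ("AL", "AR", "PL", "PR")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    @property
    def seg_area_mm2(self) -> np.ndarray:
        return self.quad_area_mm2.sum(axis=2)

    def boundary_points(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """Left and right segment-boundary points (12 each, head tip..tail tip)."""
        idx = np.arange(0, NPTS, NSUB)
        return self.left_mm[frame, idx], self.right_mm[frame, idx]

    def maneuver_intervals(self) -> list[tuple[float, float]]:
        return [(t.onset_s, t.end_s) for t in self.program.turns]


def _quadrant_polys(post: Posture, i: int):
    sl = post.segment_slice(i)
    L, R, C = post.left[sl], post.right[sl], post.center[sl]
    m = NSUB // 2
    al = np.vstack([L[: m + 1], C[: m + 1][::-1]])
    pl = np.vstack([L[m:], C[m:][::-1]])
    ar = np.vstack([R[: m + 1], C[: m + 1][::-1]])
    pr = np.vstack([R[m:], C[m:][::-1]])
    return al, ar, pl, pr


def synthesize_kinematics(
    program: BehaviorProgram,
    body: LarvaBodyModel | None = None,
    config: SimulationConfig | None = None,
) -> GroundTruth:
    """Simulate posture frame by frame for the full program duration."""
    config = config or SimulationConfig()
    body = body or default_body(config.body_length_mm, config.max_width_mm)
    rate = config.frame_rate_hz
    dt = 1.0 / rate
    n = int(round(program.duration_s * rate))
    if any(t.end_s > program.duration_s + 1e-9 for t in program.turns):
        raise ValueError("program events extend beyond the simulated duration")

    P = config.wave_period_s
    c0 = pivot_center_from_tail(config)
    amp = config.contraction_amplitude
    pw = config.pulse_half_width_seg
    v_run = config.displacement_per_wave_bl * body.body_length_mm / P
    sub_u = _sub_u(body)
    rest = body.rest_lengths_mm

    # rest quadrant areas for intensity calibration
    rest_post = build_posture(body, rest, np.zeros(N_SEGMENTS), np.zeros(2), 0.0, sub_u)
    rest_qarea = np.empty((N_SEGMENTS, 4))
    for i in range(N_SEGMENTS):
        rest_qarea[i] = [abs(polygon_area(p)) for p in _quadrant_polys(rest_post, i)]

    # precompute per-turn schedules and straightening references
    schedules = [maneuver_schedule(t, config) for t in program.turns]

    time_s = np.arange(n) / rate
    center = np.empty((n, NPTS, 2))
    left = np.empty((n, NPTS, 2))
    right = np.empty((n, NPTS, 2))
    seg_ll = np.empty((n, N_SEGMENTS))
    seg_lr = np.empty((n, N_SEGMENTS))
    qarea = np.empty((n, N_SEGMENTS, 4))
    qint = np.empty((n, N_SEGMENTS, 4))
    theta_arr = np.empty(n)
    wave_id_arr = np.full(n, -1, dtype=int)
    wave_seg_arr = np.full(n, -1, dtype=int)
    label_arr = np.empty(n, dtype=object)
    man_id_arr = np.full(n, -1, dtype=int)
    waves: list[WaveRecord] = []
    wave_index: dict[tuple, int] = {}

    base = np.zeros(2)
    psi0 = 0.0
    psi_head_ref = 0.0
    run_start = 0.0
    phi_peak_cache: dict[int, float] = {}
    turn_ptr = 0
    turns = program.turns

    def register_wave(key, t_start, t_end, x_start, kind) -> int:
        if key not in wave_index:
            init_seg = 10 - int(min(10, np.floor(x_start + 1e-9)))
            wave_index[key] = len(waves)
            waves.append(WaveRecord(
                wave_id=len(waves), t_start_s=t_start, t_end_s=t_end,
                init_segment=init_seg, kind=kind, x_start=x_start))
        return wave_index[key]

    for f in range(n):
        t = time_s[f]
        while turn_ptr < len(turns) and t >= turns[turn_ptr].end_s - 1e-12:
            run_start = turns[turn_ptr].end_s
            turn_ptr += 1
        in_turn = turn_ptr < len(turns) and turns[turn_ptr].onset_s - 1e-12 <= t
        pulse_x: float | None = None
        pulse_floor = 0.0
        theta_target = 0.0
        c_now = c0
        label = "run"

        if not in_turn:
            rel = t - run_start
            w = int(np.floor(rel / P + 1e-9))
            frac = rel / P - w
            pulse_x = frac * 11.0
            wid = register_wave(("run", run_start, w),
                                run_start + w * P, run_start + (w + 1) * P, 0.0, "run")
            wave_id_arr[f] = wid
            base = base + v_run * dt * np.array([np.cos(psi0), np.sin(psi0)])
        else:
            turn = turns[turn_ptr]
            man_id_arr[f] = turn_ptr
            rel = t - turn.onset_s
            label = "sweep"
            relax_w = 0.0
            for pi, (kind, t0, t1, th0, th1, extra) in enumerate(schedules[turn_ptr]):
                if rel < t1 or pi == len(schedules[turn_ptr]) - 1:
                    theta_target = float(_theta_in_phase(kind, t0, t1, th0, th1, rel))
                    if kind == "wave":
                        label = "straighten"
                        c_from, c_to, s_start = extra
                        u = (rel - t0) / (t1 - t0)
                        c_now = c_from + (c_to - c_from) * u
                        pulse_x = s_start + (11.0 - s_start) * u
                        pulse_floor = s_start
                        wid = register_wave(("turn", turn_ptr, pi),
                                            turn.onset_s + t0, turn.onset_s + t1,
                                            s_start, "straighten")
                        wave_id_arr[f] = wid
                    elif kind == "relax":
                        label = "straighten"
                        c_now = extra[0]
                        u = np.clip((rel - t0) / (t1 - t0), 0.0, 1.0)
                        relax_w = 0.5 * (1.0 - np.cos(np.pi * u))
                    break

        # segment lengths from the travelling contraction pulse
        lengths = rest.copy()
        if pulse_x is not None:
            d = np.abs(_X_SEG - pulse_x)
            act = np.where(d < pw, np.cos(np.pi * d / (2 * pw)) ** 2, 0.0)
            # a wave initiated within the bend does not actuate segments
            # posterior of its initiation site
            act[_X_SEG < pulse_floor - 0.5] = 0.0
            lengths = rest * (1.0 - amp * act)
            seg_at = 10 - int(min(10, np.floor(pulse_x)))
            wave_seg_arr[f] = seg_at

        # bend state: sweeps are driven to the scheduled operational angle;
        # straightening holds the bend amplitude fixed while the profile
        # slides off the tail (segments carried around the bend).
        if not in_turn:
            phi = 0.0
        elif label == "sweep":
            phi = (solve_phi(theta_target, c_now, body, lengths, config)
                   if theta_target != 0.0 else 0.0)
        else:
            if turn_ptr not in phi_peak_cache:
                acc = turns[turn_ptr].accepted_sweep
                phi_peak_cache[turn_ptr] = solve_phi(
                    acc.direction * acc.amplitude_deg, c0, body, rest, config)
            phi = phi_peak_cache[turn_ptr] * (1.0 - relax_w)

        hw = bend_half_width(phi, config)
        phis = bend_profile(phi, c_now, hw)
        if in_turn and label == "sweep":
            # heading reference: head direction attained at the accepted peak
            psi_head_ref = psi0 + phis.sum()
        elif in_turn:
            psi0 = psi_head_ref - phis.sum()
        post = build_posture(body, lengths, phis, base, psi0, sub_u)

        center[f], left[f], right[f] = post.center, post.left, post.right
        for i in range(N_SEGMENTS):
            sl = post.segment_slice(i)
            seg_ll[f, i] = np.linalg.norm(np.diff(post.left[sl], axis=0), axis=1).sum()
            seg_lr[f, i] = np.linalg.norm(np.diff(post.right[sl], axis=0), axis=1).sum()
            for q, poly in enumerate(_quadrant_polys(post, i)):
                a = abs(polygon_area(poly))
                qarea[f, i, q] = a
                qint[f, i, q] = config.calibration * rest_qarea[i, q] / max(a, 1e-12)
        theta_arr[f] = bend_angle_from_centerline(resample_polyline(post.center, 101))
        label_arr[f] = label

    return GroundTruth(
        config=config, body=body, program=program, time_s=time_s,
        center_mm=center, left_mm=left, right_mm=right,
        seg_len_left_mm=seg_ll, seg_len_right_mm=seg_lr,
        quad_area_mm2=qarea, quad_intensity=qint,
        theta_deg=theta_arr, wave_id=wave_id_arr, wave_segment=wave_seg_arr,
        event_label=label_arr, maneuver_id=man_id_arr, waves=waves,
    )
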