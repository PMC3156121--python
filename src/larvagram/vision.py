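"""Machine-vision stage: outline, head/tail, centerline, bend angle, sweeps.

Processing per frame mirrors the semi-automated tracker this package
emulates: threshold -> erosion/dilation -> largest boundary -> Gaussian
outline smoothing (sd 0.5% of boundary length) -> boundary curvature over a
sliding window (20% of boundary length) -> head/tail as the two strongest
curvature maxima, disambiguated by proximity to the previous frame ->
centerline as midpoints of corresponding left/right boundary points ->
operational bend angle theta -> head-sweep flagging at |theta| >= 40 deg
with hysteresis release.

Image arrays are indexed (row, col) with y down; points are returned as
(x, y) pixel coordinates.  Angles are computed after flipping to a y-up
frame so that leftward sweeps are positive.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as cc_label
from skimage.morphology import dilation, disk, erosion

from ._geom import (
    bend_angle_from_centerline,
    circular_smooth,
    cum_arc_length,
    polygon_area,
    resample_closed,
    resample_polyline,
)
from .config import VisionConfig

__all__ = [
    "BodyOutline",
    "Centerline",
    "HeadSweepEvent",
    "segment_body",
    "extract_outline",
    "outline_curvature",
    "locate_head_tail",
    "compute_centerline",
    "bend_angle",
    "detect_head_sweeps",
    "track_stack",
    "TrackResult",
]


class NoLarvaError(RuntimeError):
    """No foreground component found in the frame."""


class DegenerateShapeError(RuntimeError):
    """Shape analysis failed (too small, too few curvature maxima, ...)."""


@dataclass
class BodyOutline:
    """Closed, smoothed body outline with optional head/tail vertex indices.

    ``vertices`` are (x, y) pixel coordinates ordered counter-clockwise in a
    y-up sense (clockwise on screen), without a repeated endpoint.
    ``raw_vertices``, when present, is the same-length resampling of the
    contour *before* Gaussian smoothing; it shares vertex indices with
    ``vertices`` and preserves the exact tip positions that smoothing
    recedes, so tip localization uses it.
    """

    vertices: np.ndarray
    frame_id: int = 0
    head_index: int | None = None
    tail_index: int | None = None
    raw_vertices: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.vertices)

    def perimeter(self) -> float:
        closed = np.vstack([self.vertices, self.vertices[:1]])
        return float(cum_arc_length(closed)[-1])

    def tip_point(self, index: int) -> np.ndarray:
        """Best-available position of a tip vertex (raw contour if kept)."""
        src = self.raw_vertices if self.raw_vertices is not None else self.vertices
        return src[index]


@dataclass
class Centerline:
    """Midline points ordered head to tail, (x, y) pixels."""

    points: np.ndarray

    @property
    def head(self) -> np.ndarray:
        return self.points[0]

    @property
    def tail(self) -> np.ndarray:
        return self.points[-1]

    def quarter_point(self) -> np.ndarray:
        """Point 1/4 of the arc length from the tail."""
        return self._at_fraction_from_tail(0.25)

    def midpoint(self) -> np.ndarray:
        return self._at_fraction_from_tail(0.5)

    def three_quarter_point(self) -> np.ndarray:
        return self._at_fraction_from_tail(0.75)

    def _at_fraction_from_tail(self, frac: float) -> np.ndarray:
        s = cum_arc_length(self.points)
        target = (1.0 - frac) * s[-1]
        return np.array([
            np.interp(target, s, self.points[:, 0]),
            np.interp(target, s, self.points[:, 1]),
        ])


@dataclass
class HeadSweepEvent:
    onset_frame: int
    offset_frame: int
    direction: str          # "left" | "right"
    peak_deg: float         # peak |theta|
    peak_frame: int

    @property
    def size_class(self) -> str:
        return "large" if self.peak_deg > 90.0 else "small"


# ---------------------------------------------------------------------------
# per-frame operations

def segment_body(frame: np.ndarray, config: VisionConfig) -> np.ndarray:
    """Binary body mask: threshold then one erosion and one dilation."""
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if config.threshold_method == "otsu":
        if frame.max() == frame.min():
            raise NoLarvaError("flat image: no foreground")
        thr = threshold_otsu(frame)
    else:
        thr = config.fixed_threshold
    mask = frame > thr
    if config.morph_radius_px > 0:
        footprint = disk(config.morph_radius_px)
        mask = dilation(erosion(mask, footprint), footprint)
    if not mask.any():
        raise NoLarvaError("no foreground pixels after morphology")
    return mask


def extract_outline(mask: np.ndarray, config: VisionConfig, frame_id: int = 0) -> BodyOutline:
    """Boundary of the largest component, resampled and Gaussian-smoothed."""
    labels = cc_label(mask)
    if labels.max() == 0:
        raise NoLarvaError("mask has no components")
    sizes = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < config.min_component_area_px:
        raise DegenerateShapeError(
            f"largest component is {sizes[biggest - 1]} px^2, below "
            f"{config.min_component_area_px}")
    component = labels == biggest
    contours = find_contours(component.astype(float), 0.5)
    contour = max(contours, key=len)          # (row, col)
    xy = np.column_stack([contour[:, 1], contour[:, 0]])
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    xy = resample_closed(xy, config.outline_points)
    # orient counter-clockwise in the y-up sense (positive shoelace area on -y)
    yup = np.column_stack([xy[:, 0], -xy[:, 1]])
    if polygon_area(yup) < 0:
        xy = xy[::-1]
    sigma = config.boundary_smooth_frac * len(xy)
    smoothed = circular_smooth(xy, sigma)
    return BodyOutline(vertices=smoothed, frame_id=frame_id, raw_vertices=xy)


def outline_curvature(outline: BodyOutline, window_frac: float | None = None,
                      config: VisionConfig | None = None) -> np.ndarray:
    """Signed curvature per vertex from tangent-angle turning over a window.

    Convex protrusions (like the body tips) are positive.  The window spans
    ``window_frac`` of the total boundary length, centred on each vertex.
    """
    if window_frac is None:
        window_frac = (config or VisionConfig()).curvature_window_frac
    n = outline.n
    if n < 20:
        raise DegenerateShapeError("outline has too few vertices for curvature")
    if window_frac >= 0.5:
        raise ValueError("curvature window must be smaller than half the perimeter")
    v = outline.vertices
    yup = np.column_stack([v[:, 0], -v[:, 1]])
    d = np.roll(yup, -1, axis=0) - yup
    psi = np.arctan2(d[:, 1], d[:, 0])
    dpsi = np.diff(psi)
    dpsi = (dpsi + np.pi) % (2 * np.pi) - np.pi
    psi_unwrapped = np.concatenate([[psi[0]], psi[0] + np.cumsum(dpsi)])
    # circular extension: one full turn (+2*pi for CCW) per wrap
    total_turn = 2.0 * np.pi
    h = max(1, int(round(0.5 * window_frac * n)))
    ext = np.concatenate([
        psi_unwrapped[-h:] - total_turn, psi_unwrapped, psi_unwrapped[:h] + total_turn,
    ])
    ds = outline.perimeter() / n
    idx = np.arange(n) + h
    return (ext[idx + h] - ext[idx - h]) / (2 * h * ds)


def _circular_local_maxima(values: np.ndarray) -> np.ndarray:
    left = np.roll(values, 1)
    right = np.roll(values, -1)
    return np.flatnonzero((values > left) & (values >= right))


def _refine_tip(outline: BodyOutline, seed_index: int, config: VisionConfig,
                fine: np.ndarray | None = None, search: int | None = None) -> int:
    """Pin the tip apex near a seed vertex.

    The wide curvature window identifies each tip only as a broad plateau
    (the window integrates the whole tip's turning), so localization takes
    two steps: (1) the fine-scale curvature maximum within a small search
    span of the seed picks out the tip cap (a cap of radius ~w/4 turns much
    faster than the outer side of even a tight body bend); (2) the apex is
    the cap-top centroid of the unsmoothed contour — the mean of the points
    within ~1.5 px of the extremal projection along the outward direction —
    which is robust to the pixelated cap's orientation.
    """
    n = outline.n
    raw = outline.raw_vertices if outline.raw_vertices is not None else outline.vertices
    if fine is None:
        fine = outline_curvature(outline, config.tip_curvature_frac)
    if search is None:
        search = max(5, int(round(0.25 * config.curvature_window_frac * n)))
    window = np.arange(seed_index - search, seed_index + search + 1) % n
    idx = int(window[np.argmax(fine[window])])
    cap = np.arange(idx - 10, idx + 11) % n
    pts = raw[cap]
    center = pts.mean(axis=0)
    d = raw[idx] - center
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        return idx
    proj = (pts - center) @ (d / norm)
    sel = proj >= proj.max() - 1.5
    apex = pts[sel].mean(axis=0)
    return int(cap[np.argmin(np.linalg.norm(pts - apex, axis=1))])


def locate_head_tail(
    outline: BodyOutline,
    curvature: np.ndarray,
    prior: tuple[np.ndarray, np.ndarray],
    config: VisionConfig | None = None,
) -> tuple[int, int]:
    """Head and tail vertex indices from curvature maxima and the prior.

    Local maxima of the wide-window curvature are the candidate tips; with
    a strongly bent body the outer side of the bend also produces a maximum
    comparable to the tips, so the head/tail pair is the candidate pair
    (separated by at least ``min_extremum_separation_frac`` of the
    perimeter) minimizing the summed distance to the prior (previous-frame,
    or user-supplied) head/tail positions, as in frame-to-frame tip
    tracking.  Each chosen candidate is refined to the geometric apex of
    the unsmoothed contour.
    """
    config = config or VisionConfig()
    n = outline.n
    peaks = _circular_local_maxima(curvature)
    if len(peaks) < 2:
        raise DegenerateShapeError("fewer than two curvature maxima")
    fine = outline_curvature(outline, config.tip_curvature_frac)
    order = peaks[np.argsort(curvature[peaks])[::-1]][:8]
    refined = [_refine_tip(outline, int(p), config, fine) for p in order]
    head_prior, tail_prior = np.asarray(prior[0]), np.asarray(prior[1])
    # prior-anchored candidates: a tip adjacent to a tight body bend can
    # merge with the bend's curvature plateau; seed a candidate from the
    # contour point nearest each prior and refine locally.
    raw = outline.raw_vertices if outline.raw_vertices is not None else outline.vertices
    for p in (head_prior, tail_prior):
        seed = int(np.argmin(np.linalg.norm(raw - p, axis=1)))
        refined.append(_refine_tip(outline, seed, config, fine, search=18))
    refined = list(dict.fromkeys(refined))
    pts = [outline.tip_point(i) for i in refined]
    min_sep = config.min_extremum_separation_frac * n
    best: tuple[int, int] | None = None
    best_cost = np.inf
    for i, (ia, pa) in enumerate(zip(refined, pts)):
        for j, (ib, pb) in enumerate(zip(refined, pts)):
            if i == j:
                continue
            sep = abs(ia - ib)
            sep = min(sep, n - sep)
            if sep < min_sep:
                continue
            cost = float(np.linalg.norm(pa - head_prior) + np.linalg.norm(pb - tail_prior))
            if cost < best_cost:
                best_cost = cost
                best = (ia, ib)
    if best is None:
        raise DegenerateShapeError("no pair of separated curvature maxima")
    return best


def compute_centerline(outline: BodyOutline, config: VisionConfig | None = None) -> Centerline:
    """Midpoints of corresponding points on the two head-to-tail boundary arcs."""
    config = config or VisionConfig()
    if outline.head_index is None or outline.tail_index is None:
        raise ValueError("outline head/tail indices are not set")
    h, t = outline.head_index, outline.tail_index
    v = outline.vertices
    if h == t:
        raise DegenerateShapeError("head and tail indices coincide")
    if h < t:
        arc_a = v[h:t + 1]
        arc_b = np.vstack([v[t:], v[:h + 1]])[::-1]
    else:
        arc_a = np.vstack([v[h:], v[:t + 1]])
        arc_b = v[t:h + 1][::-1]
    len_a = cum_arc_length(arc_a)[-1]
    len_b = cum_arc_length(arc_b)[-1]
    if min(len_a, len_b) <= 0 or max(len_a, len_b) / max(min(len_a, len_b), 1e-9) > 3.0:
        raise DegenerateShapeError(
            "boundary arcs grossly unequal: likely self-occluding posture")
    k = config.centerline_points
    ra = resample_polyline(arc_a, k)
    rb = resample_polyline(arc_b, k)
    return Centerline(points=0.5 * (ra + rb))


def bend_angle(centerline: Centerline) -> float:
    """Signed operational bend angle (deg), leftward positive.

    Pixel y grows downward; the centerline is flipped to a y-up frame before
    the angle computation so the sign convention matches the animal's left.
    """
    pts = centerline.points
    yup = np.column_stack([pts[:, 0], -pts[:, 1]])
    return bend_angle_from_centerline(yup)


def detect_head_sweeps(
    theta_deg: np.ndarray,
    config: VisionConfig | None = None,
    valid: np.ndarray | None = None,
) -> list[HeadSweepEvent]:
    """Flag head sweeps with onset/release hysteresis on |theta|.

    Onset at the first frame with |theta| >= sweep threshold; the event ends
    when |theta| drops below the release threshold or the sign flips (a new
    sweep in the other direction starts immediately if still above
    threshold).  Events are classed large/small by the 90 deg rule.
    """
    config = config or VisionConfig()
    theta = np.asarray(theta_deg, dtype=float)
    if len(theta) < 2:
        raise ValueError("bend-angle series must cover at least 2 frames")
    if valid is None:
        valid = np.isfinite(theta)
    events: list[HeadSweepEvent] = []
    in_event = False
    onset = 0
    sign = 0
    peak = 0.0

    def close(end_frame: int) -> None:
        nonlocal in_event
        # peak frame = first frame near the peak: the bend angle plateaus
        # near its maximum while straightening waves already shift the
        # asymmetric region, so downstream region measurements want the
        # earliest full-amplitude frame.
        span = np.abs(theta[onset:end_frame + 1])
        first = onset + int(np.argmax(span >= peak - max(2.0, 0.1 * peak)))
        events.append(HeadSweepEvent(
            onset_frame=onset, offset_frame=end_frame,
            direction="left" if sign > 0 else "right",
            peak_deg=peak, peak_frame=first))
        in_event = False

    for f, th in enumerate(theta):
        if not valid[f]:
            if in_event:
                close(f)
            continue
        mag, s = abs(th), int(np.sign(th))
        if not in_event:
            if mag >= config.sweep_threshold_deg:
                in_event = True
                onset, sign, peak = f, s, mag
        else:
            if s != 0 and s != sign:
                close(f - 1)
                if mag >= config.sweep_threshold_deg:
                    in_event = True
                    onset, sign, peak = f, s, mag
            elif mag < config.sweep_release_deg:
                close(f)
            elif mag > peak:
                peak = mag
    if in_event:
        close(len(theta) - 1)
    return events


# ---------------------------------------------------------------------------
# stack driver

@dataclass
class TrackResult:
    """Per-frame tracking output for an image stack."""

    outlines: list[BodyOutline]
    centerlines: list[Centerline]
    theta_deg: np.ndarray
    head_px: np.ndarray      # (n, 2)
    tail_px: np.ndarray
    valid: np.ndarray        # bool per frame

    def events(self, config: VisionConfig | None = None) -> list[HeadSweepEvent]:
        return detect_head_sweeps(self.theta_deg, config, self.valid)


def track_stack(
    stack: np.ndarray,
    config: VisionConfig | None = None,
    prior: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrackResult:
    """Run the full vision chain over a stack, chaining head/tail priors.

    ``prior`` seeds the first frame's head/tail disambiguation (ground truth
    or user input); later frames use the previous frame's positions.
    """
    config = config or VisionConfig()
    if prior is None:
        raise ValueError("first-frame head/tail prior is required")
    n = len(stack)
    outlines: list[BodyOutline] = []
    centerlines: list[Centerline] = []
    theta = np.full(n, np.nan)
    head = np.full((n, 2), np.nan)
    tail = np.full((n, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    cur_prior = (np.asarray(prior[0], dtype=float), np.asarray(prior[1], dtype=float))
    prev_valid: list[int] = []
    for f in range(n):
        # constant-velocity prediction of the tip positions: during sweep
        # ramps the head moves several px/frame, so the raw previous-frame
        # position lags the true tip
        if len(prev_valid) >= 2:
            f1, f2 = prev_valid[-1], prev_valid[-2]
            cur_prior = (2 * head[f1] - head[f2], 2 * tail[f1] - tail[f2])
        elif len(prev_valid) == 1:
            f1 = prev_valid[-1]
            cur_prior = (head[f1], tail[f1])
        try:
            mask = segment_body(stack[f], config)
            outline = extract_outline(mask, config, frame_id=f)
            curv = outline_curvature(outline, config.curvature_window_frac)
            h_idx, t_idx = locate_head_tail(outline, curv, cur_prior, config)
            outline.head_index, outline.tail_index = h_idx, t_idx
            cl = compute_centerline(outline, config)
        except (NoLarvaError, DegenerateShapeError):
            outlines.append(BodyOutline(vertices=np.empty((0, 2)), frame_id=f))
            centerlines.append(Centerline(points=np.empty((0, 2))))
            continue
        outlines.append(outline)
        centerlines.append(cl)
        head[f] = outline.tip_point(h_idx)
        tail[f] = outline.tip_point(t_idx)
        theta[f] = bend_angle(cl)
        valid[f] = True
        prev_valid.append(f)
    return TrackResult(
        outlines=outlines, centerlines=centerlines, theta_deg=theta,
        head_px=head, tail_px=tail, valid=valid,
    )
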