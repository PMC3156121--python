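"""Small planar-geometry helpers shared by the generator and the vision code.

All functions operate on ``(n, 2)`` float arrays of ``(x, y)`` points in a
y-up coordinate frame unless stated otherwise.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "arc_length",
    "cum_arc_length",
    "resample_polyline",
    "resample_closed",
    "circular_smooth",
    "signed_angle_deg",
    "point_at_fraction",
    "polygon_area",
    "bend_angle_from_centerline",
]


def cum_arc_length(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length along an open polyline, starting at 0."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def arc_length(points: np.ndarray) -> float:
    return float(cum_arc_length(points)[-1])


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` points at equal arc-length spacing."""
    s = cum_arc_length(points)
    total = s[-1]
    if total <= 0:
        return np.repeat(points[:1], n, axis=0)
    t = np.linspace(0.0, total, n)
    x = np.interp(t, s, points[:, 0])
    y = np.interp(t, s, points[:, 1])
    return np.column_stack([x, y])


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon (no repeated endpoint) to ``n`` vertices."""
    closed = np.vstack([points, points[:1]])
    s = cum_arc_length(closed)
    total = s[-1]
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def circular_smooth(points: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth polygon vertices with circular (wrap) boundary."""
    if sigma <= 0:
        return points.copy()
    return gaussian_filter1d(points, sigma=sigma, axis=0, mode="wrap")


def signed_angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Signed angle from v1 to v2 in degrees, counter-clockwise positive."""
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = v1[0] * v2[0] + v1[1] * v2[1]
    if cross == 0.0 and dot == 0.0:
        raise ValueError("degenerate (zero-length) vector in angle computation")
    return float(np.degrees(np.arctan2(cross, dot)))


def point_at_fraction(points: np.ndarray, frac: float) -> np.ndarray:
    """Point at a given arc-length fraction (0 = first point, 1 = last)."""
    s = cum_arc_length(points)
    target = frac * s[-1]
    x = np.interp(target, s, points[:, 0])
    y = np.interp(target, s, points[:, 1])
    return np.array([x, y])


def polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area (positive for counter-clockwise in y-up)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def bend_angle_from_centerline(points: np.ndarray) -> float:
    """Operational body-bend angle of a head-to-tail centerline, degrees.

    The centerline is ordered head to tail in a y-up frame.  Fractional
    positions are measured from the tail: the bend angle is the signed angle
    from the vector (tail -> midpoint) to the vector (3/4-point -> head),
    with leftward bends positive.  The 3/4-point lies anterior (one quarter
    of the body length behind the head).
    """
    if len(points) < 4:
        raise ValueError("centerline too short for bend-angle computation")
    head = points[0]
    tail = points[-1]
    mid = point_at_fraction(points, 0.5)          # half-way from head = from tail
    q3 = point_at_fraction(points, 0.25)          # 3/4 of the way from the tail
    v1 = mid - tail
    v2 = head - q3
    if np.linalg.norm(v1) == 0 or np.linalg.norm(v2) == 0:
        raise ValueError("degenerate centerline: coincident reference points")
    return signed_angle_deg(v1, v2)
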