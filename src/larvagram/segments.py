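"""Per-segment contraction metrics: boundary lengths, quadrant intensities,
fractional changes, the ln(L_right/L_left) asymmetry index, and kymographs.

Segment boundaries are annotated by 20 points (+1..+10 left, -1..-10 right,
head 0 and tail +/-11 from the outline itself).  All metrics are measured on
the smoothed outline polygon: the "length of a segment boundary" is the
outline arc length of each segment's side between its bounding points,
which is the quantity entering the asymmetry index.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from ._geom import cum_arc_length
from .body import N_SEGMENTS, SEGMENT_NAMES
from .vision import BodyOutline, TrackResult

__all__ = [
    "SegmentAnnotation",
    "SegmentMetrics",
    "Kymograph",
    "resolve_annotation",
    "boundary_lengths",
    "quadrant_intensities",
    "fractional_change",
    "asymmetry_index",
    "build_kymograph",
    "measure_stack",
    "length_kymograph",
    "contraction_kymograph",
    "asymmetry_kymograph",
    "choose_reference_frame",
    "plot_kymograph",
]

QUAD_NAMES = ("AL", "AR", "PL", "PR")


class MalformedAnnotationError(ValueError):
    """Annotation points missing, duplicated, or out of order."""


class MisregistrationError(ValueError):
    """Annotation points too far from the outline."""


class DegenerateSegmentError(RuntimeError):
    """A segment quadrant encloses no body pixels."""


# ---------------------------------------------------------------------------
# annotation resolution

def _project_to_polygon(outline: BodyOutline, point: np.ndarray) -> tuple[float, float]:
    """Continuous vertex coordinate u in [0, n) of the nearest polygon point."""
    v = outline.vertices
    n = len(v)
    a = v
    b = np.roll(v, -1, axis=0)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1e-12
    t = np.clip(np.einsum("ij,ij->i", point - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(proj - point, axis=1)
    k = int(np.argmin(d))
    return (k + float(t[k])) % n, float(d[k])


@dataclass
class SegmentAnnotation:
    """Per-frame annotation resolved onto an outline.

    ``left_u``/``right_u`` hold the continuous outline coordinates of
    boundaries 0 (head tip) .. 11 (tail tip) along each side; ``left_dir``
    is +1 if the left side runs in the direction of increasing vertex index.
    """

    outline: BodyOutline
    left_u: np.ndarray
    right_u: np.ndarray
    left_dir: int
    max_snap_px: float
    frame_id: int = 0
    _cum: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        closed = np.vstack([self.outline.vertices, self.outline.vertices[:1]])
        self._cum = cum_arc_length(closed)

    def _s(self, u: float) -> float:
        return float(np.interp(u, np.arange(len(self._cum)), self._cum))

    def arc_between(self, u0: float, u1: float, direction: int) -> float:
        """Arc length from u0 to u1 walking in the given index direction."""
        per = self._cum[-1]
        if direction > 0:
            d = self._s(u1 % self.outline.n) - self._s(u0 % self.outline.n)
        else:
            d = self._s(u0 % self.outline.n) - self._s(u1 % self.outline.n)
        return d % per

    def side_point(self, u: float) -> np.ndarray:
        v = self.outline.vertices
        n = len(v)
        k = int(np.floor(u)) % n
        t = u - np.floor(u)
        return (1 - t) * v[k] + t * v[(k + 1) % n]

    def arc_points(self, u0: float, u1: float, direction: int, m: int = 9) -> np.ndarray:
        """m points sampled along the outline between two side coordinates."""
        n = self.outline.n
        if direction > 0:
            span = (u1 - u0) % n
            us = (u0 + np.linspace(0.0, span, m)) % n
        else:
            span = (u0 - u1) % n
            us = (u0 - np.linspace(0.0, span, m)) % n
        return np.array([self.side_point(u) for u in us])


def resolve_annotation(
    points: pd.DataFrame,
    outline: BodyOutline,
    snap_tolerance_px: float = 5.0,
) -> SegmentAnnotation:
    """Snap 20 annotated boundary points onto an outline with head/tail set.

    ``points`` must carry columns ``point_id`` (+1..+10 left, -1..-10 right),
    ``x_px``, ``y_px`` for one frame.  Points are projected to the nearest
    point on the outline polygon; ordering along each side is validated.
    """
    if outline.head_index is None or outline.tail_index is None:
        raise ValueError("outline must have head/tail indices set")
    ids = points["point_id"].to_numpy()
    side_ids = ids[(ids != 0) & (np.abs(ids) != 11)]
    expected = set(range(1, 11)) | set(range(-10, 0))
    if sorted(side_ids.tolist()) != sorted(expected):
        raise MalformedAnnotationError(
            "annotation must contain each of +-1..+-10 exactly once")

    n = outline.n
    u_head = float(outline.head_index)
    u_tail = float(outline.tail_index)
    coords: dict[int, float] = {}
    max_d = 0.0
    for _, row in points.iterrows():
        pid = int(row["point_id"])
        if pid == 0 or abs(pid) == 11:
            continue
        u, d = _project_to_polygon(outline, np.array([row["x_px"], row["y_px"]]))
        max_d = max(max_d, d)
        coords[pid] = u
    if max_d > snap_tolerance_px:
        raise MisregistrationError(
            f"annotation point {max_d:.1f} px from outline (> {snap_tolerance_px})")

    span_fwd = (u_tail - u_head) % n
    tol = 0.02 * n  # tip localization slack near head/tail

    def rel(u: float) -> float:
        return (u - u_head) % n

    left_rel = np.array([rel(coords[j]) for j in range(1, 11)])
    right_rel = np.array([rel(coords[-j]) for j in range(1, 11)])

    def in_fwd(arr: np.ndarray) -> bool:
        return bool(np.all((arr < span_fwd + tol) | (arr > n - tol)))

    def in_bwd(arr: np.ndarray) -> bool:
        return bool(np.all(arr > span_fwd - tol))

    left_fwd, right_fwd = in_fwd(left_rel), in_fwd(right_rel)
    if left_fwd == right_fwd and in_bwd(left_rel) == in_bwd(right_rel):
        raise MalformedAnnotationError("left and right points do not separate into arcs")
    if left_fwd == right_fwd:
        left_fwd = not in_bwd(left_rel)
        right_fwd = not left_fwd
    for arr, fwd in ((left_rel, left_fwd), (right_rel, right_fwd)):
        seq = arr if fwd else (n - arr) % n
        # tolerate sub-tolerance inversions (projection jitter where a
        # contracted side folds); genuinely shuffled points still fail
        if np.any(np.diff(seq) <= -tol):
            raise MalformedAnnotationError("annotation points out of order along the side")

    left_dir = 1 if left_fwd else -1

    def side_coords(arr: np.ndarray, fwd: bool) -> np.ndarray:
        seq = arr if fwd else (n - arr) % n
        seq = np.maximum.accumulate(np.clip(seq, 0.0, span_fwd if fwd else n - span_fwd))
        if fwd:
            return np.concatenate([[u_head], (u_head + seq) % n, [u_tail]])
        return np.concatenate([[u_head], (u_head - seq) % n, [u_tail]])

    left_u = side_coords(left_rel, left_fwd)
    right_u = side_coords(right_rel, right_fwd)
    return SegmentAnnotation(
        outline=outline, left_u=left_u, right_u=right_u,
        left_dir=left_dir, max_snap_px=max_d, frame_id=outline.frame_id,
    )


# ---------------------------------------------------------------------------
# metrics

def boundary_lengths(annotation: SegmentAnnotation) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment left/right boundary arc lengths (px), head to tail order."""
    ll = np.empty(N_SEGMENTS)
    lr = np.empty(N_SEGMENTS)
    for i in range(N_SEGMENTS):
        ll[i] = annotation.arc_between(
            annotation.left_u[i], annotation.left_u[i + 1], annotation.left_dir)
        lr[i] = annotation.arc_between(
            annotation.right_u[i], annotation.right_u[i + 1], -annotation.left_dir)
    return ll, lr


def quadrant_intensities(
    annotation: SegmentAnnotation, frame: np.ndarray, strict: bool = True
) -> np.ndarray:
    """Mean pixel value in each segment quadrant, shape (11, 4) AL/AR/PL/PR.

    Each segment polygon is split into anterior/posterior by the chord
    between the side-arc midpoints and into left/right by the segment's
    local midline (chord midpoints of the anterior and posterior segment
    boundaries and of the mid chord).
    """
    out = np.empty((N_SEGMENTS, 4))
    for i in range(N_SEGMENTS):
        lu0, lu1 = annotation.left_u[i], annotation.left_u[i + 1]
        ru0, ru1 = annotation.right_u[i], annotation.right_u[i + 1]
        ld, rd = annotation.left_dir, -annotation.left_dir
        larc = annotation.arc_points(lu0, lu1, ld)
        rarc = annotation.arc_points(ru0, ru1, rd)
        m = (len(larc) - 1) // 2
        l_mid, r_mid = larc[m], rarc[m]
        m_ant = 0.5 * (larc[0] + rarc[0])
        m_post = 0.5 * (larc[-1] + rarc[-1])
        center = 0.5 * (l_mid + r_mid)
        quads = {
            "AL": np.vstack([larc[: m + 1], [center, m_ant]]),
            "AR": np.vstack([rarc[: m + 1], [center, m_ant]]),
            "PL": np.vstack([larc[m:], [m_post, center]]),
            "PR": np.vstack([rarc[m:], [m_post, center]]),
        }
        for q, name in enumerate(QUAD_NAMES):
            poly = quads[name]
            rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=frame.shape)
            if len(rr) == 0:
                # sub-pixel quadrant (tip segments under strong bends):
                # sample the pixels under the polygon vertices instead
                rr = np.clip(np.round(poly[:, 1]).astype(int), 0, frame.shape[0] - 1)
                cc = np.clip(np.round(poly[:, 0]).astype(int), 0, frame.shape[1] - 1)
            if len(rr) == 0:
                if not strict:
                    out[i, q] = np.nan
                    continue
                raise DegenerateSegmentError(
                    f"segment {SEGMENT_NAMES[i]} quadrant {name} encloses no pixels")
            vals = frame[rr, cc]
            if not np.any(vals):
                if not strict:
                    out[i, q] = np.nan
                    continue
                raise DegenerateSegmentError(
                    f"segment {SEGMENT_NAMES[i]} quadrant {name} covers background only")
            out[i, q] = float(np.mean(vals))
    return out


def fractional_change(series: np.ndarray, reference_frame: int, axis: int = -1) -> np.ndarray:
    """(x_t - x_ref) / x_ref along the time axis."""
    series = np.asarray(series, dtype=float)
    ref = np.take(series, reference_frame, axis=axis)
    if np.any(ref == 0):
        raise ValueError("zero reference value in fractional change")
    return (series - np.expand_dims(ref, axis=axis)) / np.expand_dims(ref, axis=axis)


def asymmetry_index(l_left: np.ndarray, l_right: np.ndarray) -> np.ndarray:
    """a = ln(L_right / L_left); positive for leftward bends."""
    l_left = np.asarray(l_left, dtype=float)
    l_right = np.asarray(l_right, dtype=float)
    if np.any(l_left <= 0) or np.any(l_right <= 0):
        raise ValueError("boundary lengths must be positive")
    return np.log(l_right / l_left)


# ---------------------------------------------------------------------------
# kymographs

@dataclass
class SegmentMetrics:
    """Per-frame, per-segment measurements over a stack (head->tail rows)."""

    l_left_px: np.ndarray        # (n, 11)
    l_right_px: np.ndarray
    quad_mean: np.ndarray        # (n, 11, 4)
    valid: np.ndarray            # (n,) bool

    @property
    def seg_mean_intensity(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.quad_mean, axis=2)

    @property
    def asymmetry(self) -> np.ndarray:
        """ln(L_R/L_L) per frame/segment; NaN where a side length collapsed
        (fully folded inner side under an extreme bend) or untracked."""
        ll = np.where(self.l_left_px > 0.5, self.l_left_px, np.nan)
        lr = np.where(self.l_right_px > 0.5, self.l_right_px, np.nan)
        with np.errstate(invalid="ignore"):
            return np.log(lr / ll)


@dataclass
class Kymograph:
    """(body coordinate x time) matrix of a contraction metric."""

    values: np.ndarray           # (rows, frames)
    row_labels: list[str]
    metric: str                  # fractional_length | fractional_intensity | asymmetry
    reference_frame: int | None
    frame_rate_hz: float

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.row_labels):
            raise ValueError("row label count does not match matrix rows")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.row_labels)
        df.index.name = "body_coordinate"
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def build_kymograph(
    series: np.ndarray,
    row_labels: list[str],
    metric: str,
    reference_frame: int | None = None,
    frame_rate_hz: float = 8.0,
) -> Kymograph:
    """Assemble a kymograph matrix (rows = body coordinate, columns = frames)."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("kymograph input must be a 2-D (rows x frames) array")
    if series.shape[0] != len(row_labels):
        raise ValueError("ragged kymograph input: row count mismatch")
    return Kymograph(values=series, row_labels=list(row_labels), metric=metric,
                     reference_frame=reference_frame, frame_rate_hz=frame_rate_hz)


def length_kymograph(metrics: SegmentMetrics, reference_frame: int,
                     frame_rate_hz: float = 8.0) -> Kymograph:
    """Fractional boundary-length change, 22 rows: +A8..+T1 then -T1..-A8.

    Row order follows the body coordinate of the study's kymographs: the
    left side from tail (+11) to head (+1), then the right side from head
    (-1) to tail (-11).
    """
    fl = fractional_change(metrics.l_left_px.T, reference_frame)
    fr = fractional_change(metrics.l_right_px.T, reference_frame)
    rows = np.vstack([fl[::-1], fr])
    labels = [f"+{name}" for name in SEGMENT_NAMES[::-1]] + \
             [f"-{name}" for name in SEGMENT_NAMES]
    return build_kymograph(rows, labels, "fractional_length", reference_frame, frame_rate_hz)


def contraction_kymograph(metrics: SegmentMetrics, reference_frame: int,
                          metric: str = "fractional_intensity",
                          frame_rate_hz: float = 8.0) -> Kymograph:
    """Per-segment contraction signal, 11 rows T1..A8 (head at the top)."""
    if metric == "fractional_intensity":
        series = fractional_change(metrics.seg_mean_intensity.T, reference_frame)
    elif metric == "fractional_length":
        mean_len = 0.5 * (metrics.l_left_px + metrics.l_right_px)
        series = fractional_change(mean_len.T, reference_frame)
    else:
        raise ValueError(f"not a contraction metric: {metric!r}")
    return build_kymograph(series, list(SEGMENT_NAMES), metric,
                           reference_frame, frame_rate_hz)


def asymmetry_kymograph(metrics: SegmentMetrics, frame_rate_hz: float = 8.0) -> Kymograph:
    """ln(L_right/L_left) per segment, 11 rows T1..A8."""
    return build_kymograph(metrics.asymmetry.T, list(SEGMENT_NAMES), "asymmetry",
                           None, frame_rate_hz)


def choose_reference_frame(metrics: SegmentMetrics, wave_intervals, frame_rate_hz: float) -> int:
    """Inter-wave frame minimizing the total |fractional length change|.

    A first pass uses frame 0 as reference; after wave detection the
    reference is re-chosen among frames outside all wave intervals and the
    metrics are recomputed against it.
    """
    n = len(metrics.l_left_px)
    in_wave = np.zeros(n, dtype=bool)
    for t0, t1 in wave_intervals:
        f0 = max(0, int(np.floor(t0 * frame_rate_hz)))
        f1 = min(n, int(np.ceil(t1 * frame_rate_hz)) + 1)
        in_wave[f0:f1] = True
    candidates = np.flatnonzero(~in_wave & metrics.valid)
    if len(candidates) == 0:
        candidates = np.flatnonzero(metrics.valid)
    mean_len = 0.5 * (metrics.l_left_px + metrics.l_right_px)
    ref0 = mean_len[candidates[0]]
    total = np.abs((mean_len[candidates] - ref0) / ref0).sum(axis=1)
    return int(candidates[np.argmin(total)])


def measure_stack(
    stack: np.ndarray,
    track: TrackResult,
    annotation: pd.DataFrame,
    snap_tolerance_px: float = 5.0,
) -> SegmentMetrics:
    """Resolve the annotation on every tracked frame and measure all metrics."""
    n = len(stack)
    ll = np.full((n, N_SEGMENTS), np.nan)
    lr = np.full((n, N_SEGMENTS), np.nan)
    quad = np.full((n, N_SEGMENTS, 4), np.nan)
    valid = np.zeros(n, dtype=bool)
    grouped = dict(tuple(annotation.groupby("frame")))
    for f in range(n):
        if not track.valid[f] or f not in grouped:
            continue
        try:
            ann = resolve_annotation(grouped[f], track.outlines[f], snap_tolerance_px)
            ll[f], lr[f] = boundary_lengths(ann)
            quad[f] = quadrant_intensities(ann, stack[f], strict=False)
        except (MalformedAnnotationError, MisregistrationError, DegenerateSegmentError):
            # a frame the annotation cannot be registered on (typically a
            # momentary tip mislocation in an extreme posture) is dropped
            ll[f] = lr[f] = np.nan
            quad[f] = np.nan
            continue
        valid[f] = True
    return SegmentMetrics(l_left_px=ll, l_right_px=lr, quad_mean=quad, valid=valid)


def plot_kymograph(kymo: Kymograph, ax=None, cmap: str = "RdBu_r"):
    """Quick-look kymograph image (body coordinate x time)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    vmax = np.nanmax(np.abs(kymo.values)) or 1.0
    extent = (0, kymo.n_frames / kymo.frame_rate_hz, len(kymo.row_labels), 0)
    im = ax.imshow(kymo.values, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax,
                   extent=extent, interpolation="nearest")
    ax.set_yticks(np.arange(len(kymo.row_labels)) + 0.5)
    ax.set_yticklabels(kymo.row_labels, fontsize=6)
    ax.set_xlabel("time (s)")
    ax.set_title(kymo.metric)
    plt.colorbar(im, ax=ax)
    return ax
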