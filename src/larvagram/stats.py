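"""Navigation statistics: OLS regressions, thermal-phase classification,
turn frequencies, head-sweep sizes, binned initiation/straightening
summaries, forward and thermotaxis speeds, and phase comparisons.

Functions operate on plain arrays so they can be fed either from the video
pipeline (frame-based events) or from event-level simulations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.ndimage import uniform_filter1d

from .config import StatsConfig
from .temperature import TemperatureTrace

__all__ = [
    "RegressionResult",
    "PhaseLabels",
    "BinnedProbability",
    "BinnedMean",
    "regress_intensity_vs_length",
    "classify_phases",
    "turn_frequency",
    "first_sweep_size",
    "initiation_probability_by_angle",
    "straightening_waves_by_angle",
    "forward_speed",
    "thermotaxis_speed",
    "phase_comparison_test",
]

PHASES = ("warming", "cooling", "neutral")


class DegenerateRegressionError(ValueError):
    """Zero variance in the regressor."""


@dataclass
class RegressionResult:
    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    n: int


def regress_intensity_vs_length(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Closed-form simple OLS of y on x.

    Slope standard error uses the usual convention
    SE = sqrt(SSE / (n - 2)) / sqrt(sum((x - mean(x))^2)), which equals
    s_resid / (s_x * sqrt(n - 1)) with sample standard deviations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3 or not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("need at least 3 finite (x, y) pairs")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise DegenerateRegressionError("regressor has zero variance")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
    se = np.sqrt(sse / (n - 2)) / np.sqrt(sxx) if n > 2 else np.nan
    return RegressionResult(slope=slope, slope_se=float(se), intercept=intercept,
                            r_squared=float(r2), n=n)


@dataclass
class PhaseLabels:
    """Thermal phase per trace sample: warming, cooling, or neutral."""

    time_s: np.ndarray
    labels: np.ndarray            # array of str
    dtdt_C_s: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def duration_s(self, phase: str) -> float:
        return float(np.sum(self.labels == phase) * self.dt)

    def phase_at(self, t: float | np.ndarray):
        idx = np.clip(np.round(np.asarray(t) / self.dt).astype(int), 0,
                      len(self.labels) - 1)
        return self.labels[idx]


def classify_phases(trace: TemperatureTrace, config: StatsConfig | None = None) -> PhaseLabels:
    """Label each sample warming/cooling/neutral by the dT/dt threshold rule.

    dT/dt is taken by central differences after boxcar smoothing of the
    temperature (default 1 s window); warming means dT/dt above the
    threshold (default 0.001 C/s), cooling below its negative, neutral the
    band in between.
    """
    config = config or StatsConfig()
    rate = trace.rate_hz
    win = max(1, int(round(config.smooth_window_s * rate)))
    if win >= len(trace.temp_C):
        raise ValueError("trace shorter than the smoothing window")
    smooth = uniform_filter1d(trace.temp_C, size=win, mode="nearest")
    dtdt = np.gradient(smooth, trace.time_s)
    labels = np.full(len(dtdt), "neutral", dtype=object)
    labels[dtdt > config.dtdt_threshold_C_s] = "warming"
    labels[dtdt < -config.dtdt_threshold_C_s] = "cooling"
    return PhaseLabels(time_s=trace.time_s, labels=labels, dtdt_C_s=dtdt)


def turn_frequency(
    onset_times_s: np.ndarray, phases: PhaseLabels
) -> dict[str, dict[str, float]]:
    """Reorientation rate per phase: count / phase-minutes, Poisson SE."""
    onset_times_s = np.asarray(onset_times_s, dtype=float)
    onset_phases = phases.phase_at(onset_times_s) if len(onset_times_s) else np.array([])
    out: dict[str, dict[str, float]] = {}
    for phase in ("warming", "cooling"):
        minutes = phases.duration_s(phase) / 60.0
        if minutes == 0:
            continue  # phase absent from this stimulus: rate undefined
        count = int(np.sum(onset_phases == phase))
        out[phase] = {
            "rate_per_min": count / minutes,
            "se_per_min": np.sqrt(count) / minutes,
            "count": count,
            "minutes": minutes,
        }
    if not out:
        raise ZeroDivisionError("no warming or cooling time in the trace")
    return out


def first_sweep_size(
    onset_times_s: np.ndarray,
    first_sweep_peak_deg: np.ndarray,
    phases: PhaseLabels,
) -> dict[str, dict[str, float]]:
    """Mean +/- SE of each maneuver's first head-sweep peak angle, by phase."""
    onset_times_s = np.asarray(onset_times_s, dtype=float)
    peaks = np.asarray(first_sweep_peak_deg, dtype=float)
    if onset_times_s.shape != peaks.shape:
        raise ValueError("onsets and peak angles must align")
    onset_phases = phases.phase_at(onset_times_s) if len(onset_times_s) else np.array([])
    out: dict[str, dict[str, float]] = {}
    for phase in ("warming", "cooling"):
        vals = peaks[onset_phases == phase]
        n = len(vals)
        out[phase] = {
            "mean_deg": float(np.mean(vals)) if n else np.nan,
            "se_deg": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "n": n,
        }
    return out


@dataclass
class BinnedProbability:
    """m/n per peak-angle bin with binomial standard errors."""

    bin_lo_deg: np.ndarray
    bin_hi_deg: np.ndarray
    n: np.ndarray
    m: np.ndarray
    n_ambiguous: int

    @property
    def p(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.m / self.n

    @property
    def se(self) -> np.ndarray:
        p = self.p
        with np.errstate(invalid="ignore"):
            return np.sqrt(p * (1 - p) / self.n)


def initiation_probability_by_angle(
    peak_angles_deg: np.ndarray,
    init_classes: list[str],
    bin_width_deg: float = 30.0,
) -> BinnedProbability:
    """P(first wave initiates within the bend) vs head-sweep size.

    Ambiguous initiations are excluded from the bins and counted separately.
    """
    angles = np.asarray(peak_angles_deg, dtype=float)
    classes = np.asarray(init_classes, dtype=object)
    ambiguous = classes == "ambiguous"
    angles_ok = angles[~ambiguous]
    classes_ok = classes[~ambiguous]
    if len(angles_ok) == 0:
        return BinnedProbability(np.empty(0), np.empty(0), np.empty(0, int),
                                 np.empty(0, int), int(ambiguous.sum()))
    b0 = int(np.floor(angles_ok.min() / bin_width_deg))
    b1 = int(np.floor(angles_ok.max() / bin_width_deg))
    bins = np.arange(b0, b1 + 1)
    n = np.zeros(len(bins), dtype=int)
    m = np.zeros(len(bins), dtype=int)
    idx = np.floor(angles_ok / bin_width_deg).astype(int) - b0
    for i, cls in zip(idx, classes_ok):
        n[i] += 1
        if cls == "within_bend":
            m[i] += 1
    return BinnedProbability(
        bin_lo_deg=bins * bin_width_deg, bin_hi_deg=(bins + 1) * bin_width_deg,
        n=n, m=m, n_ambiguous=int(ambiguous.sum()))


@dataclass
class BinnedMean:
    bin_lo_deg: np.ndarray
    bin_hi_deg: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray


def straightening_waves_by_angle(
    peak_angles_deg: np.ndarray,
    waves_to_straighten: np.ndarray,
    bin_width_deg: float = 30.0,
) -> BinnedMean:
    """Mean +/- sd of straightening-wave counts per peak-angle bin."""
    angles = np.asarray(peak_angles_deg, dtype=float)
    counts = np.asarray(waves_to_straighten, dtype=float)
    b0 = int(np.floor(angles.min() / bin_width_deg))
    b1 = int(np.floor(angles.max() / bin_width_deg))
    bins = np.arange(b0, b1 + 1)
    mean = np.full(len(bins), np.nan)
    sd = np.full(len(bins), np.nan)
    n = np.zeros(len(bins), dtype=int)
    idx = np.floor(angles / bin_width_deg).astype(int) - b0
    for b in range(len(bins)):
        vals = counts[idx == b]
        n[b] = len(vals)
        if len(vals):
            mean[b] = float(np.mean(vals))
            sd[b] = float(np.std(vals, ddof=0))
    return BinnedMean(bin_lo_deg=bins * bin_width_deg,
                      bin_hi_deg=(bins + 1) * bin_width_deg,
                      mean=mean, sd=sd, n=n)


def forward_speed(
    track_xy: np.ndarray,
    maneuver_intervals: list[tuple[int, int]],
    pixel_scale_mm: float,
    frame_rate_hz: float,
) -> tuple[float, float]:
    """Mean frame-to-frame centroid speed (mm/s) outside maneuver frames.

    ``track_xy`` is (n, 2) in pixels; a frame-to-frame step contributes only
    if both its endpoints lie outside every maneuver interval (frames).
    Returns (mean, SE).
    """
    track_xy = np.asarray(track_xy, dtype=float)
    n = len(track_xy)
    excluded = np.zeros(n, dtype=bool)
    for f0, f1 in maneuver_intervals:
        excluded[max(0, f0):min(n, f1 + 1)] = True
    ok = ~excluded[:-1] & ~excluded[1:]
    steps = np.linalg.norm(np.diff(track_xy, axis=0), axis=1)
    finite = np.all(np.isfinite(track_xy[:-1]) & np.isfinite(track_xy[1:]), axis=1)
    ok &= finite
    if not ok.any():
        raise ValueError("no non-maneuver frames to average over")
    speeds = steps[ok] * pixel_scale_mm * frame_rate_hz
    se = float(np.std(speeds, ddof=1) / np.sqrt(len(speeds))) if len(speeds) > 1 else np.nan
    return float(np.mean(speeds)), se


@dataclass
class ThermotaxisSpeedResult:
    speed_mm_s: float
    se_mm_s: float
    stabilization_time_s: float
    stabilized_immediately: bool


def thermotaxis_speed(
    time_s: np.ndarray,
    positions_mm: np.ndarray,
    config: StatsConfig | None = None,
) -> ThermotaxisSpeedResult:
    """Population drift speed: OLS slope of mean gradient-axis position.

    The fit is truncated at stabilization: the first time the windowed mean
    drift falls below ``stabilization_frac`` of its initial value.  With at
    least two tracks the mean position is taken across animals first.
    """
    config = config or StatsConfig()
    time_s = np.asarray(time_s, dtype=float)
    positions_mm = np.atleast_2d(np.asarray(positions_mm, dtype=float))
    if positions_mm.shape[0] < 2:
        raise ValueError("need at least 2 tracks for a population estimate")
    mean_pos = positions_mm.mean(axis=0)
    dt = time_s[1] - time_s[0]
    win = max(2, int(round(config.stabilization_window_s / dt)))
    if win >= len(mean_pos):
        win = max(2, len(mean_pos) // 4)
    drift = (mean_pos[win:] - mean_pos[:-win]) / (win * dt)
    initial = drift[0]
    if abs(initial) < 1e-12:
        return ThermotaxisSpeedResult(0.0, 0.0, 0.0, True)
    below = np.flatnonzero(np.abs(drift) < config.stabilization_frac * abs(initial))
    # truncate at the *start* of the first stabilized window so no plateau
    # samples dilute the fit
    stop = int(below[0]) if len(below) else len(mean_pos) - 1
    t_stab = float(time_s[min(stop, len(time_s) - 1)])
    sel = time_s <= t_stab
    if sel.sum() < 3:
        return ThermotaxisSpeedResult(0.0, 0.0, t_stab, True)
    fit = regress_intensity_vs_length(time_s[sel], mean_pos[sel])
    return ThermotaxisSpeedResult(
        speed_mm_s=fit.slope, se_mm_s=fit.slope_se,
        stabilization_time_s=t_stab, stabilized_immediately=False)


def phase_comparison_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    method: str = "welch",
    seed: int = 0,
) -> float:
    """Two-sided test for a difference in means between phases.

    Default is Welch's unequal-variance t-test; a permutation test on the
    mean difference is available.  Two identical constant groups return
    p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    if method == "welch":
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    if method == "permutation":
        res = sps.permutation_test(
            (a, b), lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            n_resamples=2000, vectorized=True, alternative="two-sided",
            random_state=np.random.default_rng(seed))
        return float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")
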