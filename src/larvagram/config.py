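"""Configuration dataclasses for the generator and the analysis pipeline.

All configs round-trip through plain dicts (JSON/YAML); unknown keys are
rejected so typos in config files fail loudly.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .body import SEGMENT_NAMES, segment_index


def _strict_from_dict(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class TemperatureWaveform:
    """Sinusoidal temperature stimulus: offset + amplitude*sin(2*pi*t/period + phase)."""

    offset_C: float = 15.0
    amplitude_C: float = 1.0
    period_s: float = 120.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_C < 0:
            raise ValueError("amplitude must be >= 0")
        if self.period_s <= 0:
            raise ValueError("period must be > 0")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "TemperatureWaveform":
        return _strict_from_dict(cls, data)


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the emulated study conditions.

    Units are in field names.  ``wave_rate_hz`` (peristalsis cycles per
    second) is not reported by the study this emulates; 1.2 waves/s makes
    forward speed = displacement_per_wave_bl * body length * wave rate
    ~ 0.31 mm/s for a 2 mm body, matching the reported run speed scale.
    """

    # imaging
    frame_rate_hz: float = 8.0
    pixel_scale_mm: float = 0.01
    image_size_px: int = 320
    calibration: float = 10000.0       # rendered intensity of a rest-area quadrant
    noise_sd_frac: float = 0.02        # additive Gaussian sd as fraction of calibration
    # body / forward crawling
    body_length_mm: float = 2.0
    max_width_mm: float = 0.35
    wave_rate_hz: float = 1.2
    displacement_per_wave_bl: float = 0.13
    contraction_amplitude: float = 0.15
    pulse_half_width_seg: float = 2.0
    # head sweeps (pivot)
    pivot_anterior: str = "T3"
    pivot_posterior: str = "A3"
    pivot_center: str = "A1"
    bend_half_width_seg: float = 2.3
    bend_half_width_large_seg: float = 3.5
    segments_per_wave_around_bend: float = 2.0
    sweep_rise_s: float = 1.0
    sweep_hold_s: float = 0.25
    straightened_deg: float = 20.0
    # behavior statistics
    turn_rate_warming_per_min: float = 3.2
    turn_rate_cooling_per_min: float = 3.8
    sweep_mean_warming_deg: float = 53.0
    sweep_mean_cooling_deg: float = 60.0
    sweep_sd_deg: float = 10.0
    min_sweep_deg: float = 45.0
    max_sweep_deg: float = 150.0
    reject_base: float = 0.2
    reject_slope_per_degC_s: float = 40.0
    max_sweeps_per_turn: int = 4
    # event-level track synthesis (spatial-gradient mode)
    run_speed_mm_s: float | None = None   # None -> displacement * BL * wave rate
    drift_speed_mm_s: float = 0.075

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0 or self.pixel_scale_mm <= 0:
            raise ValueError("frame_rate_hz and pixel_scale_mm must be > 0")
        if not (0 < self.displacement_per_wave_bl < 1):
            raise ValueError("displacement_per_wave_bl must be in (0, 1)")
        if not (0 <= self.contraction_amplitude < 1):
            raise ValueError("contraction_amplitude must be in [0, 1)")
        for name in (self.pivot_anterior, self.pivot_posterior, self.pivot_center):
            segment_index(name)  # raises on unknown label
        if not (segment_index(self.pivot_anterior)
                <= segment_index(self.pivot_center)
                <= segment_index(self.pivot_posterior)):
            raise ValueError("pivot centre must lie within the pivot range")
        if self.min_sweep_deg >= self.max_sweep_deg:
            raise ValueError("min_sweep_deg must be < max_sweep_deg")

    @property
    def effective_run_speed_mm_s(self) -> float:
        if self.run_speed_mm_s is not None:
            return self.run_speed_mm_s
        return self.displacement_per_wave_bl * self.body_length_mm * self.wave_rate_hz

    @property
    def wave_period_s(self) -> float:
        return 1.0 / self.wave_rate_hz

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        return _strict_from_dict(cls, data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class VisionConfig:
    """Outline/centerline extraction parameters.

    ``boundary_smooth_frac`` and ``curvature_window_frac`` are fractions of
    the total boundary length (0.5% Gaussian smoothing, 20% curvature
    window); head sweeps are flagged when |theta| exceeds
    ``sweep_threshold_deg`` (40 deg) and released below ``sweep_release_deg``.
    """

    threshold_method: str = "otsu"           # "otsu" or "fixed"
    fixed_threshold: float = 0.0
    morph_radius_px: int = 2
    boundary_smooth_frac: float = 0.005
    curvature_window_frac: float = 0.20
    outline_points: int = 800
    centerline_points: int = 101
    sweep_threshold_deg: float = 40.0
    sweep_release_deg: float = 20.0
    min_extremum_separation_frac: float = 0.25
    min_component_area_px: float = 50.0
    tip_curvature_frac: float = 0.025

    def __post_init__(self) -> None:
        if not (0 <= self.boundary_smooth_frac < self.curvature_window_frac < 0.5):
            raise ValueError(
                "require 0 <= boundary_smooth_frac < curvature_window_frac < 0.5")
        if self.sweep_release_deg >= self.sweep_threshold_deg:
            raise ValueError("sweep_release_deg must be < sweep_threshold_deg")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "VisionConfig":
        return _strict_from_dict(cls, data)


@dataclass
class EventConfig:
    """Wave detection / maneuver assembly parameters."""

    wave_amplitude_threshold: float = 0.05    # fractional-change units
    min_lag_frames: int = 0
    max_lag_frames: int = 3
    min_chain_segments: int = 4
    asym_threshold: float = 0.05              # |ln(L_R/L_L)| region threshold
    straight_threshold_deg: float = 20.0
    straight_sustain_s: float = 1.0
    tail_segments: tuple[str, ...] = ("A7", "A8")

    def __post_init__(self) -> None:
        if self.min_lag_frames < 0 or self.max_lag_frames < self.min_lag_frames:
            raise ValueError("invalid wave-chaining lag bounds")
        for name in self.tail_segments:
            if name not in SEGMENT_NAMES:
                raise ValueError(f"unknown segment {name!r}")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "EventConfig":
        data = dict(data)
        if "tail_segments" in data:
            data["tail_segments"] = tuple(data["tail_segments"])
        return _strict_from_dict(cls, data)


@dataclass
class StatsConfig:
    """Statistical-summary parameters (phase rule, binning, test choice)."""

    dtdt_threshold_C_s: float = 0.001
    smooth_window_s: float = 1.0
    bin_width_deg: float = 30.0
    comparison_test: str = "welch"            # "welch" or "permutation"
    stabilization_frac: float = 0.10
    stabilization_window_s: float = 60.0

    def __post_init__(self) -> None:
        if self.comparison_test not in ("welch", "permutation"):
            raise ValueError("comparison_test must be 'welch' or 'permutation'")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "StatsConfig":
        return _strict_from_dict(cls, data)


@dataclass
class PipelineConfig:
    """Nested configuration for the simulate->track->kymo->events->stats driver."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    temperature: TemperatureWaveform = field(default_factory=TemperatureWaveform)
    vision: VisionConfig = field(default_factory=VisionConfig)
    events: EventConfig = field(default_factory=EventConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    duration_s: float = 60.0
    seed: int = 0
    out_dir: str = "larvagram_out"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sub = {
            "simulation": SimulationConfig,
            "temperature": TemperatureWaveform,
            "vision": VisionConfig,
            "events": EventConfig,
            "stats": StatsConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, subcls in sub.items():
            if key in data:
                kwargs[key] = subcls.from_dict(data.pop(key))
        known = {f.name for f in dataclasses.fields(cls)} - set(sub)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a JSON or YAML file (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, default=_json_default))
    else:
        path.write_text(yaml.safe_dump(_yamlable(data)))


def _json_default(obj):
    import numpy as np

    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _yamlable(data):
    if isinstance(data, dict):
        return {k: _yamlable(v) for k, v in data.items()}
    if isinstance(data, (list, tuple)):
        return [_yamlable(v) for v in data]
    import numpy as np

    if isinstance(data, np.ndarray):
        return data.tolist()
    if isinstance(data, (np.floating, np.integer)):
        return data.item()
    return data
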