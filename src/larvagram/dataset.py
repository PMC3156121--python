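"""Bundled synthetic datasets: simulation driver and disk round-trip.

A dataset couples the rendered image stack with everything the analysis
stages otherwise get from a human or the instrument: the 20-point
segment-boundary annotation (hand-clicked on real video), the temperature
trace, stage positions, and generator-side truth for validation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import BehaviorProgram, sample_behavior
from .body import SEGMENT_NAMES, LarvaBodyModel, default_body
from .config import SimulationConfig, TemperatureWaveform
from .kinematics import GroundTruth, synthesize_kinematics
from .render import RenderResult, render_frames, world_to_pixels
from .temperature import TemperatureTrace, generate_temperature

__all__ = ["SyntheticDataset", "simulate_dataset", "export_dataset", "load_dataset"]

# point_id convention (matches the segment-boundary numbering of the study):
# 0 = head tip, +1..+10 = left-side boundaries head->tail, -1..-10 = right
# side, 11 = tail tip.
_LEFT_IDS = list(range(1, 11))
_RIGHT_IDS = [-j for j in range(1, 11)]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    waveform: TemperatureWaveform
    duration_s: float
    seed: int
    body: LarvaBodyModel
    program: BehaviorProgram
    truth: GroundTruth
    render: RenderResult
    temperature: TemperatureTrace

    @property
    def n_frames(self) -> int:
        return self.truth.n_frames

    def annotation_points_px(self, frame: int) -> pd.DataFrame:
        """20 boundary points plus head/tail tips in pixel coordinates."""
        left_mm, right_mm = self.truth.boundary_points(frame)
        stage = self.render.stage_mm[frame]
        left = world_to_pixels(left_mm, stage, self.config)
        right = world_to_pixels(right_mm, stage, self.config)
        rows = [
            {"frame": frame, "point_id": 0, "x_px": left[0, 0], "y_px": left[0, 1]},
            {"frame": frame, "point_id": 11, "x_px": left[11, 0], "y_px": left[11, 1]},
        ]
        for j, pid in enumerate(_LEFT_IDS, start=1):
            rows.append({"frame": frame, "point_id": pid,
                         "x_px": left[j, 0], "y_px": left[j, 1]})
        for j, pid in enumerate(_RIGHT_IDS, start=1):
            rows.append({"frame": frame, "point_id": pid,
                         "x_px": right[j, 0], "y_px": right[j, 1]})
        return pd.DataFrame(rows)

    def annotation_table(self) -> pd.DataFrame:
        return pd.concat(
            [self.annotation_points_px(f) for f in range(self.n_frames)],
            ignore_index=True,
        )

    def segment_truth_table(self) -> pd.DataFrame:
        scale = self.config.pixel_scale_mm
        rows = []
        for f in range(self.n_frames):
            for i, name in enumerate(SEGMENT_NAMES):
                rows.append({
                    "frame": f, "segment": name,
                    "len_left_px": self.truth.seg_len_left_mm[f, i] / scale,
                    "len_right_px": self.truth.seg_len_right_mm[f, i] / scale,
                    "area_px2": self.truth.seg_area_mm2[f, i] / scale ** 2,
                    "i_al": self.truth.quad_intensity[f, i, 0],
                    "i_ar": self.truth.quad_intensity[f, i, 1],
                    "i_pl": self.truth.quad_intensity[f, i, 2],
                    "i_pr": self.truth.quad_intensity[f, i, 3],
                })
        return pd.DataFrame(rows)

    def frame_truth_table(self) -> pd.DataFrame:
        head_px = np.empty((self.n_frames, 2))
        tail_px = np.empty((self.n_frames, 2))
        for f in range(self.n_frames):
            stage = self.render.stage_mm[f]
            head_px[f] = world_to_pixels(self.truth.center_mm[f, 0], stage, self.config)
            tail_px[f] = world_to_pixels(self.truth.center_mm[f, -1], stage, self.config)
        return pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "time_s": self.truth.time_s,
            "theta_deg": self.truth.theta_deg,
            "wave_id": self.truth.wave_id,
            "wave_segment": self.truth.wave_segment,
            "event_label": self.truth.event_label,
            "maneuver_id": self.truth.maneuver_id,
            "stage_x_mm": self.render.stage_mm[:, 0],
            "stage_y_mm": self.render.stage_mm[:, 1],
            "head_x_px": head_px[:, 0], "head_y_px": head_px[:, 1],
            "tail_x_px": tail_px[:, 0], "tail_y_px": tail_px[:, 1],
        })


def simulate_dataset(
    config: SimulationConfig | None = None,
    waveform: TemperatureWaveform | None = None,
    duration_s: float = 60.0,
    seed: int = 0,
    program: BehaviorProgram | None = None,
) -> SyntheticDataset:
    """Run temperature -> behavior -> kinematics -> render with one seed."""
    config = config or SimulationConfig()
    waveform = waveform or TemperatureWaveform()
    ss = np.random.SeedSequence(seed)
    seed_behavior, seed_render = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2)]
    trace = generate_temperature(waveform, duration_s, config.frame_rate_hz)
    if program is None:
        program = sample_behavior(config, trace, seed_behavior)
    body = default_body(config.body_length_mm, config.max_width_mm)
    truth = synthesize_kinematics(program, body, config)
    rendered = render_frames(truth, config, seed=seed_render)
    return SyntheticDataset(
        config=config, waveform=waveform, duration_s=duration_s, seed=seed,
        body=body, program=program, truth=truth, render=rendered,
        temperature=trace,
    )


def export_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write stack (TIFF), annotation/truth (CSV), temperature (CSV), config (JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": directory / "stack.tif",
        "annotation": directory / "annotation_points.csv",
        "segments": directory / "truth_segments.csv",
        "frames": directory / "truth_frames.csv",
        "temperature": directory / "temperature.csv",
        "config": directory / "config.json",
    }
    tifffile.imwrite(paths["stack"], dataset.render.stack)
    dataset.annotation_table().to_csv(paths["annotation"], index=False)
    dataset.segment_truth_table().to_csv(paths["segments"], index=False)
    dataset.frame_truth_table().to_csv(paths["frames"], index=False)
    pd.DataFrame({
        "time_s": dataset.temperature.time_s,
        "temp_C": dataset.temperature.temp_C,
    }).to_csv(paths["temperature"], index=False)
    cfg = {
        "simulation": dataset.config.to_dict(),
        "temperature": {
            "offset_C": dataset.waveform.offset_C,
            "amplitude_C": dataset.waveform.amplitude_C,
            "period_s": dataset.waveform.period_s,
            "phase_rad": dataset.waveform.phase_rad,
        },
        "duration_s": dataset.duration_s,
        "seed": dataset.seed,
    }
    paths["config"].write_text(json.dumps(cfg, indent=2))
    return paths


@dataclass
class LoadedDataset:
    """Disk image of an exported dataset (analysis-side view)."""

    stack: np.ndarray
    annotation: pd.DataFrame
    segments: pd.DataFrame
    frames: pd.DataFrame
    temperature: TemperatureTrace
    config: SimulationConfig
    waveform: TemperatureWaveform
    duration_s: float
    seed: int


def load_dataset(directory: str | Path) -> LoadedDataset:
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    temp = pd.read_csv(directory / "temperature.csv")
    return LoadedDataset(
        stack=tifffile.imread(directory / "stack.tif"),
        annotation=pd.read_csv(directory / "annotation_points.csv"),
        segments=pd.read_csv(directory / "truth_segments.csv"),
        frames=pd.read_csv(directory / "truth_frames.csv"),
        temperature=TemperatureTrace(
            time_s=temp["time_s"].to_numpy(), temp_C=temp["temp_C"].to_numpy()),
        config=SimulationConfig.from_dict(cfg["simulation"]),
        waveform=TemperatureWaveform.from_dict(cfg["temperature"]),
        duration_s=float(cfg["duration_s"]),
        seed=int(cfg["seed"]),
    )
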