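"""End-to-end driver: simulate -> track -> kymo -> events -> stats.

``run_video_pipeline`` produces all in-memory results for one rendered
simulation; ``run_pipeline`` wraps it with file output and a manifest and is
what the command-line interface calls.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._geom import cum_arc_length
from .config import PipelineConfig
from .dataset import SyntheticDataset, export_dataset, simulate_dataset
from .events import (
    PeristalsisWave,
    ReorientationManeuver,
    annotate_maneuvers,
    assemble_maneuvers,
    detect_waves,
    wave_displacement,
)
from .render import pixels_to_world
from .segments import (
    SegmentMetrics,
    asymmetry_kymograph,
    choose_reference_frame,
    contraction_kymograph,
    length_kymograph,
    measure_stack,
)
from .stats import classify_phases, first_sweep_size, forward_speed, turn_frequency
from .vision import HeadSweepEvent, TrackResult, track_stack

log = logging.getLogger("larvagram")

__all__ = ["VideoPipelineResult", "run_video_pipeline", "run_pipeline"]


@dataclass
class VideoPipelineResult:
    dataset: SyntheticDataset
    track: TrackResult
    metrics: SegmentMetrics
    reference_frame: int
    kymo_length: object
    kymo_contraction: object
    kymo_asymmetry: object
    waves: list[PeristalsisWave]
    sweeps: list[HeadSweepEvent]
    maneuvers: list[ReorientationManeuver]
    tail_mm: np.ndarray = field(default=None)
    head_mm: np.ndarray = field(default=None)
    body_length_mm: float = 0.0

    def wave_displacements_bl(self, body_length_mm: float | None = None) -> np.ndarray:
        """Per-wave forward displacement in body lengths (full cycles).

        Each wave's displacement is measured from its onset to the next
        wave's onset (waves run back to back); pairs separated by a pause
        (maneuver) are skipped, as is the unterminated final wave.
        Displacements are normalized by the animal's nominal body length
        (experiment metadata); the video-derived estimate
        ``self.body_length_mm`` runs a few percent short because outline
        smoothing recedes the tips.
        """
        if body_length_mm is None:
            body_length_mm = self.dataset.config.body_length_mm
        rate = self.dataset.config.frame_rate_hz
        max_gap = 1.6 / self.dataset.config.wave_rate_hz * rate
        out = []
        for w, w_next in zip(self.waves, self.waves[1:]):
            if w_next.onset_frame - w.onset_frame > max_gap:
                continue
            out.append(wave_displacement(
                self.tail_mm, self.head_mm, w, body_length_mm,
                end_frame=w_next.onset_frame))
        return np.asarray(out)


def _world_tracks(dataset: SyntheticDataset, track: TrackResult):
    n = dataset.n_frames
    tail = np.full((n, 2), np.nan)
    head = np.full((n, 2), np.nan)
    centroid = np.full((n, 2), np.nan)
    for f in range(n):
        if not track.valid[f]:
            continue
        stage = dataset.render.stage_mm[f]
        tail[f] = pixels_to_world(track.tail_px[f], stage, dataset.config)
        head[f] = pixels_to_world(track.head_px[f], stage, dataset.config)
        centroid[f] = pixels_to_world(
            track.outlines[f].vertices.mean(axis=0), stage, dataset.config)
    return tail, head, centroid


def run_video_pipeline(
    dataset: SyntheticDataset,
    vision_config=None,
    event_config=None,
) -> VideoPipelineResult:
    """Track, measure, and detect events on a rendered synthetic dataset.

    The 20-point annotation comes from the dataset (ground truth standing in
    for the hand-clicked points); everything else is measured from pixels.
    The kymograph reference frame is first frame 0, then re-chosen as the
    inter-wave frame minimizing total |fractional length change| and the
    kymographs recomputed once.
    """
    from .config import EventConfig, VisionConfig

    vision_config = vision_config or VisionConfig()
    event_config = event_config or EventConfig()
    cfg = dataset.config
    frames = dataset.frame_truth_table()
    prior = (
        np.array([frames["head_x_px"][0], frames["head_y_px"][0]]),
        np.array([frames["tail_x_px"][0], frames["tail_y_px"][0]]),
    )
    track = track_stack(dataset.render.stack, vision_config, prior=prior)
    annotation = dataset.annotation_table()
    metrics = measure_stack(dataset.render.stack, track, annotation)

    # first pass: reference frame 0; re-pick between detected waves
    first_valid = int(np.flatnonzero(metrics.valid)[0])
    kymo0 = contraction_kymograph(metrics, first_valid, "fractional_length",
                                  cfg.frame_rate_hz)
    waves0 = detect_waves(kymo0, event_config)
    ref = choose_reference_frame(
        metrics, [(w.onset_s, w.offset_s) for w in waves0], cfg.frame_rate_hz)
    kymo_len = length_kymograph(metrics, ref, cfg.frame_rate_hz)
    kymo_con = contraction_kymograph(metrics, ref, "fractional_length", cfg.frame_rate_hz)
    kymo_asym = asymmetry_kymograph(metrics, cfg.frame_rate_hz)
    waves = detect_waves(kymo_con, event_config)
    sweeps = track.events(vision_config)
    maneuvers = assemble_maneuvers(sweeps, waves, track.theta_deg, event_config,
                                   cfg.frame_rate_hz)
    annotate_maneuvers(maneuvers, kymo_asym, event_config)

    tail, head, centroid = _world_tracks(dataset, track)
    # body length from the uncontracted posture: the centerline shortens by
    # a few percent while a contraction pulse is on the body, so use a high
    # percentile of the per-frame arc lengths
    lengths = [
        cum_arc_length(track.centerlines[f].points)[-1] * cfg.pixel_scale_mm
        for f in range(dataset.n_frames) if track.valid[f]
    ]
    return VideoPipelineResult(
        dataset=dataset, track=track, metrics=metrics, reference_frame=ref,
        kymo_length=kymo_len, kymo_contraction=kymo_con, kymo_asymmetry=kymo_asym,
        waves=waves, sweeps=sweeps, maneuvers=maneuvers,
        tail_mm=tail, head_mm=head,
        body_length_mm=float(np.percentile(lengths, 95)),
    )


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Execute all stages, writing artifacts and a manifest; returns out dir."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    try:
        log.info("simulate: %.0f s at %.0f Hz", config.duration_s,
                 config.simulation.frame_rate_hz)
        dataset = simulate_dataset(config.simulation, config.temperature,
                                   config.duration_s, config.seed)
        sim_paths = export_dataset(dataset, out / "simulate")
        manifest["stages"]["simulate"] = {k: str(v) for k, v in sim_paths.items()}

        log.info("track + kymo + events")
        result = run_video_pipeline(dataset, config.vision, config.events)

        track_df = pd.DataFrame({
            "frame": np.arange(dataset.n_frames),
            "head_x": result.track.head_px[:, 0], "head_y": result.track.head_px[:, 1],
            "tail_x": result.track.tail_px[:, 0], "tail_y": result.track.tail_px[:, 1],
            "theta_deg": result.track.theta_deg,
            "valid": result.track.valid,
        })
        track_path = out / "track.csv"
        track_df.to_csv(track_path, index=False)
        manifest["stages"]["track"] = {"track": str(track_path)}

        kymo_paths = {}
        for name, kymo in [("length", result.kymo_length),
                           ("contraction", result.kymo_contraction),
                           ("asymmetry", result.kymo_asymmetry)]:
            p = out / f"kymo_{name}.csv"
            kymo.to_csv(p)
            kymo_paths[name] = str(p)
        manifest["stages"]["kymo"] = kymo_paths

        waves_df = pd.DataFrame([{
            "wave_id": i, "onset_s": w.onset_s, "offset_s": w.offset_s,
            "init_segment": w.initiation_segment,
            "term_segment": w.termination_segment,
            "speed_seg_s": w.speed_seg_s,
        } for i, w in enumerate(result.waves)])
        rate = config.simulation.frame_rate_hz
        man_df = pd.DataFrame([{
            "maneuver_id": i,
            "onset_s": m.onset_frame / rate,
            "straightened_s": m.straightened_frame / rate,
            "n_sweeps": m.n_sweeps,
            "first_peak_deg": m.first_sweep.peak_deg,
            "accepted_peak_deg": m.accepted_sweep.peak_deg,
            "direction": m.accepted_sweep.direction,
            "size_class": m.accepted_sweep.size_class,
            "waves_to_straighten": m.waves_to_straighten,
            "region_anterior": m.region.anterior_extent if m.region else "",
            "region_posterior": m.region.posterior_extent if m.region else "",
            "region_peak": m.region.peak_segment if m.region else "",
            "init_class": m.init_class or "",
        } for i, m in enumerate(result.maneuvers)])
        events_path = out / "events"
        events_path.mkdir(exist_ok=True)
        waves_df.to_csv(events_path / "waves.csv", index=False)
        man_df.to_csv(events_path / "maneuvers.csv", index=False)
        manifest["stages"]["events"] = {
            "waves": str(events_path / "waves.csv"),
            "maneuvers": str(events_path / "maneuvers.csv"),
        }

        log.info("stats")
        phases = classify_phases(dataset.temperature, config.stats)
        onsets = np.array([m.onset_frame / rate for m in result.maneuvers])
        firsts = np.array([m.first_sweep.peak_deg for m in result.maneuvers])
        summary = {
            "n_waves": len(result.waves),
            "n_maneuvers": len(result.maneuvers),
            "body_length_mm": result.body_length_mm,
            "reference_frame": result.reference_frame,
        }
        disp = result.wave_displacements_bl()
        if len(disp):
            summary["mean_wave_displacement_bl"] = float(np.mean(disp))
        try:
            summary["turn_frequency"] = turn_frequency(onsets, phases)
            summary["first_sweep_size"] = first_sweep_size(onsets, firsts, phases)
        except ZeroDivisionError:
            summary["turn_frequency"] = None
        _, _, centroid = _world_tracks(dataset, result.track)
        try:
            speed, speed_se = forward_speed(
                centroid / config.simulation.pixel_scale_mm,
                [(m.onset_frame, m.straightened_frame) for m in result.maneuvers],
                config.simulation.pixel_scale_mm, rate)
            summary["forward_speed_mm_s"] = {"mean": speed, "se": speed_se}
        except ValueError:
            summary["forward_speed_mm_s"] = None
        stats_path = out / "summary.json"
        stats_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest["stages"]["stats"] = {"summary": str(stats_path)}
    except Exception:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.exception("pipeline stage failed; partial outputs retained in %s", out)
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
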