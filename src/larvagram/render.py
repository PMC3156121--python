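"""Render ground-truth kinematics into 16-bit fluorescence-like image stacks.

Each segment quadrant is drawn as a filled polygon whose intensity is
``calibration * rest_area / current_area``: total fluorophore per quadrant is
conserved, so contraction concentrates signal and brightens, as muscle-GFP
does.  Frames are recentred on the body centroid (emulating the tracking
stage); the stage position is returned so world coordinates can be
reconstructed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon as draw_polygon

from .config import SimulationConfig
from .kinematics import GroundTruth, Posture, _quadrant_polys

__all__ = ["RenderResult", "render_frames", "world_to_pixels", "pixels_to_world"]


class OutOfFrameError(RuntimeError):
    """The body does not fit the pixel grid (the tracking stage would recentre)."""


@dataclass
class RenderResult:
    stack: np.ndarray        # (n, H, W) uint16
    stage_mm: np.ndarray     # (n, 2) world position of the image centre

    @property
    def n_frames(self) -> int:
        return len(self.stack)


def world_to_pixels(points_mm: np.ndarray, stage_mm: np.ndarray,
                    config: SimulationConfig) -> np.ndarray:
    """Map world (x, y) mm (y-up) to pixel (x=col, y=row) with y flipped down."""
    half = config.image_size_px / 2.0
    x = (points_mm[..., 0] - stage_mm[0]) / config.pixel_scale_mm + half
    y = half - (points_mm[..., 1] - stage_mm[1]) / config.pixel_scale_mm
    return np.stack([x, y], axis=-1)


def pixels_to_world(points_px: np.ndarray, stage_mm: np.ndarray,
                    config: SimulationConfig) -> np.ndarray:
    half = config.image_size_px / 2.0
    x = (points_px[..., 0] - half) * config.pixel_scale_mm + stage_mm[0]
    y = (half - points_px[..., 1]) * config.pixel_scale_mm + stage_mm[1]
    return np.stack([x, y], axis=-1)


def render_frames(truth: GroundTruth, config: SimulationConfig | None = None,
                  seed: int = 0) -> RenderResult:
    config = config or truth.config
    n = truth.n_frames
    size = config.image_size_px
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x52454E44]))
    stack = np.zeros((n, size, size), dtype=np.uint16)
    stage = np.empty((n, 2))
    noise_sd = config.noise_sd_frac * config.calibration

    for f in range(n):
        outline = np.vstack([truth.left_mm[f], truth.right_mm[f][::-1]])
        centroid = outline.mean(axis=0)
        stage[f] = centroid
        img = np.zeros((size, size), dtype=np.float64)
        post = Posture(center=truth.center_mm[f], left=truth.left_mm[f],
                       right=truth.right_mm[f])
        for i in range(truth.quad_area_mm2.shape[1]):
            for q, poly in enumerate(_quadrant_polys(post, i)):
                px = world_to_pixels(poly, stage[f], config)
                if (px < -0.5).any() or (px > size - 0.5).any():
                    raise OutOfFrameError(
                        f"frame {f}: body exceeds the {size}x{size} field of view")
                rr, cc = draw_polygon(px[:, 1], px[:, 0], shape=img.shape)
                img[rr, cc] = truth.quad_intensity[f, i, q]
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, size=img.shape)
        stack[f] = np.clip(img, 0, 65535).astype(np.uint16)
    return RenderResult(stack=stack, stage_mm=stage)
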