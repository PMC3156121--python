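"""Larva body model: eleven trapezoidal segments T1..T3, A1..A8.

Segment arrays throughout the package are ordered head to tail
(index 0 = T1, index 10 = A8).  Segment *boundaries* are indexed 0 (head tip)
to 11 (tail tip); boundary ``j`` separates segment ``j-1`` from segment ``j``.
The bend ("pivot") machinery also uses a tail-based boundary coordinate
``x = 11 - j`` so that the tail is 0 and the head is 11, matching the
direction in which peristalsis waves travel.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEGMENT_NAMES: tuple[str, ...] = (
    "T1", "T2", "T3", "A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8",
)
N_SEGMENTS = len(SEGMENT_NAMES)


def segment_index(name: str) -> int:
    try:
        return SEGMENT_NAMES.index(name)
    except ValueError as exc:
        raise ValueError(f"unknown segment name {name!r}") from exc


@dataclass(frozen=True)
class LarvaBodyModel:
    """Rest geometry of the larva body.

    ``rest_lengths_mm`` are per-segment centerline lengths head to tail; the
    body half-width tapers as ``0.5 * max_width_mm * sqrt(sin(pi * u))``
    where ``u`` is the rest arc-length fraction from the head: a rounded
    (parabolic) taper at both tips, like the real animal, that still gives
    the boundary-curvature head/tail detector its two maxima and renders
    T1/A8 as near-triangular segments.
    """

    rest_lengths_mm: np.ndarray
    max_width_mm: float = 0.35
    segment_names: tuple[str, ...] = field(default=SEGMENT_NAMES)

    def __post_init__(self) -> None:
        lengths = np.asarray(self.rest_lengths_mm, dtype=float)
        object.__setattr__(self, "rest_lengths_mm", lengths)
        if lengths.shape != (N_SEGMENTS,):
            raise ValueError(f"expected {N_SEGMENTS} segment lengths, got {lengths.shape}")
        if np.any(lengths <= 0) or self.max_width_mm <= 0:
            raise ValueError("segment lengths and body width must be positive")

    @property
    def body_length_mm(self) -> float:
        return float(self.rest_lengths_mm.sum())

    def boundary_fractions(self) -> np.ndarray:
        """Rest arc-length fraction from the head of boundaries 0..11."""
        cum = np.concatenate([[0.0], np.cumsum(self.rest_lengths_mm)])
        return cum / cum[-1]

    def half_width_at(self, u) -> np.ndarray:
        """Half-width (mm) at rest arc-length fraction ``u`` from the head."""
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        return 0.5 * self.max_width_mm * np.sqrt(np.sin(np.pi * u))


def default_body(body_length_mm: float = 2.0, max_width_mm: float = 0.35) -> LarvaBodyModel:
    """Second-instar-like body: 2 mm long, 11 equal segments, 0.35 mm wide."""
    lengths = np.full(N_SEGMENTS, body_length_mm / N_SEGMENTS)
    return LarvaBodyModel(rest_lengths_mm=lengths, max_width_mm=max_width_mm)
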