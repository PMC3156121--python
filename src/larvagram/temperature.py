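"""Sinusoidal temperature stimulus traces."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import TemperatureWaveform

__all__ = ["TemperatureTrace", "TemperatureWaveform", "generate_temperature"]


@dataclass
class TemperatureTrace:
    """Regularly sampled temperature record."""

    time_s: np.ndarray
    temp_C: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        if self.time_s.shape != self.temp_C.shape or self.time_s.ndim != 1:
            raise ValueError("time and temperature arrays must be 1-D and equal length")
        if len(self.time_s) < 2:
            raise ValueError("trace needs at least two samples")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1])

    def derivative(self) -> np.ndarray:
        """dT/dt (deg C per second) by central differences."""
        return np.gradient(self.temp_C, self.time_s)


def generate_temperature(
    waveform: TemperatureWaveform, duration_s: float, rate_hz: float
) -> TemperatureTrace:
    """Sample T(t) = offset + amplitude * sin(2*pi*t/period + phase)."""
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    n = int(round(duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    temp = waveform.offset_C + waveform.amplitude_C * np.sin(
        2.0 * np.pi * t / waveform.period_s + waveform.phase_rad
    )
    return TemperatureTrace(time_s=t, temp_C=temp)
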