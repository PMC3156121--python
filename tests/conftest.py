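"""Shared fixtures: rendered synthetic datasets reused across test modules.

All fixtures are seeded, so every run of the suite sees identical data.
"""
from __future__ import annotations

import warnings

import pytest

from larvagram import SimulationConfig, TemperatureWaveform, simulate_dataset
from larvagram.behavior import BehaviorProgram, SweepPlan, _build_turn
from larvagram.pipeline import run_video_pipeline

warnings.filterwarnings("ignore", category=FutureWarning)


def single_sweep_dataset(amplitude_deg: float, direction: int = 1, seed: int = 2,
                         duration_s: float = 14.0, config: SimulationConfig | None = None):
    """One maneuver with a single head sweep of the given amplitude."""
    config = config or SimulationConfig()
    turn = _build_turn(2.5, [SweepPlan(direction, amplitude_deg, True)], "cooling", config)
    program = BehaviorProgram(duration_s=duration_s, turns=[turn])
    return simulate_dataset(config, TemperatureWaveform(), duration_s, seed=seed,
                            program=program)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def run_dataset(sim_config):
    """60 s of pure forward crawling (72 full peristalsis cycles)."""
    program = BehaviorProgram(duration_s=60.0, turns=[])
    return simulate_dataset(sim_config, TemperatureWaveform(), 60.0, seed=5,
                            program=program)


@pytest.fixture(scope="session")
def run_result(run_dataset):
    return run_video_pipeline(run_dataset)


@pytest.fixture(scope="session")
def sweep_datasets():
    """Single-sweep maneuvers at 50/90/130 deg (small, large, large)."""
    return {amp: single_sweep_dataset(amp) for amp in (50.0, 90.0, 130.0)}


@pytest.fixture(scope="session")
def sweep_results(sweep_datasets):
    return {amp: run_video_pipeline(ds) for amp, ds in sweep_datasets.items()}


@pytest.fixture(scope="session")
def default_video_dataset(sim_config):
    """60 s at the default behavior statistics (runs plus a few maneuvers)."""
    return simulate_dataset(sim_config, TemperatureWaveform(), 60.0, seed=42)


@pytest.fixture(scope="session")
def default_video_result(default_video_dataset):
    return run_video_pipeline(default_video_dataset)
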