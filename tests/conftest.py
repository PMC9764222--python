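"""Shared fixtures: schedules, grids, and simulated cohorts.

The cohort fixtures are session-scoped because several tests interrogate
different aspects of the same simulated study (detection sensitivity,
model recovery, predictability statistics).
"""

from __future__ import annotations

import numpy as np
import pytest

from oddball_fmri import design, pipeline, simulate


@pytest.fixture(scope="session")
def schedule():
    return design.build_run(seed=42)


@pytest.fixture(scope="session")
def small_grid():
    """Single 100-voxel ROI."""
    return simulate.make_roi_grid(
        {"shape": (10, 5, 2), "rois": {"A": ((0, 10), (0, 5), (0, 2))}})


def _recovery_config(model: str, seed: int) -> pipeline.PipelineConfig:
    """10 participants x 4 runs, two 100-voxel ROIs generated by ``model``."""
    profile = {"model": model, "gain": simulate.DEFAULT_GAIN,
               "slope_sign": -1 if model == "h2" else 1,
               "baseline": 1.0 if model == "h2" else 0.0}
    names = simulate.DEFAULT_ROI_NAMES[:2]
    return pipeline.PipelineConfig(
        n_participants=10, n_runs=4, grid_shape=(11, 5, 4),
        roi_block=(5, 5, 4),
        roi_profiles={n: dict(profile) for n in names}, seed=seed)


@pytest.fixture(scope="session")
def h2_report():
    """Full pipeline on a cohort whose 200 signal voxels follow h2."""
    return pipeline.run_pipeline(_recovery_config("h2", seed=2024))


@pytest.fixture(scope="session")
def h1_report():
    """Same cohort geometry and seeds, generated under h1."""
    return pipeline.run_pipeline(_recovery_config("h1", seed=2024))


@pytest.fixture(scope="session")
def mixed_cohort_detection():
    """19 participants x 4 runs on the 8-ROI grid: one h2 ROI, one h1 ROI,
    six null ROIs (200 signal voxels among 800)."""
    names = simulate.DEFAULT_ROI_NAMES
    profiles = {n: {"model": "null", "gain": 0.0, "slope_sign": 1,
                    "baseline": 0.0} for n in names}
    profiles["Te1.0L"] = {"model": "h2", "gain": simulate.DEFAULT_GAIN,
                          "slope_sign": -1, "baseline": 1.0}
    profiles["Te1.0R"] = {"model": "h1", "gain": simulate.DEFAULT_GAIN,
                          "slope_sign": 1, "baseline": 0.0}
    config = pipeline.PipelineConfig(n_participants=19, n_runs=4,
                                     roi_profiles=profiles, seed=21)
    cohort = pipeline.simulate_cohort(config)
    maps = pipeline.fit_cohort(config, cohort)
    detection = pipeline.detect_ssa(config, maps, cohort.grid)
    return {"config": config, "cohort": cohort, "maps": maps,
            "detection": detection}
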