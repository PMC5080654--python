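"""Shared fixtures: coarse scan configs and a session-wide calibration.

All simulation in tests uses grids far coarser than the instrument's
2.2 arcmin (typically 30-60 arcmin) to keep runtime at desk scale; the
geometry is unchanged.
"""

import numpy as np
import pytest

from attiscan.normals import ScaleConfig, calibrate_thresholds, planar_calibration_cloud
from attiscan.scenes import PlanePatch, ScanConfig, SceneSpec, SENSOR_HEIGHT_M


def ground_plane(albedo: float = 0.55) -> PlanePatch:
    return PlanePatch(
        center=np.array([0.0, 0.0, -SENSOR_HEIGHT_M]),
        normal=np.array([0.0, 0.0, 1.0]),
        u_axis=np.array([1.0, 0.0, 0.0]),
        v_axis=np.array([0.0, 1.0, 0.0]),
        half_u=500.0,
        half_v=500.0,
        albedo=albedo,
    )


@pytest.fixture(scope="session")
def coarse_config() -> ScanConfig:
    """30 arcmin grid with default noise."""
    return ScanConfig(step_arcmin=30.0)


@pytest.fixture(scope="session")
def noiseless_config() -> ScanConfig:
    return ScanConfig(
        step_arcmin=30.0, range_noise_m=0.0, intensity_noise=0.0, low_intensity_fraction=0.0
    )


@pytest.fixture(scope="session")
def ground_scene() -> SceneSpec:
    return SceneSpec(category="outdoor-built", primitives=(ground_plane(),), seed=0)


@pytest.fixture(scope="session")
def scale_config() -> ScaleConfig:
    return ScaleConfig()


@pytest.fixture(scope="session")
def calibration(scale_config):
    """Thresholds from simulated 1 mm-noise planar scans at three ranges."""
    clouds = [
        planar_calibration_cloud(d, range_noise_m=0.001, step_arcmin=30.0, rng_seed=i)
        for i, d in enumerate((3.0, 10.0, 30.0))
    ]
    return calibrate_thresholds(clouds, scale_config, rng_seed=0)
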