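"""Shared fixtures: small optical configurations and the (reused) expensive
simulation + reconstruction runs that several test modules evaluate."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import fpmscope as fp
from fpmscope.demo import DEFAULT_GEOMETRY, PRESETS, _LADDERS


def config_for(na: float, nominal_mag: float, object_pixel_um: float,
               downsample_factor: int) -> fp.OpticalSystemConfig:
    """Config whose camera pixel is exactly consistent with the simulation
    grid (object pixel * downsample factor)."""
    eff = nominal_mag * 150.0 / 180.0
    return fp.OpticalSystemConfig(
        objective_na=na, nominal_magnification=nominal_mag,
        tube_focal_length_mm=150.0, wavelength_um=0.53,
        camera_pixel_um=object_pixel_um * downsample_factor * eff)


def single_led_plan(wavelength_um: float = 0.53) -> fp.IlluminationPlan:
    return fp.build_illumination_plan(
        fp.LEDArrayGeometry(used_rows=1, used_cols=1), wavelength_um)


# ---------------------------------------------------------------------------
# chromosome-scene reconstruction experiments (0.25 NA, 15x15 LEDs)
# ---------------------------------------------------------------------------

RECOVERY_PIXEL_UM = 0.2
RECOVERY_SHAPE = 128


@pytest.fixture(scope="session")
def chromosome_scene():
    obj, truth = fp.generate_chromosome_phantom(
        3, RECOVERY_PIXEL_UM, seed=7,
        shape=(RECOVERY_SHAPE, RECOVERY_SHAPE), length_range_um=(5, 9))
    cfg = config_for(0.25, 10, RECOVERY_PIXEL_UM, 1)
    plan = fp.build_illumination_plan(DEFAULT_GEOMETRY, cfg.wavelength_um)
    return obj, truth, cfg, plan


@pytest.fixture(scope="session")
def recovery_run(chromosome_scene):
    """Noiseless acquisition + reconstruction with the correct (known) pupil."""
    obj, _, cfg, plan = chromosome_scene
    stack = fp.simulate_acquisition(obj, cfg, plan)
    result = fp.reconstruct(
        stack, upsampling=2,
        options=fp.ReconstructionOptions(max_iterations=30, tolerance=1e-7,
                                         pupil_recovery=False))
    return obj, stack, result


@pytest.fixture(scope="session")
def pupil_recovery_run(chromosome_scene):
    """Planted 10-um defocus aberration, embedded pupil recovery enabled."""
    obj, _, cfg, plan = chromosome_scene
    stack = fp.simulate_acquisition(
        obj, cfg, plan, fp.AcquisitionOptions(defocus_um=10.0))
    result = fp.reconstruct(
        stack, upsampling=2,
        options=fp.ReconstructionOptions(max_iterations=50, tolerance=0.0,
                                         pupil_recovery=True))
    return cfg, stack, result


# ---------------------------------------------------------------------------
# USAF-scene experiments under the 4x/0.1 NA preset
# ---------------------------------------------------------------------------

USAF_RAW_PIXELS = 112
USAF_FACTOR = 4
USAF_UPSAMPLING = 4


@pytest.fixture(scope="session")
def usaf4x_scene():
    cfg = PRESETS["4x"]
    dx = cfg.object_pixel_um / USAF_FACTOR
    n = USAF_RAW_PIXELS * USAF_FACTOR
    obj, index = fp.generate_usaf_phantom(_LADDERS["4x"], dx, shape=(n, n))
    plan = fp.build_illumination_plan(DEFAULT_GEOMETRY, cfg.wavelength_um)
    return obj, index, cfg, plan


@pytest.fixture(scope="session")
def usaf4x_stack(usaf4x_scene):
    obj, index, cfg, plan = usaf4x_scene
    return fp.simulate_acquisition(
        obj, cfg, plan,
        fp.AcquisitionOptions(downsample_factor=USAF_FACTOR))


@pytest.fixture(scope="session")
def usaf4x_recon(usaf4x_stack):
    return fp.reconstruct(
        usaf4x_stack, upsampling=USAF_UPSAMPLING,
        options=fp.ReconstructionOptions(max_iterations=25, tolerance=1e-5))


@pytest.fixture(scope="session")
def usaf4x_defocus_recon(usaf4x_scene):
    """Reconstruction from raw data acquired 20 um out of focus."""
    obj, index, cfg, plan = usaf4x_scene
    stack = fp.simulate_acquisition(
        obj, cfg, plan,
        fp.AcquisitionOptions(downsample_factor=USAF_FACTOR, defocus_um=20.0))
    return fp.reconstruct(
        stack, upsampling=USAF_UPSAMPLING,
        options=fp.ReconstructionOptions(max_iterations=25, tolerance=1e-5))
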