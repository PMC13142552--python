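import numpy as np
import pytest

import filmspec as fs
from filmspec.synthetic import (
    AcquisitionSpec,
    build_reference_library,
    ir_power_profile,
    photobleach_curve,
    random_scene,
    render_stack,
)


@pytest.fixture(scope="session")
def axis64():
    return fs.make_axis(1000, 1800, 64)


@pytest.fixture(scope="session")
def refs64(axis64):
    return build_reference_library("default8", axis64)


@pytest.fixture(scope="session")
def noiseless_scene(axis64, refs64):
    """Hard-disk scene with full instrument response but no noise; exact
    calibration recovery is possible on it."""
    scene = random_scene(shape=(48, 48), n_organelles=8, seed=3)
    scene = fs.SceneSpec(
        shape=scene.shape,
        organelles=scene.organelles,
        background_dye=scene.background_dye,
        background_composition=scene.background_composition,
        feather_px=0.0,
    )
    acq = AcquisitionSpec(
        axis=axis64,
        ir_power=ir_power_profile(axis64, dip_depth=0.4),
        bleach_rate=0.01,
        baseline_offset=0.02,
        ir_off_frames=(0, 1, 2),
        noise_sigma=0.0,
        seed=1,
    )
    stack, truth = render_stack(scene, refs64, acq)
    return scene, acq, stack, truth


@pytest.fixture(scope="session")
def noiseless_calibration_config(noiseless_scene, axis64):
    _, acq, _, _ = noiseless_scene
    return fs.CalibrationConfig(
        ir_power=acq.effective_power(),
        bleach_curve=photobleach_curve(axis64.n_frames, acq.bleach_rate),
        baseline_mode="ir_off_frames",
        ir_off_frames=acq.ir_off_frames,
        smooth_window=1,
        exclude_bands=((1380.0, 1480.0),),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_stack(rng):
    axis = fs.make_axis(1000.0, 1090.0, 10)
    data = rng.uniform(1.0, 2.0, size=(8, 8, 10))
    dc = rng.uniform(0.5, 1.5, size=(8, 8))
    return fs.HyperStack(data, axis, dc=dc, meta={"origin": "test"})
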