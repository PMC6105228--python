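import numpy as np
import pytest

from gravikine.config import RunConfig
from gravikine.simulate import GPParams, LumModel, SimGrid, render_frames, simulate_gp_rod

RASTER = (256, 256)
PIXEL_SCALE = 16.0  # um/px -> 4.1 mm field, fits a 3 mm organ


@pytest.fixture(scope="session")
def gp_traj():
    """Reference GP trajectory: 3 mm organ, default bending parameters."""
    return simulate_gp_rod(GPParams(beta=0.4, gamma=1.5, length=3.0), SimGrid())


@pytest.fixture(scope="session")
def lum_model():
    return LumModel()


@pytest.fixture(scope="session")
def rendered(gp_traj, lum_model):
    """Noisy rendering of the reference trajectory (default noise model)."""
    return render_frames(gp_traj, lum_model, pixel_scale=PIXEL_SCALE,
                         shape=RASTER, seed=7, noise=True)


@pytest.fixture(scope="session")
def rendered_clean(gp_traj, lum_model):
    """Noise-free rendering of the reference trajectory."""
    return render_frames(gp_traj, lum_model, pixel_scale=PIXEL_SCALE,
                         shape=RASTER, seed=7, noise=False)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(length=3.0, raster=RASTER, pixel_scale=PIXEL_SCALE)


@pytest.fixture(scope="session")
def extracted(rendered, run_config):
    """Midlines + fields for the noisy rendering, shared across tests."""
    from gravikine.pipeline import extract_stage, kinematics_stage

    anchor0 = rendered.world_to_image(np.zeros(2))
    midlines, pairs = extract_stage(rendered, run_config, anchor0)
    fields, troughs, heights, sign = kinematics_stage(midlines, run_config)
    return dict(midlines=midlines, pairs=pairs, fields=fields,
                troughs=troughs, heights=heights, turning_sign=sign)
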