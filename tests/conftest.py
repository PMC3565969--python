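import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rbcqpi as rq

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cfg():
    """Default optical configuration (550 nm, 0.125 um pitch, MCHC 33 g/dL)."""
    return rq.OpticalConfig()


@pytest.fixture(scope="session")
def noiseless_model():
    return rq.InterferogramModel(noise_sd=0.0)


@pytest.fixture(scope="session")
def single_cell_scene(cfg):
    """One 90 fL biconcave cell on a clean 512x512 field."""
    spec = rq.CellSpec(
        shape="biconcave", target_volume_fl=90.0, radius_um=3.9, center_xy_um=(32.0, 32.0)
    )
    return rq.build_scene([spec], (512, 512), cfg, aberration_peak_rad=0.0, n_dirt=0, seed=1)


@pytest.fixture(scope="session")
def dirty_scene(cfg):
    """Two cells plus aberration and dirt, for background-subtraction checks."""
    specs = [
        rq.CellSpec("biconcave", 90.0, 3.9, center_xy_um=(20.0, 20.0)),
        rq.CellSpec("spherocyte", 85.0, 3.65, center_xy_um=(45.0, 42.0)),
    ]
    return rq.build_scene(
        specs, (512, 512), cfg, aberration_peak_rad=0.5, n_dirt=10, dirt_peak_rad=1.0, seed=3
    )
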