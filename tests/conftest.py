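import warnings

import numpy as np
import pytest

from onhmorph.phantom import PhantomParams, analytic_truth, generate_surfaces
from onhmorph.regions import REGIONS


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def flat_phantom():
    """Uniform control phantom: flat rim 0.30 mm, untilted, noise-free."""
    return PhantomParams(grid_spacing=0.01)


@pytest.fixture(scope="session")
def asymmetric_phantom():
    """Tilted, sloped phantom with distinct per-region targets."""
    vals = [0.32, 0.30, 0.28, 0.27, 0.31, 0.29, 0.25, 0.33]
    return PhantomParams(
        rim_height_profile=dict(zip(REGIONS, vals)),
        pnfl_profile={r: 0.10 + 0.01 * i for i, r in enumerate(REGIONS)},
        prelamina_thickness_profile={r: 0.35 + 0.02 * i for i, r in enumerate(REGIONS)},
        cup_depth=0.2, lc_depth=0.6, bmo_plane_tilt=3.0, rim_slope=0.15,
        grid_spacing=0.01)


@pytest.fixture(scope="session")
def asymmetric_measurement(asymmetric_phantom):
    from onhmorph.morphometry import measure_eye

    ss = generate_surfaces(asymmetric_phantom, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return (analytic_truth(asymmetric_phantom), measure_eye(ss))


def region_profile(value):
    return {r: float(value) for r in REGIONS}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
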