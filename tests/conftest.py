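import numpy as np
import pytest

from kelpsat import synthdata, unmix


@pytest.fixture(scope="session")
def library():
    return synthdata.gen_endmember_library(n_water=30, n_bands=6, seed=11)


@pytest.fixture(scope="session")
def small_library():
    return synthdata.gen_endmember_library(n_water=5, n_bands=6, seed=11)


@pytest.fixture()
def toy_scene(small_library):
    """A 16x16 noiseless scene with a centered kelp patch and known truth."""
    dates = np.array([np.datetime64("2005-09-15")])
    patch = synthdata.GaussianPatch(center_row=8, center_col=8, sigma_px=3,
                                    peaks=np.array([0.9]))
    spec = synthdata.SceneSpec(n_rows=16, n_cols=16, dates=dates,
                               kelp_patch=patch, noise_sd=0.0,
                               water_variability=0.0, seed=5)
    scenes, truth, clouds = synthdata.gen_scene_series(spec, small_library)
    return scenes[0], truth[0], clouds[0], spec


@pytest.fixture(scope="session")
def grid16():
    return unmix.Grid(n_rows=16, n_cols=16, pixel_size=30.0)
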