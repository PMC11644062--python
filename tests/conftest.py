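import numpy as np
import pytest

from canopyseg import SceneParams, default_library, generate_layout, render


@pytest.fixture(scope="session")
def lib176():
    """Default spectral library on the full 176-band 400-1000 nm grid."""
    return default_library(SceneParams().wavelength_grid())


@pytest.fixture(scope="session")
def make_scene(lib176):
    """Factory rendering a default-parameter scene for a given seed.

    Scenes are cached per (seed, overrides) for the session; callers must not
    mutate the returned objects.
    """
    cache = {}

    def _make(seed=0, **overrides):
        key = (seed, tuple(sorted(overrides.items())))
        if key not in cache:
            params = SceneParams(seed=seed, **overrides)
            layout = generate_layout(params)
            cube, trio = render(layout, lib176, params)
            cache[key] = (cube, trio, layout, params)
        return cache[key]

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20261201)
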