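import numpy as np
import pandas as pd
import pytest

from smtrack.refinement import PSFParams, integrated_gaussian_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spot_image():
    """Noiseless 15x15 rendered spot (N=50, b=10, sigma=1) + its params."""
    p = PSFParams(7.3, 6.8, 50.0, 10.0, 1.0)
    grid = np.arange(15.0)
    return integrated_gaussian_model(grid, grid, p), p


def make_locs(frames, xs, ys, **extra):
    """Small localization DataFrame helper."""
    base = {
        "frame": np.asarray(frames, dtype=int),
        "x": np.asarray(xs, dtype=float),
        "y": np.asarray(ys, dtype=float),
    }
    base.update({k: np.asarray(v) for k, v in extra.items()})
    return pd.DataFrame(base)
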