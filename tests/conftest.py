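"""Shared fixtures: small phantoms and preprocessed runs built at test time."""

import numpy as np
import pytest

from rtnf.paradigm import default_paradigm, make_paradigm
from rtnf.phantom import PhantomSpec, default_patterns, simulate_run
from rtnf.preproc import make_mask, smooth

SMALL_GRID = (16, 16, 10)
VOXEL_MM = (3.0, 3.0, 3.0)


@pytest.fixture(scope="session")
def paper_paradigm():
    """The study design: 9 rest + 8 task blocks of 30 s at TR = 2 s."""
    return default_paradigm()


@pytest.fixture(scope="session")
def tiny_paradigm():
    """3 rest + 2 task blocks of 30 s at TR = 2 s (75 volumes)."""
    return make_paradigm(3, 2, 30.0, 2.0, ["LGO", "RGO"])


def make_phantom(paradigm, seed, amplitude=1.0, noise_sd=1.0, ar1_rho=0.3,
                 drift=None, grid=SMALL_GRID, lateral_weight=0.35):
    spec = PhantomSpec(
        grid=grid,
        paradigm=paradigm,
        patterns=default_patterns(grid, amplitude, lateral_weight=lateral_weight),
        noise_sd=noise_sd,
        ar1_rho=ar1_rho,
        drift=drift,
        seed=seed,
    )
    return simulate_run(spec)


def smooth_series(series, fwhm_mm=8.0, voxel_mm=VOXEL_MM):
    out = np.empty_like(series)
    for t in range(series.shape[-1]):
        out[..., t] = smooth(series[..., t], fwhm_mm, voxel_mm)
    return out


@pytest.fixture(scope="session")
def small_run(tiny_paradigm):
    """(raw series, smoothed series, mask, truth) for a default-noise run."""
    data, truth = make_phantom(tiny_paradigm, seed=11)
    mask = make_mask(data.mean(axis=-1))
    return data, smooth_series(data), mask, truth
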