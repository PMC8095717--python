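"""Shared fixtures: small, fast simulator configurations.

The imaging fixtures run the simulator on reduced frames (96-128 px,
5 slices) so the full pipeline stays fast; the acquisition cadence, noise
model and analysis parameters are the same as at full scale.
"""

import numpy as np
import pytest

from spineltd import (ImagingSimConfig, make_spine_grid,
                      simulate_imaging_experiment)


def clean_imaging_config(**overrides):
    """Noiseless, nuisance-free small-frame configuration."""
    kw = dict(frame_size=(96, 96), z_slices=5, background_level=0.0,
              bleach_rate_per_frame=0.0, fluctuation_sigma=0.0,
              drift_step_sigma=0.0, read_noise_sigma=0.0, shot_noise=False,
              seed=0)
    kw.update(overrides)
    return ImagingSimConfig(**kw)


@pytest.fixture(scope="session")
def clean_sim():
    """Nuisance-free 3-spine simulation with 16% shrinkage + 25% SEP drop."""
    cfg = clean_imaging_config()
    spines = make_spine_grid(cfg, n_spines=3, shrinkage=0.16,
                             sep_surface_drop=0.25)
    series, rois, gt = simulate_imaging_experiment(cfg, spines)
    return cfg, spines, series, rois, gt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
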