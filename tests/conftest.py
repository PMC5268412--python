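"""Shared fixtures: reduced-resolution stimuli and filter runs.

Unit and property tests run at 128 x 128 pixels with 600-1000 particles;
the full 256 x 256 / 2000-particle settings are exercised only by the
acceptance tests.
"""

import dataclasses

import numpy as np
import pytest

import dmbp


@pytest.fixture(scope="session")
def small_model():
    return dataclasses.replace(dmbp.ModelParams(), n_particles=800,
                               grid_step=2.0 / 128.0)


@pytest.fixture(scope="session")
def small_stim():
    return dmbp.standard_params(N_X=128, N_Y=128)


@pytest.fixture(scope="session")
def small_movie(small_stim):
    return dmbp.render_movie(small_stim, 4)


@pytest.fixture(scope="session")
def small_trace(small_movie, small_model):
    return dmbp.run_dmbp(small_movie, small_model, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def tiny_stim(**overrides):
    """A 32-pixel, 20-frame stimulus for grid-oracle tests."""
    base = dict(T=1.0, N_T=20, N_X=32, N_Y=32, dot_size=0.2, V=1.0,
                dot_start=0.1, dot_stop=0.9, I_noise=0.05,
                flash_frames=(8, 9), flash_dy=0.25, C_flash=0.5)
    base.update(overrides)
    return dmbp.StimulusParams(**base)


def tiny_model(**overrides):
    base = dict(delta_t=0.05, tau=0.15, n_particles=800,
                grid_step=2.0 / 32.0)
    base.update(overrides)
    return dataclasses.replace(dmbp.ModelParams(), **base)
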