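"""Shared fixtures: phantom configurations at several scales.

Heavy pipeline products (preprocessed/segmented phantoms) are session-scoped
so multiple tests can share one computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ramanresp import PhantomConfig, generate_phantom, preprocess_cube, segment_cube

ZERO_BASELINE = ((0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0))


def make_small_config(**overrides) -> PhantomConfig:
    """A 60 x 60 pixel phantom: same generative model, smaller cell."""
    defaults = dict(
        field_of_view=30.0,
        pixel_size=0.5,
        cell_semiaxes=(11.0, 8.5),
        nucleus_semiaxes=(4.0, 3.0),
        droplet_count_range=(4, 6),
        droplet_radius_range=(0.8, 1.3),
        seed=42,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


def make_noiseless(config: PhantomConfig) -> PhantomConfig:
    return dataclasses.replace(
        config, noise_sd=0.0, spike_rate=0.0, baseline_coeff_ranges=ZERO_BASELINE
    )


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return make_small_config()


@pytest.fixture(scope="session")
def noiseless_config(small_config) -> PhantomConfig:
    return make_noiseless(small_config)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_config):
    return generate_phantom(noiseless_config, "control")


@pytest.fixture(scope="session")
def noisy_phantom(small_config):
    return generate_phantom(small_config, "control")


@pytest.fixture(scope="session")
def noisy_pre(noisy_phantom):
    cube, _ = noisy_phantom
    return preprocess_cube(cube)


@pytest.fixture(scope="session")
def noiseless_pre(noiseless_phantom):
    cube, _ = noiseless_phantom
    return preprocess_cube(cube)


@pytest.fixture(scope="session")
def noiseless_segmentation(noiseless_pre):
    return segment_cube(noiseless_pre, k=8)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
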