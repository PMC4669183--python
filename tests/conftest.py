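"""Shared fixtures: synthetic phantoms at three scales.

``tiny_truth`` is a coarse 32x40x32 head used by fast unit tests;
``coarse_spec`` builds 64-cube heads for bias-field work; the
session-scoped ``truth128``/``sweep128`` pair is the full-resolution
dataset shared by the segmentation-recovery tests (generated once because
the 31-subset sweep is the most expensive fixture in the suite).
"""

from __future__ import annotations

import numpy as np
import pytest

from mr2plan.fcm_segmentation import FcmParams, make_air_mask, sweep_combinations
from mr2plan.phantom import PhantomSpec, default_sequence_models, generate_phantom

TINY_SPEC = PhantomSpec(
    grid_shape=(32, 40, 32),
    spacing=(1.0, 1.2, 1.0),
    head_axes=(9.0, 14.0, 8.0),
    skull_thickness=1.6,
    scalp_thickness=1.8,
    n_air_cavities=1,
    rostrum_complexity=1,
    seed=7,
)


def coarse_spec(seed: int) -> PhantomSpec:
    """64-cube head with the full-resolution field of view (spacing doubled)."""
    return PhantomSpec(
        grid_shape=(64, 64, 64),
        spacing=(0.55, 1.0, 0.55),
        skull_thickness=1.2,
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_truth():
    return generate_phantom(TINY_SPEC, default_sequence_models())


@pytest.fixture(scope="session")
def tiny_mask(tiny_truth):
    return make_air_mask(tiny_truth.noisy_images["T1"])


@pytest.fixture(scope="session")
def truth128():
    # study conditions for segmentation recovery: 128^3, 5 % Rician noise,
    # no bias field (bias estimation is exercised separately)
    models = default_sequence_models(noise_fraction=0.05, bias_amplitude=0.0)
    return generate_phantom(PhantomSpec(seed=1), models)


@pytest.fixture(scope="session")
def sweep128(truth128):
    mask = make_air_mask(truth128.noisy_images["T1"])
    return sweep_combinations(truth128.noisy_images, mask, FcmParams(seed=0))
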