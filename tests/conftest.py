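"""Shared fixtures: model backends and pre-built surrogates.

Expensive surrogate builds are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from conical.descriptors import DescriptorConfig
from conical.gpr_core import FitOptions
from conical.model_backends import (
    ConeModelBackend,
    ConeModelParams,
    Geometry,
    NoisyBackend,
)
from conical.sampling import SamplingConfig
from conical.surrogate import build_surrogate

CONE_G, CONE_H, CONE_SX, CONE_SY = 0.2, 0.1, 0.05, 0.02
SEAM_CURVATURE = 0.3


@pytest.fixture(scope="session")
def cone_backend():
    """Tilted anisotropic cone with a quadratic seam minimum, 3 coordinates."""
    return ConeModelBackend(
        ConeModelParams(CONE_G, CONE_H, CONE_SX, CONE_SY),
        dimension=3,
        seam_curvature=SEAM_CURVATURE,
    )


@pytest.fixture(scope="session")
def raw_descriptor():
    return DescriptorConfig(kind="raw_model_coordinates")


@pytest.fixture(scope="session")
def origin3():
    return Geometry.from_flat(np.zeros(3))


@pytest.fixture(scope="session")
def clean_surrogate(cone_backend, origin3, raw_descriptor):
    """Noiseless surrogate of the cone+seam model (jitter-pinned noise)."""
    return build_surrogate(
        cone_backend,
        origin3,
        SamplingConfig(n_samples=120, half_width=0.5, seed=3),
        raw_descriptor,
        FitOptions(restarts=8, seed=3, fix_noise=1e-10),
    )


@pytest.fixture(scope="session")
def noisy_surrogate(cone_backend, origin3, raw_descriptor):
    """Same model with deterministic noise of amplitude 1e-3 injected."""
    noisy = NoisyBackend(cone_backend, amplitude=1e-3, key=5)
    return build_surrogate(
        noisy,
        origin3,
        SamplingConfig(n_samples=120, half_width=0.5, seed=4),
        raw_descriptor,
        FitOptions(restarts=8, seed=4),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
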