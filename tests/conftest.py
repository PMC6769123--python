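"""Shared fixtures: random admissible states, small meshes, parameter sets."""

import numpy as np
import pytest

from cardioemx.constitutive import DeformationState, make_frame, make_law


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_frame(rng):
    while True:
        f = rng.standard_normal(3)
        s = rng.standard_normal(3)
        if np.linalg.norm(np.cross(f, s)) > 1e-3:
            return make_frame(f, s)


def random_state(rng, amp=0.12):
    """Random admissible deformation state (det F bounded away from zero,
    strains inside the physical regime of the exponential law)."""
    while True:
        F = np.eye(3) + amp * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.5:
            break
    return DeformationState.from_F(F, random_frame(rng))


@pytest.fixture
def identity_state():
    return DeformationState.from_F(np.eye(3), make_frame([1, 0, 0], [0, 1, 0]))


@pytest.fixture(params=["TIC", "TII", "HO"])
def law(request):
    return make_law(request.param)
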