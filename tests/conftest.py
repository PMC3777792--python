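"""Shared fixtures: the worked-example fiber set and small synthetic
tensor-field geometries used across the test modules."""

import numpy as np
import pytest

from visconn import make_fan_phantom, make_worked_example, oriented_tensor_field

ANISO = (1.7e-3, 0.3e-3, 0.3e-3)


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def slab_field():
    """Straight bundle: uniform x-oriented anisotropic tensors, 20x6x6 mm."""
    shape = (20, 6, 6)
    ori = np.zeros(shape + (3,))
    ori[..., 0] = 1.0
    return oriented_tensor_field(ori, ANISO)


@pytest.fixture(scope="session")
def interface_field():
    """Abrupt 90-degree orientation interface at i = 10 (x- then y-oriented)."""
    shape = (20, 20, 5)
    ori = np.zeros(shape + (3,))
    ori[:10, ..., 0] = 1.0
    ori[10:, ..., 1] = 1.0
    return oriented_tensor_field(ori, ANISO)


@pytest.fixture(scope="session")
def graded_slab_field():
    """x-oriented slab whose anisotropy decays linearly away from the
    mid-plane i = 12 (isotropic at the +/- 12 voxel edges)."""
    shape = (24, 14, 3)
    w = np.clip(1.0 - np.abs(np.indices(shape)[0] - 12.0) / 12.0, 0.0, 1.0)
    lam1 = 0.7e-3 + w * 1.0e-3
    lam23 = 0.7e-3 - w * 0.4e-3
    ev = np.stack([lam1, lam23, lam23], axis=-1)
    ori = np.zeros(shape + (3,))
    ori[..., 0] = 1.0
    return oriented_tensor_field(ori, ev)


@pytest.fixture(scope="session")
def fan_field():
    return make_fan_phantom()
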