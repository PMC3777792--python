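"""Affine and demons registration, histogram matching, inverse warps."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from visconn import (
    AffineParams,
    DisplacementField,
    affine_register,
    approximate_inverse,
    demons_register,
    histogram_match,
)
from visconn.registration import apply_affine, composition_residual


def _blob(shape=(32, 32, 32)):
    x, y, z = np.indices(shape)
    img = np.exp(-(((x - 16) / 6.0) ** 2 + ((y - 14) / 5.0) ** 2
                   + ((z - 16) / 7.0) ** 2))
    img += 0.3 * np.exp(-(((x - 8) / 4.0) ** 2 + ((y - 22) / 4.0) ** 2
                          + ((z - 10) / 4.0) ** 2))
    return img


# ---------------------------------------------------------------------------
# affine


def test_affine_identity():
    img = _blob()
    p = affine_register(img, img, voxel_size=(1, 1, 1))
    np.testing.assert_allclose(p.translation, 0.0, atol=1e-6)
    np.testing.assert_allclose(p.rotation, 0.0, atol=1e-6)
    np.testing.assert_allclose(p.scale, 1.0, atol=1e-6)


def test_affine_recovers_translation():
    img = _blob()
    moved = apply_affine(img, AffineParams(translation=np.array([2.0, 0, 0])),
                         voxel_size=(1, 1, 1))
    with pytest.warns(UserWarning):
        p = affine_register(moved, img, voxel_size=(1, 1, 1))
    # registering the shifted image back: the recovered transform undoes it
    assert p.translation[0] == pytest.approx(-2.0, abs=0.1)
    np.testing.assert_allclose(p.translation[1:], 0.0, atol=0.1)
    np.testing.assert_allclose(p.scale, 1.0, atol=0.02)


def test_affine_recovers_scale():
    img = _blob()
    moved = apply_affine(img, AffineParams(scale=np.array([1.0, 1.1, 1.0])),
                         voxel_size=(1, 1, 1))
    with pytest.warns(UserWarning):
        p = affine_register(moved, img, voxel_size=(1, 1, 1))
    assert p.scale[1] == pytest.approx(1.0 / 1.1, abs=0.02)
    np.testing.assert_allclose(p.scale[[0, 2]], 1.0, atol=0.02)


def test_affine_params_validation():
    with pytest.raises(ValueError):
        AffineParams(scale=np.array([1.0, 0.0, 1.0]))
    m = AffineParams().matrix()
    np.testing.assert_array_equal(m, np.eye(4))


# ---------------------------------------------------------------------------
# histogram matching


def test_histogram_match_moments():
    rng = np.random.default_rng(0)
    a = rng.normal(5, 2, (16, 16, 16))
    b = rng.normal(10, 4, (16, 16, 16))
    m = histogram_match(a, b)
    assert m.mean() == pytest.approx(b.mean(), rel=1e-6)
    assert m.std() == pytest.approx(b.std(), rel=1e-6)
    # monotone: ranking preserved
    assert np.array_equal(np.argsort(a.ravel()), np.argsort(m.ravel()))


def test_histogram_match_constant_source_warns():
    with pytest.warns(UserWarning, match="constant"):
        out = histogram_match(np.ones((4, 4, 4)), np.random.rand(4, 4, 4))
    np.testing.assert_array_equal(out, 1.0)
    with pytest.raises(ValueError):
        histogram_match(np.empty((0, 1, 1)), np.ones((2, 2, 2)))


# ---------------------------------------------------------------------------
# demons


def test_demons_reduces_mse():
    fixed = _blob()
    x, y, z = np.indices(fixed.shape)
    env = np.exp(-(((x - 16) / 10.0) ** 2 + ((y - 16) / 10.0) ** 2
                   + ((z - 16) / 10.0) ** 2))
    coords = np.stack([x + 1.5 * env, y, z]).astype(float)
    moving = map_coordinates(fixed, coords, order=1)

    d = demons_register(fixed, moving, voxel_size=(1, 1, 1), n_iter=60)
    warped = map_coordinates(
        moving,
        np.stack([x + d.disp[..., 0], y + d.disp[..., 1], z + d.disp[..., 2]]),
        order=1,
    )
    mse0 = np.mean((fixed - moving) ** 2)
    mse1 = np.mean((fixed - warped) ** 2)
    assert mse1 < 0.1 * mse0
    # iteration log tracks the pre-update MSE and is monotone overall
    assert d.iteration_log[-1] < d.iteration_log[0]


def test_demons_identical_images_zero_field():
    fixed = _blob((16, 16, 16))
    d = demons_register(fixed, fixed, voxel_size=(1, 1, 1), n_iter=10)
    assert np.abs(d.disp).max() == 0.0


def test_demons_fully_frozen_is_noop():
    fixed = _blob((16, 16, 16))
    moving = np.roll(fixed, 1, axis=0)
    d = demons_register(fixed, moving,
                        lesion_mask=np.ones(fixed.shape, dtype=bool),
                        voxel_size=(1, 1, 1), n_iter=10)
    assert np.abs(d.disp).max() == 0.0


def test_demons_lesion_frozen_locally():
    """Voxels mapping into the lesion receive no update while free tissue
    still registers."""
    fixed = _blob((24, 24, 24))
    moving = np.roll(fixed, 1, axis=0)
    lesion = np.zeros(fixed.shape, dtype=bool)
    lesion[10:14, 10:14, 10:14] = True
    d = demons_register(fixed, moving, lesion_mask=lesion,
                        voxel_size=(1, 1, 1), n_iter=20)
    # field starts at zero so frozen voxels (mapping to themselves, inside
    # the lesion) never move
    assert np.abs(d.disp[11:13, 11:13, 11:13]).max() == 0.0
    assert np.abs(d.disp[~lesion]).max() > 0.0


# ---------------------------------------------------------------------------
# displacement fields and inversion


def test_displacement_field_validation():
    with pytest.raises(ValueError):
        DisplacementField(np.zeros((4, 4, 4)))
    with pytest.raises(ValueError):
        DisplacementField(np.full((2, 2, 2, 3), np.nan))
    f = DisplacementField(np.zeros((2, 2, 2, 3)))
    with pytest.raises(ValueError, match="residual"):
        f.residual_stats


def test_inverse_of_uniform_translation_exact():
    disp = np.zeros((24, 24, 24, 3))
    disp[..., 0] = 1.2
    inv = approximate_inverse(DisplacementField(disp, (1.0, 1.0, 1.0)),
                              iterations=10, fwhm_mm=2.0)
    interior = inv.disp[4:-4, 4:-4, 4:-4]
    np.testing.assert_allclose(interior[..., 0], -1.2, atol=1e-9)
    np.testing.assert_allclose(interior[..., 1:], 0.0, atol=1e-9)
    mean, _ = inv.residual_stats
    assert mean < 0.01  # residual concentrated at the clamped boundary


def test_inverse_sinusoid_residual_non_increasing():
    shape = (32, 32, 32)
    xx = np.indices(shape)[0].astype(float)
    disp = np.zeros(shape + (3,))
    disp[..., 0] = 2.0 * np.sin(2 * np.pi * xx / 32.0)
    fwd = DisplacementField(disp, (1.0, 1.0, 1.0))
    inv = approximate_inverse(fwd, iterations=10, fwhm_mm=2.0)
    log = inv.iteration_log
    assert len(log) == 10
    assert all(log[i + 1] <= log[i] + 1e-9 for i in range(9))
    assert log[-1] < 0.25 * 2.0  # well under the 2 mm amplitude
    # residual map consistent with composition_residual
    np.testing.assert_allclose(
        inv.residual, composition_residual(fwd, inv), atol=1e-12
    )


def test_displacement_sample_clamps():
    disp = np.zeros((4, 4, 4, 3))
    disp[..., 1] = 3.0
    f = DisplacementField(disp, (1.0, 1.0, 1.0))
    out, clamped = f.sample(np.array([[2.0, 2.0, 2.0], [99.0, 2.0, 2.0]]),
                            count_clamped=True)
    np.testing.assert_allclose(out[:, 1], 3.0)
    assert clamped == 1
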