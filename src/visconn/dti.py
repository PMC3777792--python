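"""Diffusion tensor estimation and scalar maps (FA, MD).

The diffusion-weighted signal at b-value ``b`` along a unit gradient ``g`` is
modelled as ``S = S0 * exp(-b * g^T D g)`` with ``D`` the symmetric 3x3
diffusion tensor.  Per voxel the apparent diffusion coefficient along each
direction, ``ADC_k = -(1/b) ln(S_k / S0)``, is fit to the six unique tensor
elements by ordinary least squares, and the tensor is diagonalised into
eigenvalues (sorted descending, lambda1 >= lambda2 >= lambda3) and orthonormal
eigenvectors.  Mean diffusivity is the eigenvalue mean; fractional anisotropy
is the normalised eigenvalue dispersion (Basser's formula), in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusionVolume",
    "TensorField",
    "ScalarMap",
    "fit_tensor",
    "compute_fa",
    "compute_md",
    "fa_from_eigenvalues",
    "md_from_eigenvalues",
    "tensor_design_matrix",
]

#: order of the six unique tensor elements used throughout the package
TENSOR_ELEMENTS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")

_UNIT_TOL = 1e-6


@dataclass
class DiffusionVolume:
    """A 4D diffusion-weighted acquisition.

    Parameters
    ----------
    data:
        Signal array, shape ``(nx, ny, nz, n_volumes)``; non-negative.
    bvals:
        Per-volume b-value (s/mm^2); zero flags the unweighted (b0) channel.
    bvecs:
        Per-volume unit gradient direction, shape ``(n_volumes, 3)``;
        ignored (conventionally zero) for b0 channels.
    voxel_size:
        Voxel edge lengths in mm.
    affine:
        4x4 voxel-to-world matrix (NIfTI convention).
    """

    data: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, volumes)")
        n = self.data.shape[3]
        if self.bvals.shape[0] != n or self.bvecs.shape[0] != n:
            raise ValueError(
                f"gradient table ({self.bvals.shape[0]} bvals, "
                f"{self.bvecs.shape[0]} bvecs) does not match "
                f"{n} volumes in the DWI data"
            )
        if np.any(self.data < 0):
            raise ValueError("DWI signals must be non-negative")
        b0 = self.bvals == 0
        if not np.any(b0):
            raise ValueError("no b0 (unweighted) channel in gradient table")
        norms = np.linalg.norm(self.bvecs[~b0], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("diffusion gradient directions must be unit-norm")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_directions(self) -> int:
        return int(np.count_nonzero(~self.b0_mask))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class TensorField:
    """Per-voxel diffusion tensors with eigendecomposition.

    ``tensor`` holds the six unique elements in :data:`TENSOR_ELEMENTS` order.
    ``evals`` are sorted descending; ``evecs[..., :, i]`` is the eigenvector of
    ``evals[..., i]``.  ``valid`` marks voxels where the fit was defined;
    ``nonphysical`` flags fitted voxels with a negative eigenvalue (possible
    under noise) which are retained for FA/MD arithmetic but auditable.
    """

    tensor: np.ndarray
    evals: np.ndarray
    evecs: np.ndarray
    valid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    nonphysical: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        if self.nonphysical is None:
            self.nonphysical = np.any(self.evals < 0, axis=-1) & self.valid

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.evals.shape[:3]

    @property
    def principal_direction(self) -> np.ndarray:
        """Unit eigenvector of the largest eigenvalue, shape (..., 3)."""
        return self.evecs[..., :, 0]


@dataclass
class ScalarMap:
    """A named 3D scalar image (FA, MD, VISC, fiber_count, ...)."""

    values: np.ndarray
    name: str
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ScalarMap values must be 3D")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)


def tensor_design_matrix(bvecs: np.ndarray) -> np.ndarray:
    """Design matrix mapping the 6 tensor elements to per-direction ADCs.

    Row k is ``[gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]`` so that
    ``B @ d = g^T D g`` for ``d`` in :data:`TENSOR_ELEMENTS` order.
    """
    g = np.asarray(bvecs, dtype=float)
    return np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def _tensor_elements_to_matrices(d: np.ndarray) -> np.ndarray:
    """(..., 6) unique elements -> (..., 3, 3) symmetric matrices."""
    out = np.empty(d.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = d[..., 0]
    out[..., 1, 1] = d[..., 1]
    out[..., 2, 2] = d[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d[..., 5]
    return out


def fit_tensor(dwi: DiffusionVolume) -> TensorField:
    """Fit the diffusion tensor per voxel by log-linear least squares.

    Voxels with non-positive b0 or any non-positive diffusion-weighted
    signal are masked invalid (the log transform is undefined there), not
    raised on.

    Raises
    ------
    ValueError
        If fewer than 6 diffusion directions are supplied or the direction
        set is rank-deficient (collinear/coplanar configurations).
    """
    b0 = dwi.b0_mask
    if dwi.n_directions < 6:
        raise ValueError(
            f"tensor fit requires >= 6 diffusion directions, got {dwi.n_directions}"
        )
    gdirs = dwi.bvecs[~b0]
    bvals = dwi.bvals[~b0]
    design = tensor_design_matrix(gdirs)
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("gradient direction set is rank-deficient for a tensor fit")

    # multiple b0 volumes (not the usual protocol) are averaged
    s0 = dwi.data[..., b0].mean(axis=-1)
    sk = dwi.data[..., ~b0]

    valid = (s0 > 0) & np.all(sk > 0, axis=-1)
    shape = dwi.shape
    n_vox = int(np.prod(shape))
    adc = np.zeros((n_vox, bvals.shape[0]))
    flat_valid = valid.reshape(-1)
    if np.any(flat_valid):
        sk_v = sk.reshape(n_vox, -1)[flat_valid]
        s0_v = s0.reshape(-1)[flat_valid][:, None]
        adc[flat_valid] = -np.log(sk_v / s0_v) / bvals[None, :]

    pinv = np.linalg.pinv(design)
    d_flat = adc @ pinv.T  # (n_vox, 6)
    d_flat[~flat_valid] = 0.0
    tensor = d_flat.reshape(shape + (6,))

    mats = _tensor_elements_to_matrices(tensor)
    evals, evecs = np.linalg.eigh(mats)  # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., :, ::-1]

    return TensorField(
        tensor=tensor,
        evals=evals,
        evecs=evecs,
        valid=valid,
        voxel_size=dwi.voxel_size,
        affine=dwi.affine,
    )


def md_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Mean diffusivity: (lambda1 + lambda2 + lambda3) / 3."""
    return np.asarray(evals, dtype=float).mean(axis=-1)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalues; 0 where all eigenvalues are 0.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||
    """
    lam = np.asarray(evals, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    out = np.zeros(lam.shape[:-1])
    nz = den > 0
    out[nz] = np.sqrt(1.5) * num[nz] / den[nz]
    return out


def compute_md(tfield: TensorField) -> ScalarMap:
    """Mean-diffusivity map; invalid voxels carry 0 and are masked."""
    md = md_from_eigenvalues(tfield.evals)
    md = np.where(tfield.valid, md, 0.0)
    return ScalarMap(
        md, "MD", voxel_size=tfield.voxel_size, affine=tfield.affine, valid=tfield.valid
    )


def compute_fa(tfield: TensorField) -> ScalarMap:
    """Fractional-anisotropy map; invalid voxels carry 0 and are masked."""
    fa = fa_from_eigenvalues(tfield.evals)
    fa = np.where(tfield.valid, fa, 0.0)
    return ScalarMap(
        fa, "FA", voxel_size=tfield.voxel_size, affine=tfield.affine, valid=tfield.valid
    )
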