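"""Lesion-aware image registration utilities.

Pipeline pieces for aligning a subject brain to a reference: a nine-parameter
affine (3 translations, 3 rotations, 3 scales) optimised by gradient descent
on a mean-squared-difference cost over a coarse-to-fine resolution schedule;
histogram matching for cross-contrast alignment; a demons-style deformable
registration in which displacements that map into a manually delineated
lesion mask are frozen and the per-iteration Gaussian regularisation is made
edge-preserving (normalised convolution that never mixes displacements across
the frozen/free boundary, so tissue around the lesion registers while the
lesion region keeps its features); and an iterative approximation of the
inverse displacement field (small-deformation demons fields are not
analytically invertible).

Displacement fields map fixed-grid voxel centers (mm) to offsets toward the
moving image: the moving image is resampled at ``x + u(x)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.exposure import match_histograms as _match_histograms

__all__ = [
    "AffineParams",
    "DisplacementField",
    "affine_register",
    "histogram_match",
    "demons_register",
    "approximate_inverse",
    "composition_residual",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class AffineParams:
    """Nine-parameter affine: translations (mm), rotations (rad), scales."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    converged: bool = True

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("affine scales must be positive")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation, self.scale])

    @classmethod
    def from_vector(cls, v: np.ndarray, converged: bool = True) -> "AffineParams":
        v = np.asarray(v, dtype=float)
        return cls(v[:3], v[3:6], v[6:9], converged=converged)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix T @ R @ S (rotations about x, y, z)."""
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        r_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        r_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        r_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        m = np.eye(4)
        m[:3, :3] = r_z @ r_y @ r_x @ np.diag(self.scale)
        m[:3, 3] = self.translation
        return m


@dataclass
class DisplacementField:
    """Per-voxel 3D displacement (mm) on the fixed grid.

    ``disp`` has shape ``(nx, ny, nz, 3)``.  ``residual`` (optional) is the
    per-voxel magnitude of the forward-then-inverse composition error when
    the field was produced by :func:`approximate_inverse`.
    """

    disp: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    residual: np.ndarray | None = None
    iteration_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx,ny,nz,3)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement field must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp.shape[:3]

    @property
    def residual_stats(self) -> tuple[float, float]:
        """Mean and sd (mm) of the composition residual magnitude."""
        if self.residual is None:
            raise ValueError("no residual map attached to this field")
        return float(self.residual.mean()), float(self.residual.std())

    def sample(self, points: np.ndarray, count_clamped: bool = False):
        """Trilinear displacement at mm points (clamped to the lattice)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vs = np.asarray(self.voxel_size)
        u = pts / vs - 0.5
        hi = np.asarray(self.shape) - 1.0
        clamped = int(np.count_nonzero(np.any((u < 0) | (u > hi), axis=1)))
        u = np.clip(u, 0.0, hi)
        out = np.stack(
            [
                ndimage.map_coordinates(self.disp[..., d], u.T, order=1, mode="nearest")
                for d in range(3)
            ],
            axis=-1,
        )
        if count_clamped:
            return out, clamped
        return out


# ---------------------------------------------------------------------------
# helpers


def _grid_coords_mm(shape, voxel_size) -> np.ndarray:
    """(nx,ny,nz,3) voxel-center coordinates in mm."""
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, voxel_size)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _mm_to_index(points_mm: np.ndarray, voxel_size) -> np.ndarray:
    return points_mm / np.asarray(voxel_size) - 0.5


def _resample_moving(moving: np.ndarray, coords_mm: np.ndarray, voxel_size) -> np.ndarray:
    idx = _mm_to_index(coords_mm, voxel_size)
    return ndimage.map_coordinates(
        moving, [idx[..., d] for d in range(3)], order=1, mode="nearest"
    )


# ---------------------------------------------------------------------------
# affine registration


def _affine_cost(params_vec, fixed, moving, voxel_size, center) -> float:
    p = AffineParams.from_vector(params_vec)
    m = p.matrix()
    coords = _grid_coords_mm(fixed.shape, voxel_size) - center
    mapped = coords @ m[:3, :3].T + m[:3, 3] + center
    warped = _resample_moving(moving, mapped, voxel_size)
    return float(np.mean((warped - fixed) ** 2))


def affine_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    voxel_size=(1.0, 1.0, 1.0),
    init: AffineParams | None = None,
    resolutions_mm=(4.0, 2.0, 1.0),
    max_iter: int = 100,
    tol: float = 1e-10,
) -> AffineParams:
    """Nine-parameter affine registration by gradient descent on MSE.

    A coarse-to-fine schedule smooths and subsamples both images to each
    stated resolution; at each level a finite-difference gradient descent
    with backtracking updates the parameters.  Transforms pivot about the
    volume center.  Deterministic given a fixed initialisation.  If the
    finest level fails to converge, the best parameters so far are returned
    with ``converged=False`` (a warning is issued).
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    p = (init or AffineParams()).as_vector()
    # finite-difference scales: mm for translation, rad for rotation, unitless
    eps = np.array([0.1] * 3 + [0.002] * 3 + [0.002] * 3)
    converged = False

    for res in resolutions_mm:
        factor = np.maximum(vs / res, 1e-6)
        if np.all(factor < 0.999):
            sigma = 0.5 / factor
            fix_s = ndimage.zoom(ndimage.gaussian_filter(fixed, sigma), factor, order=1)
            mov_s = ndimage.zoom(ndimage.gaussian_filter(moving, sigma), factor, order=1)
            vs_level = vs / factor * 1.0
            # zoom changes the grid; recompute effective voxel size
            vs_level = vs * np.asarray(fixed.shape) / np.asarray(fix_s.shape)
        else:
            fix_s, mov_s, vs_level = fixed, moving, vs
        center = np.asarray(fix_s.shape) * vs_level / 2.0

        step = 1.0
        cost = _affine_cost(p, fix_s, mov_s, vs_level, center)
        converged = False
        for _ in range(max_iter):
            grad = np.zeros(9)
            for k in range(9):
                dp = np.zeros(9)
                dp[k] = eps[k]
                c_plus = _affine_cost(p + dp, fix_s, mov_s, vs_level, center)
                c_minus = _affine_cost(p - dp, fix_s, mov_s, vs_level, center)
                grad[k] = (c_plus - c_minus) / (2 * eps[k])
            gnorm = np.linalg.norm(grad * eps)
            if gnorm == 0:
                converged = True
                break
            direction = -grad * eps**2 / gnorm  # scaled steepest descent
            improved = False
            while step > 1e-6:
                trial = p + step * direction
                if np.any(trial[6:9] <= 0):
                    step *= 0.5
                    continue
                c_trial = _affine_cost(trial, fix_s, mov_s, vs_level, center)
                if c_trial < cost - tol:
                    p, cost = trial, c_trial
                    improved = True
                    step *= 1.2
                    break
                step *= 0.5
            if not improved:
                converged = True
                break

    if not converged:
        warnings.warn(
            "affine registration did not converge; returning best parameters",
            stacklevel=2,
        )
    return AffineParams.from_vector(p, converged=converged)


def apply_affine(
    moving: np.ndarray, params: AffineParams, voxel_size=(1.0, 1.0, 1.0)
) -> np.ndarray:
    """Resample the moving image through the affine (fixed-grid output)."""
    vs = np.asarray(voxel_size, dtype=float)
    center = np.asarray(moving.shape) * vs / 2.0
    m = params.matrix()
    coords = _grid_coords_mm(moving.shape, vs) - center
    mapped = coords @ m[:3, :3].T + m[:3, 3] + center
    return _resample_moving(np.asarray(moving, dtype=float), mapped, vs)


# ---------------------------------------------------------------------------
# histogram matching


def histogram_match(source: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Monotone intensity remap so source quantiles match the reference.

    A constant source carries no rank information and is returned unchanged
    with a warning.
    """
    source = np.asarray(source, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if source.size == 0 or reference.size == 0:
        raise ValueError("histogram matching requires nonempty images")
    if np.ptp(source) == 0:
        warnings.warn("constant source image; histogram match is a no-op", stacklevel=2)
        return source.copy()
    return _match_histograms(source, reference)


# ---------------------------------------------------------------------------
# demons registration


def _edge_preserving_smooth(
    disp: np.ndarray, frozen: np.ndarray, sigma_vox: np.ndarray
) -> np.ndarray:
    """Gaussian smoothing by normalised convolution over free voxels only.

    Frozen voxels keep their displacement; free-voxel smoothing assigns zero
    weight to frozen voxels so no displacement leaks across the boundary.
    """
    w = (~frozen).astype(float)
    den = ndimage.gaussian_filter(w, sigma_vox, mode="nearest")
    out = disp.copy()
    free = ~frozen
    for d in range(3):
        num = ndimage.gaussian_filter(disp[..., d] * w, sigma_vox, mode="nearest")
        vals = np.where(den > 1e-12, num / np.maximum(den, 1e-12), disp[..., d])
        out[..., d] = np.where(free, vals, disp[..., d])
    return out


def demons_register(
    fixed: np.ndarray,
    moving: np.ndarray,
    lesion_mask: np.ndarray | None = None,
    voxel_size=(1.0, 1.0, 1.0),
    n_iter: int = 50,
    smooth_fwhm_mm: float = 2.0,
    init: DisplacementField | None = None,
) -> DisplacementField:
    """Demons deformable registration with lesion freezing.

    Classic fixed-image-gradient demons force with the stabilised
    denominator: ``du = -(m(x+u) - f) grad f / (|grad f|^2 + (m(x+u)-f)^2)``,
    skipped on zero-gradient plateaus.  Voxels whose current mapping
    ``x + u(x)`` lands inside the lesion mask (defined in the moving/subject
    space) are frozen: their update is skipped and the edge-preserving
    regularisation never mixes displacements across the frozen boundary.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    sigma_vox = smooth_fwhm_mm * _FWHM_TO_SIGMA / vs

    if init is not None:
        u = init.disp.copy()
    else:
        u = np.zeros(fixed.shape + (3,))
    coords = _grid_coords_mm(fixed.shape, vs)
    grad_f = np.stack(np.gradient(fixed, *vs), axis=-1)
    gnorm2 = (grad_f**2).sum(axis=-1)
    log = []

    for _ in range(n_iter):
        mapped = coords + u
        warped = _resample_moving(moving, mapped, vs)
        diff = warped - fixed
        denom = gnorm2 + diff**2
        ok = denom > 1e-12
        force = np.zeros_like(u)
        scale = np.where(ok, -diff / np.where(ok, denom, 1.0), 0.0)
        force = grad_f * scale[..., None]

        if lesion_mask is not None:
            idx = _mm_to_index(mapped, vs)
            in_lesion = (
                ndimage.map_coordinates(
                    np.asarray(lesion_mask, dtype=float),
                    [idx[..., d] for d in range(3)],
                    order=0,
                    mode="nearest",
                )
                > 0.5
            )
        else:
            in_lesion = np.zeros(fixed.shape, dtype=bool)

        u_new = u + np.where(in_lesion[..., None], 0.0, force)
        u = _edge_preserving_smooth(u_new, in_lesion, sigma_vox)
        log.append(float(np.mean(diff**2)))

    return DisplacementField(disp=u, voxel_size=tuple(vs), iteration_log=log)


# ---------------------------------------------------------------------------
# inverse displacement approximation


def composition_residual(
    forward: DisplacementField, inverse: DisplacementField
) -> np.ndarray:
    """Per-voxel magnitude (mm) of ``u(x) + u_inv(x + u(x))`` — how far the
    forward-then-inverse composition misses the identity."""
    coords = _grid_coords_mm(forward.shape, forward.voxel_size)
    mapped = coords + forward.disp
    inv_at = inverse.sample(mapped.reshape(-1, 3)).reshape(forward.disp.shape)
    return np.linalg.norm(forward.disp + inv_at, axis=-1)


def approximate_inverse(
    field: DisplacementField,
    iterations: int = 10,
    fwhm_mm: float = 2.0,
) -> DisplacementField:
    """Iteratively approximate the inverse of a displacement field.

    The inverse is initialised to zero.  Each iteration forces the inverse
    at every forward-mapped location ``y = x + u(x)`` to point back to ``x``
    (values scattered onto the grid with trilinear weights; collisions
    averaged; out-of-domain targets clamped to the nearest grid node), then
    smooths the field with a Gaussian of the stated FWHM to repair the
    inhomogeneous scatter.  The returned field carries the per-voxel
    composition-residual magnitude map and an iteration log of its mean.
    """
    vs = np.asarray(field.voxel_size, dtype=float)
    shape = field.shape
    coords = _grid_coords_mm(shape, vs)
    y = coords + field.disp  # forward-mapped locations (fixed once)
    target = -field.disp.reshape(-1, 3)  # inverse should map y back to x

    # trilinear scatter weights for the forward-mapped points
    idx = _mm_to_index(y.reshape(-1, 3), vs)
    hi = np.asarray(shape) - 1.0
    idx = np.clip(idx, 0.0, hi)  # nearest-grid assignment outside the domain
    i0 = np.clip(np.floor(idx).astype(np.int64), 0, np.maximum(np.asarray(shape) - 2, 0))
    f = np.clip(idx - i0, 0.0, 1.0)

    num = np.zeros(shape + (3,))
    den = np.zeros(shape)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ii = np.minimum(i0[:, 0] + dx, shape[0] - 1)
                jj = np.minimum(i0[:, 1] + dy, shape[1] - 1)
                kk = np.minimum(i0[:, 2] + dz, shape[2] - 1)
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                lin = np.ravel_multi_index((ii, jj, kk), shape)
                np.add.at(den.reshape(-1), lin, w)
                for d in range(3):
                    np.add.at(num.reshape(-1, 3)[:, d], lin, w * target[:, d])

    hit = den > 1e-12
    scatter = np.zeros(shape + (3,))
    scatter[hit] = num[hit] / den[hit][:, None]

    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / vs
    inv = np.zeros(shape + (3,))
    log = []
    for _ in range(iterations):
        # force the inverse at forward-mapped locations to point back
        forced = np.where(hit[..., None], scatter, inv)
        inv = np.stack(
            [ndimage.gaussian_filter(forced[..., d], sigma_vox, mode="nearest") for d in range(3)],
            axis=-1,
        )
        res = composition_residual(field, DisplacementField(inv, tuple(vs)))
        log.append(float(res.mean()))

    inv_field = DisplacementField(disp=inv, voxel_size=tuple(vs), iteration_log=log)
    inv_field.residual = composition_residual(field, inv_field)
    return inv_field
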