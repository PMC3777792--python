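"""Synthetic diffusion phantoms, lesioned variants, cohorts, and the
six-voxel worked-example fiber fixture.

The forward model is Stejskal-Tanner attenuation: per voxel and unit
gradient ``g``, ``S = S0 exp(-b g^T D g)``.  Rician noise (when requested)
adds two independent Gaussian channels of the stated sigma to the complex
signal and takes the magnitude, matching magnitude MR reconstruction.

Phantoms are built from fiber-bundle specifications: tube-shaped regions
around a polyline centerline whose tensors are cylindrically anisotropic
(lambda1 along the local tangent), embedded in an isotropic background.
An optional lesion (box or sphere) overwrites the contained voxels with an
isotropic tensor of elevated mean diffusivity, mimicking the raised
diffusivity of chronic stroke lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import VoxelGrid
from .dti import DiffusionVolume, TensorField
from .tractography import FiberSet, Streamline

__all__ = [
    "BundleSpec",
    "LesionSpec",
    "PhantomSpec",
    "WorkedExampleFixture",
    "make_worked_example",
    "synthesize_dwi",
    "generate_phantom",
    "generate_cohort",
    "make_fan_phantom",
    "oriented_tensor_field",
    "uniform_gradient_directions",
]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class BundleSpec:
    """A tube-shaped fiber bundle.

    centerline: polyline (mm) of at least two points.
    radius_mm: tube radius around the centerline.
    eigenvalues: on-bundle tensor eigenvalues (mm^2/s), lambda1 along the
        local tangent, lambda2 = lambda3 transverse.
    """

    centerline: tuple
    radius_mm: float
    eigenvalues: tuple[float, float, float] = (1.7e-3, 0.3e-3, 0.3e-3)

    def __post_init__(self) -> None:
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[0] < 2 or cl.shape[1] != 3:
            raise ValueError("centerline must be >= 2 3D points")
        if self.radius_mm <= 0:
            raise ValueError("bundle radius must be positive")
        if any(ev <= 0 for ev in self.eigenvalues):
            raise ValueError("bundle eigenvalues must be positive")


@dataclass(frozen=True)
class LesionSpec:
    """Box or sphere region (voxel coordinates) overwritten with an
    isotropic tensor of ``md_factor`` times the background MD."""

    kind: str  # "box" | "sphere"
    center_vox: tuple[float, float, float]
    size_vox: float | tuple[float, float, float]
    md_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("box", "sphere"):
            raise ValueError("lesion kind must be 'box' or 'sphere'")

    def mask(self, shape) -> np.ndarray:
        idx = np.indices(shape).astype(float)
        c = np.asarray(self.center_vox, dtype=float)
        if self.kind == "sphere":
            r = float(self.size_vox)  # radius in voxels
            d2 = sum((idx[d] - c[d]) ** 2 for d in range(3))
            m = d2 <= r**2
        else:
            half = np.broadcast_to(np.asarray(self.size_vox, dtype=float), (3,)) / 2.0
            m = np.ones(shape, dtype=bool)
            for d in range(3):
                m &= np.abs(idx[d] - c[d]) <= half[d]
        return m


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; a fixed seed makes outputs bit-reproducible."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bundles: tuple = ()
    background_eigenvalue: float = 0.7e-3
    lesion: LesionSpec | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape):
            raise ValueError("grid dimensions must be >= 1")
        if self.lesion is not None:
            c = np.asarray(self.lesion.center_vox)
            if np.any(c < 0) or np.any(c >= np.asarray(self.shape)):
                raise ValueError("lesion center must lie within the grid")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.shape, self.voxel_size)


# ---------------------------------------------------------------------------
# worked-example fixture


@dataclass
class WorkedExampleFixture:
    """Three polyline fibers on a 3x2x1 grid reproducing the six-voxel
    worked connectivity example.

    The fibers' penetrated-voxel sets are {A,B,C}, {D,B,E} and {C,F}, the
    minimal three-fiber realisation consistent with the stated neighbor
    relations: B, C are voxel A's direct neighbors; D, E, F its indirect
    neighbors with direct-connection counts 2, 2 and 1 (total 5), giving
    VISC(A) = 5/3 at alpha = 1.
    """

    fibers: FiberSet
    grid: VoxelGrid
    voxel_index: dict  # letter -> linear voxel index

    def linear_index(self, letter: str) -> int:
        return self.voxel_index[letter]


def make_worked_example() -> WorkedExampleFixture:
    """Build the six-voxel worked-example fiber set (see :class:`WorkedExampleFixture`)."""
    grid = VoxelGrid(shape=(3, 2, 1), voxel_size=(1.0, 1.0, 1.0))
    letters = {
        "A": (0, 0, 0),
        "B": (1, 0, 0),
        "C": (2, 0, 0),
        "D": (0, 1, 0),
        "E": (1, 1, 0),
        "F": (2, 1, 0),
    }
    centers = {k: grid.center_of(np.array(v)) for k, v in letters.items()}

    def fiber(*names: str) -> Streamline:
        return Streamline(points=np.array([centers[n] for n in names]))

    fibers = FiberSet(
        streamlines=[fiber("A", "B", "C"), fiber("D", "B", "E"), fiber("C", "F")],
        space="reference",
    )
    voxel_index = {k: int(grid.ravel(np.array(v))) for k, v in letters.items()}
    return WorkedExampleFixture(fibers=fibers, grid=grid, voxel_index=voxel_index)


# ---------------------------------------------------------------------------
# forward signal model


def uniform_gradient_directions(n: int = 25, seed: int = 7) -> np.ndarray:
    """Approximately uniformly spread unit directions on the hemisphere,
    via electrostatic repulsion from a seeded random start (deterministic)."""
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    for _ in range(200):
        # antipodally symmetric repulsion
        force = np.zeros_like(g)
        for s in (1.0, -1.0):
            diff = g[:, None, :] - s * g[None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
            np.fill_diagonal(dist, np.inf)
            force += (diff / (dist**3 + 1e-12)[..., None]).sum(axis=1)
        g = g + 0.05 * force
        g /= np.linalg.norm(g, axis=1, keepdims=True)
    g[g[:, 2] < 0] *= -1.0
    return g


def synthesize_dwi(
    tensor_field: TensorField,
    gradient_table: np.ndarray,
    b_value: float = 1000.0,
    s0: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DiffusionVolume:
    """Simulate a DWI volume from a tensor field (Stejskal-Tanner model).

    One leading b0 channel is produced followed by the diffusion-weighted
    channels.  Rician noise of ``noise_sigma`` (signal units) is added when
    positive, using the stated seed.

    Raises
    ------
    ValueError
        For non-unit gradients or non-positive-definite tensors.
    """
    if b_value <= 0:
        raise ValueError("b-value must be positive")
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    g = np.asarray(gradient_table, dtype=float).reshape(-1, 3)
    if np.any(np.abs(np.linalg.norm(g, axis=1) - 1.0) > 1e-6):
        raise ValueError("gradient directions must be unit-norm")
    evals = tensor_field.evals
    # zero tensors are allowed (no diffusion); negative eigenvalues are not
    if np.any(evals < 0):
        raise ValueError("tensor field contains non-positive-definite tensors")

    # g^T D g from the 6 unique elements
    d = tensor_field.tensor  # (...,6): dxx dyy dzz dxy dxz dyz
    quad = (
        d[..., None, 0] * g[:, 0] ** 2
        + d[..., None, 1] * g[:, 1] ** 2
        + d[..., None, 2] * g[:, 2] ** 2
        + 2 * d[..., None, 3] * g[:, 0] * g[:, 1]
        + 2 * d[..., None, 4] * g[:, 0] * g[:, 2]
        + 2 * d[..., None, 5] * g[:, 1] * g[:, 2]
    )
    signal = s0 * np.exp(-b_value * quad)
    data = np.concatenate(
        [np.full(tensor_field.shape + (1,), float(s0)), signal], axis=-1
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        real = data + rng.normal(0.0, noise_sigma, data.shape)
        imag = rng.normal(0.0, noise_sigma, data.shape)
        data = np.sqrt(real**2 + imag**2)

    n = g.shape[0]
    bvals = np.concatenate([[0.0], np.full(n, float(b_value))])
    bvecs = np.vstack([np.zeros(3), g])
    return DiffusionVolume(
        data=data,
        bvals=bvals,
        bvecs=bvecs,
        voxel_size=tensor_field.voxel_size,
        affine=tensor_field.affine,
    )


# ---------------------------------------------------------------------------
# phantom construction


def _tube_geometry(spec: BundleSpec, centers: np.ndarray):
    """Distance from each voxel center to the bundle centerline and the
    local tangent at the closest segment."""
    cl = np.asarray(spec.centerline, dtype=float)
    seg_a = cl[:-1]
    seg_v = cl[1:] - cl[:-1]
    seg_len2 = (seg_v**2).sum(axis=1)
    n = centers.shape[0]
    best_d2 = np.full(n, np.inf)
    best_tan = np.zeros((n, 3))
    for a, v, l2 in zip(seg_a, seg_v, seg_len2):
        if l2 == 0:
            continue
        t = np.clip(((centers - a) @ v) / l2, 0.0, 1.0)
        proj = a + t[:, None] * v
        d2 = ((centers - proj) ** 2).sum(axis=1)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_tan[closer] = v / np.sqrt(l2)
    return np.sqrt(best_d2), best_tan


def _tensor_from_axis(evals: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Cylindrical tensor elements (6,) with lambda1 along ``axis``."""
    e1 = axis / np.linalg.norm(axis)
    # any orthonormal completion; transverse eigenvalues are equal so the
    # choice does not affect the tensor
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    mat = evals[0] * np.outer(e1, e1) + evals[1] * np.outer(e2, e2) + evals[2] * np.outer(e3, e3)
    return np.array(
        [mat[0, 0], mat[1, 1], mat[2, 2], mat[0, 1], mat[0, 2], mat[1, 2]]
    )


def oriented_tensor_field(
    orientations: np.ndarray,
    eigenvalues,
    voxel_size=(1.0, 1.0, 1.0),
) -> TensorField:
    """Tensor field with a prescribed principal axis per voxel.

    ``orientations`` has shape (nx, ny, nz, 3); ``eigenvalues`` is either a
    single (lambda1, lambda2, lambda3) triple applied everywhere or a
    per-voxel (nx, ny, nz, 3) array.  Useful for building fields with
    abrupt orientation interfaces or graded anisotropy.
    """
    orientations = np.asarray(orientations, dtype=float)
    shape = orientations.shape[:3]
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.ndim == 1:
        ev = np.broadcast_to(ev, shape + (3,))
    tensor = np.zeros(shape + (6,))
    for idx in np.ndindex(shape):
        tensor[idx] = _tensor_from_axis(ev[idx], orientations[idx])
    from .dti import _tensor_elements_to_matrices

    mats = _tensor_elements_to_matrices(tensor)
    evals, evecs = np.linalg.eigh(mats)
    return TensorField(
        tensor=tensor,
        evals=evals[..., ::-1],
        evecs=evecs[..., :, ::-1],
        valid=np.ones(shape, dtype=bool),
        voxel_size=voxel_size,
    )


def make_fan_phantom(
    shape=(24, 16, 3),
    focus=(4.0, 8.0, 1.5),
    fa_falloff_radius_mm: float = 20.0,
    voxel_size=(1.0, 1.0, 1.0),
) -> TensorField:
    """Fan-shaped phantom: fiber orientations radiate in-plane from a focus
    and anisotropy decays linearly with distance from it.

    Streamlines form rays through the focus, so ray voxels on different rays
    share the focus voxels as direct neighbors without sharing a fiber —
    genuine indirect connectivity, unlike a parallel bundle whose voxels all
    collapse into one clique.  The graded anisotropy makes the tracked
    extent, and hence VISC, sensitive to the FA stopping threshold.
    """
    shape = tuple(shape)
    focus = np.asarray(focus, dtype=float)
    ii, jj, kk = np.indices(shape)
    centers = np.stack([ii + 0.5, jj + 0.5, kk + 0.5], axis=-1) * np.asarray(voxel_size)
    rel = centers - focus
    r = np.linalg.norm(rel[..., :2], axis=-1)
    safe_r = np.maximum(r, 1e-9)
    ori = np.zeros(shape + (3,))
    ori[..., 0] = np.where(r > 1e-9, rel[..., 0] / safe_r, 1.0)
    ori[..., 1] = np.where(r > 1e-9, rel[..., 1] / safe_r, 0.0)
    w = np.clip(1.0 - r / fa_falloff_radius_mm, 0.0, 1.0)
    lam1 = 0.7e-3 + w * 1.0e-3
    lam23 = 0.7e-3 - w * 0.4e-3
    ev = np.stack([lam1, lam23, lam23], axis=-1)
    return oriented_tensor_field(ori, ev, voxel_size=voxel_size)


def generate_phantom(spec: PhantomSpec) -> tuple[TensorField, dict]:
    """Tensor field and masks from a phantom spec.

    Voxels within a bundle's radius get the bundle tensor oriented along the
    local centerline tangent (overlaps resolved by first-listed bundle
    precedence); other voxels are isotropic background; lesion voxels are
    overwritten last with an isotropic tensor of ``md_factor`` x background
    MD.  Returns the field and ``{"bundle": mask, "lesion": mask}``.
    """
    grid = spec.grid
    shape = spec.shape
    n = grid.n_voxels
    ijk = grid.unravel(np.arange(n))
    centers = grid.center_of(ijk)

    bg = spec.background_eigenvalue
    tensor = np.zeros((n, 6))
    tensor[:, :3] = bg  # isotropic background
    bundle_mask = np.zeros(n, dtype=bool)

    for bundle in spec.bundles:
        dist, tangents = _tube_geometry(bundle, centers)
        inside = (dist <= bundle.radius_mm) & ~bundle_mask  # first-listed wins
        evals = np.asarray(bundle.eigenvalues, dtype=float)
        for i in np.flatnonzero(inside):
            tensor[i] = _tensor_from_axis(evals, tangents[i])
        bundle_mask |= inside

    lesion_mask = np.zeros(shape, dtype=bool)
    if spec.lesion is not None:
        lesion_mask = spec.lesion.mask(shape)
        flat = lesion_mask.reshape(-1)
        tensor[flat] = 0.0
        tensor[flat, 0] = tensor[flat, 1] = tensor[flat, 2] = (
            bg * spec.lesion.md_factor
        )
        bundle_mask &= ~flat

    from .dti import _tensor_elements_to_matrices

    mats = _tensor_elements_to_matrices(tensor.reshape(shape + (6,)))
    evals, evecs = np.linalg.eigh(mats)
    tfield = TensorField(
        tensor=tensor.reshape(shape + (6,)),
        evals=evals[..., ::-1],
        evecs=evecs[..., :, ::-1],
        valid=np.ones(shape, dtype=bool),
        voxel_size=spec.voxel_size,
    )
    masks = {"bundle": bundle_mask.reshape(shape), "lesion": lesion_mask}
    return tfield, masks


def generate_cohort(
    spec: PhantomSpec,
    n_controls: int,
    lesion_spec: LesionSpec | None = None,
    seed: int = 0,
    gradient_table: np.ndarray | None = None,
    b_value: float = 1000.0,
    s0: float = 1000.0,
) -> tuple[list[TensorField], TensorField]:
    """Noisy control cohort plus one lesioned subject on the same phantom.

    Each realisation synthesises a DWI volume from the (lesion-free) phantom
    with the spec's Rician noise and refits the tensor; the subject uses the
    lesioned phantom.  Per-realisation seeds derive deterministically from
    the master seed.  Requires ``n_controls >= 2`` (the group t-test needs a
    variance estimate).
    """
    if n_controls < 2:
        raise ValueError("a cohort needs >= 2 controls")
    from dataclasses import replace as _dc_replace

    from .dti import fit_tensor

    if gradient_table is None:
        gradient_table = uniform_gradient_directions()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_controls + 1)]

    control_spec = _dc_replace(spec, lesion=None)
    control_field, _ = generate_phantom(control_spec)
    subject_spec = _dc_replace(spec, lesion=lesion_spec or spec.lesion)
    subject_field, _ = generate_phantom(subject_spec)

    def realize(tfield: TensorField, child: int) -> TensorField:
        if spec.noise_sigma == 0:
            return tfield
        dwi = synthesize_dwi(
            tfield, gradient_table, b_value, s0, spec.noise_sigma, seed=child
        )
        return fit_tensor(dwi)

    controls = [realize(control_field, child_seeds[i]) for i in range(n_controls)]
    subject = realize(subject_field, child_seeds[-1])
    return controls, subject
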