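"""Deterministic streamline tractography (FACT-style, RK4 integration).

Streamlines follow the FA-weighted principal-eigenvector field
``v(x) = FA(x) * e1(x)``: the field is sampled by trilinear interpolation of
the eight surrounding voxel vectors, each sign-aligned to the current heading
(eigenvectors carry an arbitrary sign), and integrated with a 4th-order
Runge-Kutta step of fixed arc length.  Tracking is bidirectional from each
seed and stops when

* the local FA falls below the stopping threshold,
* the heading turns more than the maximum curvature angle relative to the
  heading one voxel-length earlier (per-step angles at sub-voxel step sizes
  are tiny; the voxel-scale look-back is what detects crossing-bundle turns),
* the next point would leave the volume, or
* the half-track reaches the maximum length.

Seeds are placed on a uniform lattice (anchored at voxel centers) and kept
only where the interpolated FA strictly exceeds the seed threshold.  After
tracking, fibers shorter than the minimum or longer than the maximum length
are removed (boundaries inclusive).

Everything here is deterministic: identical inputs give identical fibers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .dti import ScalarMap, TensorField

__all__ = [
    "TrackingParams",
    "Streamline",
    "FiberSet",
    "generate_seeds",
    "track_fiber",
    "track_all",
    "filter_fibers",
    "warp_fibers",
]


@dataclass(frozen=True)
class TrackingParams:
    """Tracking parameters (defaults follow the standard protocol).

    step_size_mm: RK4 arc-length step (0.1 mm).
    max_angle_deg: maximum curvature between headings one voxel apart (60).
    fa_stop: propagation stops where FA drops below this (0.15).
    fa_seed: seeds require FA strictly above this (0.3).
    seed_spacing_mm: lattice spacing for seed placement (1 mm).
    min_length_mm / max_length_mm: post-hoc fiber length filter (10, 140);
        fibers with length < min or > max are excluded, boundaries kept.
    """

    step_size_mm: float = 0.1
    max_angle_deg: float = 60.0
    fa_stop: float = 0.15
    fa_seed: float = 0.3
    seed_spacing_mm: float = 1.0
    min_length_mm: float = 10.0
    max_length_mm: float = 140.0

    def __post_init__(self) -> None:
        if self.step_size_mm <= 0:
            raise ValueError("step size must be positive")
        if not (0 < self.fa_stop < 1 and 0 < self.fa_seed < 1):
            raise ValueError("FA thresholds must lie strictly in (0, 1)")
        if self.min_length_mm >= self.max_length_mm:
            raise ValueError("min length must be below max length")
        if not 0 < self.max_angle_deg < 180:
            raise ValueError("max angle must lie in (0, 180) degrees")


@dataclass
class Streamline:
    """An ordered polyline in mm coordinates with termination bookkeeping."""

    points: np.ndarray
    seed_index: int = -1
    termination_forward: str = ""
    termination_backward: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    @property
    def length(self) -> float:
        if self.points.shape[0] < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class FiberSet:
    """A collection of streamlines with provenance."""

    streamlines: list[Streamline]
    space: str = "subject"
    params: TrackingParams | None = None
    n_seeds: int = 0

    def __iter__(self):
        return iter(self.streamlines)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.streamlines])


# ---------------------------------------------------------------------------
# field sampling


class _VectorField:
    """Trilinear, sign-aligned sampler of the FA-weighted e1 field.

    Coordinates are clamped to the voxel-center lattice (nearest-edge
    extension) so the field is defined on the full physical extent of the
    volume.
    """

    def __init__(self, tfield: TensorField, fa: np.ndarray):
        self.w = fa[..., None] * tfield.principal_direction  # (x,y,z,3)
        self.fa = fa
        self.vs = np.asarray(tfield.voxel_size, dtype=float)
        self.shape = np.asarray(tfield.shape)
        self.extent = self.shape * self.vs

    def _corners(self, pts: np.ndarray):
        u = pts / self.vs - 0.5
        u = np.clip(u, 0.0, self.shape - 1.0)
        i0 = np.clip(np.floor(u).astype(np.int64), 0, np.maximum(self.shape - 2, 0))
        f = np.clip(u - i0, 0.0, 1.0)
        i1 = np.minimum(i0 + 1, self.shape - 1)
        return i0, i1, f

    def sample_fa(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        i0, i1, f = self._corners(pts)
        out = np.zeros(pts.shape[0])
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    ix = i1[:, 0] if dx else i0[:, 0]
                    iy = i1[:, 1] if dy else i0[:, 1]
                    iz = i1[:, 2] if dz else i0[:, 2]
                    wx = f[:, 0] if dx else 1 - f[:, 0]
                    wy = f[:, 1] if dy else 1 - f[:, 1]
                    wz = f[:, 2] if dz else 1 - f[:, 2]
                    out += wx * wy * wz * self.fa[ix, iy, iz]
        return out

    def sample_direction(self, pts: np.ndarray, headings: np.ndarray) -> np.ndarray:
        """FA-weighted mean direction, each corner sign-aligned to the
        current heading; NOT normalised (zero where FA vanishes)."""
        pts = np.atleast_2d(pts)
        headings = np.atleast_2d(headings)
        i0, i1, f = self._corners(pts)
        out = np.zeros((pts.shape[0], 3))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    ix = i1[:, 0] if dx else i0[:, 0]
                    iy = i1[:, 1] if dy else i0[:, 1]
                    iz = i1[:, 2] if dz else i0[:, 2]
                    wx = f[:, 0] if dx else 1 - f[:, 0]
                    wy = f[:, 1] if dy else 1 - f[:, 1]
                    wz = f[:, 2] if dz else 1 - f[:, 2]
                    vec = self.w[ix, iy, iz]  # (N,3)
                    sign = np.where((vec * headings).sum(axis=1) < 0, -1.0, 1.0)
                    out += (wx * wy * wz * sign)[:, None] * vec
        return out

    def inside(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return np.all((pts >= 0) & (pts < self.extent), axis=1)


def _normalize(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.linalg.norm(v, axis=-1)
    out = np.zeros_like(v)
    nz = n > 0
    out[nz] = v[nz] / n[nz][:, None]
    return out, n


# ---------------------------------------------------------------------------
# seeding and tracking


def generate_seeds(fa_map: ScalarMap, params: TrackingParams) -> np.ndarray:
    """Uniform seed lattice kept where interpolated FA strictly exceeds the
    seed threshold.  The lattice is anchored at the first voxel center and
    spaced ``seed_spacing_mm`` along each axis.  Returns (N, 3) mm points;
    an empty result only warns."""
    vs = np.asarray(fa_map.voxel_size, dtype=float)
    shape = np.asarray(fa_map.values.shape)
    extent = shape * vs
    sp_mm = params.seed_spacing_mm
    axes = [
        np.arange(vs[d] / 2.0, extent[d], sp_mm) for d in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    dummy = _FAOnly(fa_map)
    fa_vals = dummy.sample_fa(pts)
    keep = fa_vals > params.fa_seed  # strictly above
    seeds = pts[keep]
    if seeds.shape[0] == 0:
        warnings.warn("no seeds above the FA seed threshold", stacklevel=2)
    return seeds


class _FAOnly(_VectorField):
    """FA-only sampler used for seeding (no tensor field required)."""

    def __init__(self, fa_map: ScalarMap):
        self.fa = fa_map.values
        self.vs = np.asarray(fa_map.voxel_size, dtype=float)
        self.shape = np.asarray(fa_map.values.shape)
        self.extent = self.shape * self.vs


def _propagate(
    sampler: _VectorField,
    seeds: np.ndarray,
    init_headings: np.ndarray,
    params: TrackingParams,
) -> tuple[list[list[np.ndarray]], list[str]]:
    """Batch one-directional propagation.  Returns per-seed point lists
    (excluding the seed itself) and termination reasons."""
    n = seeds.shape[0]
    h = params.step_size_mm
    max_steps = int(np.ceil(params.max_length_mm / h))
    lookback = max(1, int(round(float(np.min(sampler.vs)) / h)))
    cos_max = np.cos(np.deg2rad(params.max_angle_deg))

    pos = seeds.copy()
    heading = init_headings.copy()
    active = np.ones(n, dtype=bool)
    reasons = np.array(["max_length"] * n, dtype=object)
    # FA check at the seed itself
    fa0 = sampler.sample_fa(pos)
    low = fa0 < params.fa_stop
    reasons[low] = "low_fa"
    active &= ~low
    # zero field at the seed (fully isotropic): nothing to follow
    v0 = sampler.sample_direction(pos, heading)
    _, n0 = _normalize(v0)
    dead = active & (n0 == 0)
    reasons[dead] = "low_fa"
    active &= ~dead

    # history[0] holds the heading from `lookback` steps ago
    history: list[np.ndarray] = [heading.copy() for _ in range(lookback)]
    points: list[list[np.ndarray]] = [[] for _ in range(n)]

    for _step in range(max_steps):
        if not np.any(active):
            break
        idx = np.flatnonzero(active)
        p = pos[idx]
        hd = heading[idx]

        k1, _ = _normalize(sampler.sample_direction(p, hd))
        k2, _ = _normalize(sampler.sample_direction(p + 0.5 * h * k1, k1))
        k3, _ = _normalize(sampler.sample_direction(p + 0.5 * h * k2, k2))
        k4, _ = _normalize(sampler.sample_direction(p + h * k3, k3))
        combo = k1 + 2 * k2 + 2 * k3 + k4
        direction, norm = _normalize(combo)

        stop_zero = norm == 0
        new_p = p + h * direction
        inside = sampler.inside(new_p)
        fa_new = sampler.sample_fa(new_p)
        low_fa = fa_new < params.fa_stop

        # curvature over a 1-voxel look-back
        ref = history[0][idx]
        cosang = (direction * ref).sum(axis=1)
        sharp = cosang < cos_max

        ok = ~stop_zero & inside & ~low_fa & ~sharp
        # record terminations
        gidx = idx[~ok]
        r = np.where(
            stop_zero[~ok],
            "low_fa",
            np.where(~inside[~ok], "out_of_bounds", np.where(low_fa[~ok], "low_fa", "angle")),
        )
        reasons[gidx] = r
        active[gidx] = False

        keep = idx[ok]
        pos[keep] = new_p[ok]
        heading[keep] = direction[ok]
        history.pop(0)
        history.append(heading.copy())
        for gi, pt in zip(keep, new_p[ok]):
            points[gi].append(pt)

    return points, list(reasons)


def track_all(
    seeds: np.ndarray,
    tfield: TensorField,
    fa_map: ScalarMap,
    params: TrackingParams = TrackingParams(),
) -> FiberSet:
    """Track bidirectionally from every seed (vectorised over seeds).

    The two half-tracks (along +e1 and -e1 at the seed) are concatenated
    through the shared seed point.  No length filter is applied here; see
    :func:`filter_fibers`.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    sampler = _VectorField(tfield, fa_map.values)
    if not np.all(sampler.inside(seeds)):
        raise ValueError("seed outside the volume")

    e1_seed = sampler.sample_direction(seeds, np.tile([1.0, 0, 0], (seeds.shape[0], 1)))
    init, _ = _normalize(e1_seed)
    # fall back to +x for zero-field seeds (they terminate immediately anyway)
    zero = np.all(init == 0, axis=1)
    init[zero] = [1.0, 0.0, 0.0]

    fwd_pts, fwd_reason = _propagate(sampler, seeds, init, params)
    bwd_pts, bwd_reason = _propagate(sampler, seeds, -init, params)

    streamlines = []
    for i in range(seeds.shape[0]):
        back = bwd_pts[i][::-1]
        pts = np.array(back + [seeds[i]] + fwd_pts[i])
        streamlines.append(
            Streamline(
                points=pts,
                seed_index=i,
                termination_forward=fwd_reason[i],
                termination_backward=bwd_reason[i],
            )
        )
    return FiberSet(
        streamlines=streamlines, space="subject", params=params, n_seeds=seeds.shape[0]
    )


def track_fiber(
    seed: np.ndarray,
    tfield: TensorField,
    fa_map: ScalarMap,
    params: TrackingParams = TrackingParams(),
) -> Streamline:
    """Track a single streamline from one seed (see :func:`track_all`)."""
    return track_all(np.atleast_2d(seed), tfield, fa_map, params)[0]


def filter_fibers(fibers: FiberSet, params: TrackingParams) -> FiberSet:
    """Keep fibers with min_length <= length <= max_length (inclusive)."""
    kept = [
        s
        for s in fibers
        if params.min_length_mm <= s.length <= params.max_length_mm
    ]
    return FiberSet(
        streamlines=kept, space=fibers.space, params=params, n_seeds=fibers.n_seeds
    )


def warp_fibers(fibers: FiberSet, dfield, to_space: str = "reference") -> FiberSet:
    """Displace every fiber point by the (trilinearly interpolated)
    displacement field; out-of-domain points are clamped (counted in a
    warning).  Lengths are implicitly recomputed; the space tag flips."""
    n_clamped = 0
    warped = []
    for s in fibers:
        disp, clamped = dfield.sample(s.points, count_clamped=True)
        n_clamped += clamped
        warped.append(
            replace(s, points=s.points + disp)
        )
    if n_clamped:
        warnings.warn(
            f"{n_clamped} fiber points fell outside the displacement field "
            "domain and were clamped",
            stacklevel=2,
        )
    return FiberSet(
        streamlines=warped, space=to_space, params=fibers.params, n_seeds=fibers.n_seeds
    )
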