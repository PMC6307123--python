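"""Mixed quadric/voxel geometry.

The machine (patient-dependent linac head: MLC leaves, jaws) is modeled as an
ordered list of :class:`Body` objects, each an intersection of signed quadric
surfaces with an optional rigid transform; the phantom/patient is an
axis-aligned :class:`VoxelGrid`.  A horizontal interface plane at
``z = z_interface`` separates the two regions so a particle can be handed
from quadric tracking to voxel (Woodcock) tracking in a single simulation.

Conventions (fixed here because they are otherwise arbitrary): the beam axis
is -z pointing toward the phantom, the isocenter is the coordinate origin,
voxel indices are zero-based and voxel intervals are half-open [low, high) —
a point exactly on a shared face belongs to the higher-index voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["VoxelGrid", "Quadric", "Body", "MixedGeometry", "voxel_ray_walk",
           "coarsen_grid", "coarsen_field", "rotation_matrix"]

#: crossing roots closer than this (cm) are treated as the surface just left
BOUNDARY_TOL = 1e-8


# ---------------------------------------------------------------------------
# voxel grid

@dataclass
class VoxelGrid:
    """Axis-aligned voxel grid with per-voxel material index and density."""

    origin: np.ndarray          # (3,) lower corner, cm
    spacing: np.ndarray         # (3,) cm
    material: np.ndarray        # (nx, ny, nz) small ints into a registry list
    density: np.ndarray         # (nx, ny, nz) g/cm^3
    materials: Tuple[str, ...] = ("water",)   # registry names, index -> name
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.material = np.asarray(self.material)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacings must be positive")
        if self.material.shape != self.density.shape or self.material.ndim != 3:
            raise ValueError("material and density must be 3-D arrays of equal shape")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        if self.material.max(initial=0) >= len(self.materials):
            raise ValueError("material index outside registry")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.material.shape

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.spacing * np.array(self.shape)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def locate(self, points) -> np.ndarray:
        """Voxel indices (n,3) for points; -1 on any axis means outside.
        Half-open convention: a point on a face goes to the higher voxel."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor((p - self.origin) / self.spacing).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        idx[~inside] = -1
        return idx

    def flat_index(self, idx: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.shape
        return (idx[..., 0] * ny + idx[..., 1]) * nz + idx[..., 2]

    def total_mass(self) -> float:
        return float(self.density.sum() * self.voxel_volume)

    def ray_box_span(self, p, d):
        """(t_in, t_out) of rays with the grid bounding box (vectorized);
        t_in > t_out means no intersection.  Entry clamped at 0."""
        p = np.atleast_2d(p)
        d = np.atleast_2d(d)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (self.origin - p) / d
            t2 = (self.upper - p) / d
        lo = np.where(np.abs(d) > 0, np.minimum(t1, t2), -np.inf)
        hi = np.where(np.abs(d) > 0, np.maximum(t1, t2), np.inf)
        # rays parallel to an axis outside the slab never enter
        par_out = (np.abs(d) == 0) & ((p < self.origin) | (p >= self.upper))
        t_in = np.where(np.any(par_out, axis=1), np.inf, np.max(lo, axis=1))
        t_out = np.min(hi, axis=1)
        return np.maximum(t_in, 0.0), t_out


def voxel_ray_walk(point, direction, grid: VoxelGrid) -> Iterator[Tuple[Tuple[int, int, int], float]]:
    """Yield (voxel index, chord length) along a ray through the grid.

    Chord lengths sum to the in-grid path length; consecutive voxels are
    face neighbors (Amanatides-Woo traversal).
    """
    p = np.asarray(point, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    t_in, t_out = grid.ray_box_span(p[None], d[None])
    t, t_end = float(t_in[0]), float(t_out[0])
    if not t < t_end:
        return
    eps = 1e-12 * max(1.0, abs(t_end))
    start = p + (t + eps) * d
    idx = grid.locate(start[None])[0]
    if np.any(idx < 0):
        return
    step = np.where(d > 0, 1, -1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # parametric t of the next face crossing on each axis
        next_edge = grid.origin + (idx + (d > 0)) * grid.spacing
        t_next = np.where(d != 0, (next_edge - p) / d, np.inf)
        dt = np.where(d != 0, grid.spacing / np.abs(d), np.inf)
    shape = np.array(grid.shape)
    while t < t_end - 1e-15:
        axis = int(np.argmin(t_next))
        t_hit = min(float(t_next[axis]), t_end)
        chord = t_hit - t
        if chord > 0:
            yield (int(idx[0]), int(idx[1]), int(idx[2])), chord
        t = t_hit
        if t >= t_end - 1e-15:
            break
        idx[axis] += step[axis]
        if idx[axis] < 0 or idx[axis] >= shape[axis]:
            break
        t_next[axis] += dt[axis]


# ---------------------------------------------------------------------------
# quadric surfaces and bodies

@dataclass(frozen=True)
class Quadric:
    """Implicit quadric A x^2 + B y^2 + C z^2 + D xy + E xz + F yz
    + G x + H y + I z + J = 0."""

    coeffs: Tuple[float, ...]

    def __post_init__(self):
        c = tuple(float(v) for v in self.coeffs)
        if len(c) != 10:
            raise ValueError("quadric needs 10 coefficients")
        if all(v == 0.0 for v in c[:9]):
            raise ValueError("degenerate quadric: all non-constant coefficients zero")
        object.__setattr__(self, "coeffs", c)

    @classmethod
    def plane(cls, normal, offset) -> "Quadric":
        n = np.asarray(normal, dtype=float)
        return cls((0, 0, 0, 0, 0, 0, n[0], n[1], n[2], -float(offset)))

    @classmethod
    def sphere(cls, center, radius) -> "Quadric":
        cx, cy, cz = center
        return cls((1, 1, 1, 0, 0, 0, -2 * cx, -2 * cy, -2 * cz,
                    cx**2 + cy**2 + cz**2 - radius**2))

    @classmethod
    def cylinder_y(cls, x0, z0, radius) -> "Quadric":
        """Circular cylinder with axis parallel to y through (x0, ., z0)."""
        return cls((1, 0, 1, 0, 0, 0, -2 * x0, 0, -2 * z0, x0**2 + z0**2 - radius**2))

    def matrix(self) -> np.ndarray:
        A, B, C, D, E, F, G, H, I, J = self.coeffs
        return np.array([[A, D / 2, E / 2, G / 2],
                         [D / 2, B, F / 2, H / 2],
                         [E / 2, F / 2, C, I / 2],
                         [G / 2, H / 2, I / 2, J]])

    def evaluate(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        A, B, C, D, E, F, G, H, I, J = self.coeffs
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        return (A * x * x + B * y * y + C * z * z + D * x * y + E * x * z
                + F * y * z + G * x + H * y + I * z + J)


def _transform_quadric_matrix(M: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """World-frame matrix of a quadric given local->world rigid transform."""
    L = np.eye(4)
    L[:3, :3] = rotation.T
    L[:3, 3] = -rotation.T @ translation
    return L.T @ M @ L


def rotation_matrix(axis: str, degrees: float) -> np.ndarray:
    a = np.deg2rad(degrees)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError(f"unknown axis {axis!r}")


@dataclass
class Body:
    """Intersection of signed quadric surfaces with a rigid transform.

    ``surfaces`` lists (quadric, required_sign): a point is inside when
    sign(Q(x_local)) == required_sign (or Q == 0) for every surface.
    ``rotation``/``translation`` map local to world coordinates.
    """

    surfaces: Tuple[Tuple[Quadric, int], ...]
    material: str
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    name: str = ""
    tags: Dict = field(default_factory=dict)
    range_reject: bool = False

    def __post_init__(self):
        if not self.surfaces:
            raise ValueError("body needs at least one surface")
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation must be orthonormal")

    def world_matrices(self) -> np.ndarray:
        """(n_surf, 4, 4) world-frame quadric matrices."""
        return np.stack([_transform_quadric_matrix(q.matrix(), self.rotation, self.translation)
                         for q, _ in self.surfaces])

    def contains(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        local = (p - self.translation) @ self.rotation
        ok = np.ones(len(p), dtype=bool)
        for q, sign in self.surfaces:
            ok &= sign * q.evaluate(local) >= -1e-12
        return ok

    def aabb(self, fallback: float = 200.0) -> Tuple[np.ndarray, np.ndarray]:
        """Conservative world-frame bounding box, derived from plane and
        quadric surfaces where possible (``fallback`` half-extent otherwise)."""
        lo = np.full(3, -np.inf)
        hi = np.full(3, np.inf)
        for q, sign in self.surfaces:
            A, B, C, D, E, F, G, H, I, J = q.coeffs
            quad = (A, B, C, D, E, F)
            if not any(quad):
                n = np.array([G, H, I])
                nz = np.flatnonzero(n)
                if len(nz) == 1:
                    k = nz[0]
                    bound = -J / n[k]
                    if sign * n[k] > 0:
                        lo[k] = max(lo[k], bound)
                    else:
                        hi[k] = min(hi[k], bound)
            elif sign < 0 and not any((D, E, F)):
                # inside an axis-aligned quadric: per-axis bounds where the
                # squared term is present
                cen = {0: -G / (2 * A) if A else 0.0, 1: -H / (2 * B) if B else 0.0,
                       2: -I / (2 * C) if C else 0.0}
                r2 = (A * cen[0] ** 2 + B * cen[1] ** 2 + C * cen[2] ** 2) - J
                if r2 >= 0:
                    r = np.sqrt(r2)
                    for k, coef in ((0, A), (1, B), (2, C)):
                        if coef > 0:
                            lo[k] = max(lo[k], cen[k] - r / np.sqrt(coef))
                            hi[k] = min(hi[k], cen[k] + r / np.sqrt(coef))
        lo = np.where(np.isfinite(lo), lo, -fallback)
        hi = np.where(np.isfinite(hi), hi, fallback)
        corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])
                            for z in (lo[2], hi[2])])
        world = corners @ self.rotation.T + self.translation
        return world.min(axis=0), world.max(axis=0)

    def transformed(self, rotation=None, translation=None) -> "Body":
        """Compose an additional world-frame rigid transform."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return Body(self.surfaces, self.material,
                    rotation=R @ self.rotation,
                    translation=R @ self.translation + t,
                    name=self.name, tags=dict(self.tags), range_reject=self.range_reject)


def ray_quadric_distance(point, direction, body: Body) -> float:
    """Distance to the nearest boundary crossing of ``body`` along the ray,
    or inf.  A crossing is a sign change of any of the body's surfaces at a
    positive root of the (possibly linear) quadratic along the ray."""
    p = np.asarray(point, dtype=float)
    d = np.asarray(direction, dtype=float)
    best = np.inf
    local_p = body.rotation.T @ (p - body.translation)
    local_d = body.rotation.T @ d
    for q, _ in body.surfaces:
        M = q.matrix()
        ph = np.append(local_p, 1.0)
        dh = np.append(local_d, 0.0)
        a = dh @ M @ dh
        b = 2.0 * ph @ M @ dh
        c = ph @ M @ ph
        for t in _positive_roots(a, b, c):
            if BOUNDARY_TOL < t < best:
                best = t
    return best


def _positive_roots(a, b, c):
    if abs(a) < 1e-300:
        if b == 0:
            return ()
        t = -c / b
        return (t,) if t > 0 else ()
    disc = b * b - 4 * a * c
    if disc < 0:
        return ()
    sq = np.sqrt(disc)
    return tuple(t for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)) if t > 0)


# ---------------------------------------------------------------------------
# mixed geometry

@dataclass
class MixedGeometry:
    """Quadric machine region above ``z_interface``, voxel grid below,
    embedded in a world filled with ``world_material``."""

    bodies: List[Body]
    grid: VoxelGrid
    z_interface: float
    world_material: str = "air"
    world_half_extent: float = 200.0

    def __post_init__(self):
        if self.grid.upper[2] > self.z_interface + 1e-9:
            raise ValueError("voxel grid must lie below the interface plane")
        for b in self.bodies:
            lo, hi = self.grid.origin, self.grid.upper
            corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                                for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
            if b.contains(corners).any():
                raise ValueError(f"machine body {b.name!r} intersects the voxel grid")

    def locate(self, points):
        """Region tag per point: ('voxel', flat index), ('body', body index)
        or ('world', -1)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        tags = [("world", -1)] * len(p)
        vox = self.grid.locate(p)
        inside = np.all(vox >= 0, axis=1)
        for i in np.flatnonzero(inside):
            tags[i] = ("voxel", int(self.grid.flat_index(vox[i])))
        rest = np.flatnonzero(~inside)
        if len(rest):
            for bi, b in enumerate(self.bodies):
                if not len(rest):
                    break
                hit = b.contains(p[rest])
                for j in np.flatnonzero(hit):
                    tags[rest[j]] = ("body", bi)
                rest = rest[~hit]
        return tags[0] if np.asarray(points).ndim == 1 else tags


# ---------------------------------------------------------------------------
# grid coarsening

def _overlap_matrix(fine_edges: np.ndarray, coarse_edges: np.ndarray) -> np.ndarray:
    """(n_coarse, n_fine) interval-overlap lengths."""
    lo = np.maximum(coarse_edges[:-1, None], fine_edges[None, :-1])
    hi = np.minimum(coarse_edges[1:, None], fine_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def coarsen_grid(grid: VoxelGrid, target_spacing=(0.25, 0.25, 0.25)) -> VoxelGrid:
    """Volume-weighted rebinning of a voxel grid onto a coarser grid.

    Each coarse voxel's density is the overlapping mass divided by the full
    coarse voxel volume, so total mass (sum rho*V) is conserved exactly; the
    material index is the one contributing the largest overlap volume.  The
    coarse grid starts at the fine origin and extends past the fine grid by
    at most one voxel per axis when spacings are incommensurate.
    """
    target = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,))
    if np.any(target < grid.spacing - 1e-12):
        raise ValueError("target spacing must not be finer than the source grid")
    shape = np.array(grid.shape)
    extent = shape * grid.spacing
    n_c = np.maximum(np.ceil(extent / target - 1e-9).astype(int), 1)
    W = []
    for ax in range(3):
        fe = grid.origin[ax] + np.arange(shape[ax] + 1) * grid.spacing[ax]
        ce = grid.origin[ax] + np.arange(n_c[ax] + 1) * target[ax]
        W.append(_overlap_matrix(fe, ce))
    mass = np.einsum("af,bg,ch,fgh->abc", W[0], W[1], W[2], grid.density, optimize=True)
    rho_c = mass / np.prod(target)
    mat_c = np.zeros(tuple(n_c), dtype=grid.material.dtype)
    best = np.full(tuple(n_c), -1.0)
    for m in np.unique(grid.material):
        vol = np.einsum("af,bg,ch,fgh->abc", W[0], W[1], W[2],
                        (grid.material == m).astype(float), optimize=True)
        take = vol > best
        mat_c[take] = m
        best = np.maximum(best, vol)
    return VoxelGrid(grid.origin.copy(), target.copy(), mat_c, rho_c,
                     materials=grid.materials, orientation=grid.orientation.copy())


def coarsen_field(grid: VoxelGrid, values: np.ndarray, target_spacing) -> Tuple[VoxelGrid, np.ndarray]:
    """Volume-fraction-weighted average of a per-voxel field (e.g. dose) onto
    the coarse grid; normalization is by covered volume so uniform fields
    stay uniform.  Returns (coarse grid, coarse field)."""
    coarse = coarsen_grid(grid, target_spacing)
    target = coarse.spacing
    shape = np.array(grid.shape)
    W = []
    for ax in range(3):
        fe = grid.origin[ax] + np.arange(shape[ax] + 1) * grid.spacing[ax]
        ce = grid.origin[ax] + np.arange(coarse.shape[ax] + 1) * target[ax]
        W.append(_overlap_matrix(fe, ce))
    num = np.einsum("af,bg,ch,fgh->abc", W[0], W[1], W[2],
                    np.asarray(values, dtype=float), optimize=True)
    cov = np.einsum("af,bg,ch,fgh->abc", W[0], W[1], W[2],
                    np.ones(grid.shape), optimize=True)
    return coarse, num / np.maximum(cov, 1e-300)
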