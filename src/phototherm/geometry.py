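"""Scene geometry and material definitions.

Lengths are millimetres throughout.  Optical coefficients are stored in
cm^-1 (the unit tissue-optics tables are printed in) and converted to
mm^-1 once, when a scene is compiled for transport.  Thermal parameters
are SI.

A scene is a cuboid domain filled with an ambient material (air) plus a
list of watertight triangle-mesh entities, each carrying an optical
material and an integer priority.  Nesting (tumour inside flesh inside
air) is resolved by priority: the highest-priority entity containing a
point wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import trimesh

__all__ = [
    "OpticalMaterial",
    "BioheatParams",
    "Entity",
    "DiscSource",
    "VoxelGrid",
    "Scene",
    "RayHit",
    "OutOfDomainError",
    "composite_material",
    "make_oblate_spheroid",
    "make_box",
    "make_disc_source",
    "load_stl",
]

#: Minimum accepted ray-hit distance (mm); guards against self-intersection
#: immediately after a reflection.
INTERSECT_EPS = 1e-9


class OutOfDomainError(ValueError):
    """A query point lies outside the simulation domain."""


# ---------------------------------------------------------------------------
# Ray / containment primitives (vectorized Moller-Trumbore)
# ---------------------------------------------------------------------------
# Deliberately skewed casting direction: axis-aligned rays from voxel
# centres would graze mesh edges and break the crossing-parity test.
_PARITY_DIR = np.array([0.5391356, 0.3419385, 0.7698203])
_PARITY_DIR /= np.linalg.norm(_PARITY_DIR)


def ray_mesh_hits(
    mesh: "trimesh.Trimesh", origin: np.ndarray, direction: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All ray-triangle intersections of one ray with a mesh.

    Returns (t values, triangle indices), unsorted, for t > 0.
    """
    tri = mesh.triangles
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    h = np.cross(direction[None, :], e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-14
    if not ok.any():
        return np.empty(0), np.empty(0, dtype=int)
    idx = np.flatnonzero(ok)
    f = 1.0 / a[idx]
    s = origin[None, :] - v0[idx]
    u = np.einsum("ij,ij->i", s, h[idx]) * f
    q = np.cross(s, e1[idx])
    v = (q @ direction) * f
    t = np.einsum("ij,ij->i", q, e2[idx]) * f
    hit = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0) & (t > 0.0)
    return t[hit], idx[hit]


def points_in_mesh(
    mesh: "trimesh.Trimesh", points: np.ndarray, chunk: int = 65536
) -> np.ndarray:
    """Point-in-volume test for a watertight mesh via crossing parity."""
    tri = mesh.triangles
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    d = _PARITY_DIR
    h = np.cross(d[None, :], e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-14
    v0, e1, e2, h = v0[ok], e1[ok], e2[ok], h[ok]
    f = 1.0 / a[ok]
    points = np.atleast_2d(points)
    out = np.empty(len(points), dtype=bool)
    for lo_i in range(0, len(points), chunk):
        pts = points[lo_i : lo_i + chunk]
        s = pts[:, None, :] - v0[None, :, :]
        u = np.einsum("pmi,mi->pm", s, h) * f[None, :]
        q = np.cross(s, e1[None, :, :])
        v = (q @ d) * f[None, :]
        t = np.einsum("pmi,mi->pm", q, e2) * f[None, :]
        hits = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0) & (t > 0.0)
        out[lo_i : lo_i + chunk] = (hits.sum(axis=1) % 2).astype(bool)
    return out


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalMaterial:
    """Optical properties of a homogeneous medium at a single wavelength.

    Parameters
    ----------
    mu_a, mu_s:
        Absorption and scattering coefficients in cm^-1.
    g:
        Henyey–Greenstein anisotropy factor (mean cosine of the
        scattering deflection), in [-1, 1].
    n:
        Refractive index, >= 1.
    """

    name: str
    mu_a: float
    mu_s: float
    g: float = 0.9
    n: float = 1.38

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError(
                f"material {self.name!r}: mu_a and mu_s must be >= 0, "
                f"got ({self.mu_a}, {self.mu_s})"
            )
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"material {self.name!r}: g must lie in [-1, 1]")
        if self.n < 1.0:
            raise ValueError(f"material {self.name!r}: n must be >= 1")

    @property
    def mu(self) -> float:
        """Total interaction coefficient mu_a + mu_s (cm^-1)."""
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        """Single-scattering albedo mu_s / (mu_a + mu_s)."""
        if self.mu == 0.0:
            raise ZeroDivisionError(
                f"material {self.name!r} is a vacuum (mu = 0); albedo undefined"
            )
        return self.mu_s / self.mu


def composite_material(
    base: OpticalMaterial, additive: OpticalMaterial, name: str | None = None
) -> OpticalMaterial:
    """Optical properties of a host tissue infused with an additive.

    The absorption and scattering coefficients sum component-wise
    (independent attenuators at the same wavelength); the anisotropy and
    refractive index are those of the host, since a dilute nanoparticle
    load contributes a negligible fraction of the composite scattering.
    """
    return OpticalMaterial(
        name=name or f"{base.name}+{additive.name}",
        mu_a=base.mu_a + additive.mu_a,
        mu_s=base.mu_s + additive.mu_s,
        g=base.g,
        n=base.n,
    )


@dataclass(frozen=True)
class BioheatParams:
    """Thermal and perfusion constants of the Pennes bioheat equation.

    Defaults are standard soft-tissue values: density rho (kg/m^3),
    specific heat c (J/(kg K)), conductivity k (W/(m K)), blood density
    rho_b, blood specific heat c_b, perfusion rate w_b (1/s), and
    arterial blood temperature T_a (degC).
    """

    rho: float = 1079.0
    c: float = 3540.0
    k: float = 0.53
    rho_b: float = 1060.0
    c_b: float = 3617.0
    w_b: float = 0.01
    T_a: float = 37.0

    def __post_init__(self) -> None:
        for name in ("rho", "c", "k", "rho_b", "c_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.w_b < 0:
            raise ValueError("w_b must be >= 0")
        if not np.isfinite(self.T_a):
            raise ValueError("T_a must be finite")

    @property
    def B(self) -> float:
        """Perfusion heat-sink coefficient c_b * w_b * rho_b, W/(m^3 K)."""
        return self.c_b * self.w_b * self.rho_b


# ---------------------------------------------------------------------------
# Mesh generators
# ---------------------------------------------------------------------------

def make_oblate_spheroid(
    center: Sequence[float],
    semi_axes: Sequence[float],
    subdivisions: int = 4,
) -> trimesh.Trimesh:
    """Watertight triangle mesh of an ellipsoid with semi-axes (a, b, c) mm.

    Built by anisotropically scaling an icosphere, so the mesh volume
    converges to (4/3)*pi*a*b*c with subdivision level.
    """
    a, b, c = (float(x) for x in semi_axes)
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    if subdivisions < 1:
        raise ValueError("subdivisions must be >= 1")
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    mesh.apply_scale([a, b, c])
    mesh.apply_translation(np.asarray(center, dtype=float))
    return mesh


def make_box(center: Sequence[float], extents: Sequence[float]) -> trimesh.Trimesh:
    """Axis-aligned cuboid mesh with the given full edge lengths (mm)."""
    mesh = trimesh.creation.box(extents=np.asarray(extents, dtype=float))
    mesh.apply_translation(np.asarray(center, dtype=float))
    return mesh


def load_stl(path: str) -> trimesh.Trimesh:
    """Load a triangle mesh from an STL file (binary or ASCII)."""
    mesh = trimesh.load(path, force="mesh")
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a triangle mesh")
    return mesh


# ---------------------------------------------------------------------------
# Entities and the light source
# ---------------------------------------------------------------------------

@dataclass
class Entity:
    """A watertight mesh bound to an optical material.

    Higher ``priority`` wins where entities nest (tumour > flesh > air).
    """

    name: str
    mesh: trimesh.Trimesh
    material: OpticalMaterial
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.mesh.is_watertight:
            raise ValueError(f"entity {self.name!r}: mesh is not watertight")
        if self.mesh.volume < 0:
            self.mesh.invert()

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized point-in-volume test (ray-crossing parity)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        # cheap AABB rejection before the ray test
        inside_box = np.all(
            (points >= self.mesh.bounds[0]) & (points <= self.mesh.bounds[1]), axis=1
        )
        out = np.zeros(len(points), dtype=bool)
        if inside_box.any():
            out[inside_box] = points_in_mesh(self.mesh, points[inside_box])
        return out


@dataclass
class DiscSource:
    """Planar disc light source emitting normal to its face.

    The disc is meshed as a triangle fan (``n_fan`` triangles) purely
    for visualisation/export; emission samples the exact disc uniformly
    by area.  ``direction`` is the emission direction (unit vector).
    """

    center: np.ndarray
    radius: float
    power: float
    direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -1.0])
    )
    n_fan: int = 16
    mesh: trimesh.Trimesh = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("source radius must be positive")
        if self.power <= 0:
            raise ValueError("source power must be positive")
        if self.n_fan < 3:
            raise ValueError("triangle fan needs at least 3 triangles")
        self.center = np.asarray(self.center, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        self.direction = self.direction / np.linalg.norm(self.direction)
        self.mesh = self._fan_mesh()

    def _fan_mesh(self) -> trimesh.Trimesh:
        # orthonormal frame spanning the disc plane
        u, v = _plane_basis(self.direction)
        ang = np.linspace(0.0, 2.0 * np.pi, self.n_fan, endpoint=False)
        rim = (
            self.center
            + self.radius * np.cos(ang)[:, None] * u
            + self.radius * np.sin(ang)[:, None] * v
        )
        vertices = np.vstack([self.center, rim])
        tri = np.array(
            [[0, 1 + i, 1 + (i + 1) % self.n_fan] for i in range(self.n_fan)]
        )
        return trimesh.Trimesh(vertices=vertices, faces=tri, process=False)

    def sample_emission(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform-by-area emission points on the disc, shape (n, 3)."""
        r = self.radius * np.sqrt(rng.random(n))
        theta = 2.0 * np.pi * rng.random(n)
        u, v = _plane_basis(self.direction)
        return (
            self.center
            + (r * np.cos(theta))[:, None] * u
            + (r * np.sin(theta))[:, None] * v
        )


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``normal`` and to each other."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def make_disc_source(
    center: Sequence[float],
    radius: float,
    n_fan: int = 16,
    power: float = 1.0,
    direction: Sequence[float] = (0.0, 0.0, -1.0),
) -> DiscSource:
    """Convenience constructor for :class:`DiscSource`."""
    return DiscSource(
        center=np.asarray(center, dtype=float),
        radius=radius,
        power=power,
        direction=np.asarray(direction, dtype=float),
        n_fan=n_fan,
    )


# ---------------------------------------------------------------------------
# Voxel grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelGrid:
    """Uniform Cartesian grid covering a cuboid domain.

    ``bounds`` is ``[[xmin, ymin, zmin], [xmax, ymax, zmax]]`` in mm;
    ``n_cells`` the cell count per axis.
    """

    bounds: tuple[tuple[float, float, float], tuple[float, float, float]]
    n_cells: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.bounds[0]), np.asarray(self.bounds[1])
        if np.any(hi <= lo):
            raise ValueError("grid bounds must have positive extent")
        if min(self.n_cells) < 1:
            raise ValueError("n_cells must be >= 1 per axis")

    @classmethod
    def cube(cls, half_extent: float, n: int) -> "VoxelGrid":
        b = float(half_extent)
        return cls(bounds=((-b, -b, -b), (b, b, b)), n_cells=(n, n, n))

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.bounds[0], dtype=float)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.bounds[1], dtype=float)

    @property
    def edges(self) -> np.ndarray:
        """Voxel edge lengths (dx, dy, dz) in mm."""
        return (self.hi - self.lo) / np.asarray(self.n_cells, dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.edges))

    @property
    def voxel_volume_m3(self) -> float:
        return self.voxel_volume_mm3 * 1e-9

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(n) for n in self.n_cells)

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis (mm)."""
        n = self.n_cells[axis]
        e = self.edges[axis]
        return self.lo[axis] + (np.arange(n) + 0.5) * e

    def centers(self) -> np.ndarray:
        """All voxel centres as an (nx, ny, nz, 3) array (mm)."""
        xs, ys, zs = (self.axis_centers(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def point_to_index(self, point: Sequence[float]) -> tuple[int, int, int]:
        p = np.asarray(point, dtype=float)
        if np.any(p < self.lo) or np.any(p > self.hi):
            raise OutOfDomainError(f"point {p} outside grid bounds")
        idx = np.floor((p - self.lo) / self.edges).astype(int)
        idx = np.minimum(idx, np.asarray(self.n_cells) - 1)
        return tuple(int(i) for i in idx)


# ---------------------------------------------------------------------------
# Scene
# ---------------------------------------------------------------------------

class RayHit(NamedTuple):
    distance: float
    point: np.ndarray
    normal: np.ndarray              # oriented against the ray
    material_near: OpticalMaterial  # medium on the origin side
    material_far: OpticalMaterial   # medium past the boundary


@dataclass
class Scene:
    """Cuboid domain, ambient material, and prioritized mesh entities."""

    domain: VoxelGrid
    ambient: OpticalMaterial
    entities: list[Entity] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entities = sorted(self.entities, key=lambda e: -e.priority)
        names = [e.name for e in self.entities]
        if len(set(names)) != len(names):
            raise ValueError("entity names must be unique")

    # -- material queries ---------------------------------------------------

    def medium_at(self, point: Sequence[float]) -> OpticalMaterial:
        """Material of the innermost entity containing ``point``."""
        p = np.asarray(point, dtype=float)
        if np.any(p < self.domain.lo) or np.any(p > self.domain.hi):
            raise OutOfDomainError(f"point {p} outside the domain")
        for ent in self.entities:  # descending priority
            if ent.contains(p[None, :])[0]:
                return ent.material
        return self.ambient

    def material_table(self) -> list[OpticalMaterial]:
        """Materials indexed as in :meth:`voxelize` (0 = ambient)."""
        return [self.ambient] + [e.material for e in reversed(self.entities)]

    def voxelize(self, grid: VoxelGrid | None = None) -> np.ndarray:
        """Per-voxel material index (uint8) sampled at voxel centres.

        Index 0 is the ambient material; entity k (in ascending priority)
        gets index k+1.  Higher-priority entities overwrite lower ones,
        matching :meth:`medium_at`.
        """
        grid = grid or self.domain
        idx = np.zeros(grid.shape, dtype=np.uint8)
        pts = grid.centers().reshape(-1, 3)
        for k, ent in enumerate(reversed(self.entities)):  # ascending priority
            mask = ent.contains(pts).reshape(grid.shape)
            idx[mask] = k + 1
        return idx

    # -- ray queries --------------------------------------------------------

    def ray_intersect(
        self, origin: Sequence[float], direction: Sequence[float]
    ) -> RayHit | None:
        """Nearest entity-boundary hit along a ray, or ``None``.

        The returned normal is oriented against the ray; the two
        materials are those immediately before and after the boundary.
        """
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        norm = np.linalg.norm(d)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")
        best_t = np.inf
        best_normal = None
        for ent in self.entities:
            ts, tri_idx = ray_mesh_hits(ent.mesh, o, d)
            for t, tri in zip(ts, tri_idx):
                if INTERSECT_EPS < t < best_t:
                    best_t = float(t)
                    best_normal = np.array(ent.mesh.face_normals[tri])
        if best_normal is None:
            return None
        if best_normal @ d > 0:
            best_normal = -best_normal
        point = o + best_t * d
        delta = 1e-6
        near = self.medium_at(np.clip(point - delta * d, self.domain.lo, self.domain.hi))
        far = self.medium_at(np.clip(point + delta * d, self.domain.lo, self.domain.hi))
        return RayHit(best_t, point, best_normal, near, far)

    def with_material(self, entity_name: str, material: OpticalMaterial) -> "Scene":
        """Copy of the scene with one entity's material replaced."""
        ents = [
            replace(e, material=material) if e.name == entity_name else replace(e)
            for e in self.entities
        ]
        return Scene(domain=self.domain, ambient=self.ambient, entities=ents)
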