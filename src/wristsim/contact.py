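"""Elastic-foundation bone-bone contact via penetration volume.

A contact pair consists of two rigid surfaces and a pressure module PM
[N/m^3].  The contact force magnitude is the product of PM and the overlap
(penetration) volume of the two surfaces, directed along the mean contact
normal so that it pushes the surfaces apart:

    F = PM * V_overlap * n_hat

This volumetric elastic-foundation law is linear in both PM and volume and
vanishes exactly when the surfaces do not overlap.  Analytic closed forms
are used for sphere-sphere and sphere-halfspace pairs; arbitrary watertight
triangle meshes fall back to point-in-solid voxel sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .errors import ValidationError


def _vec(x) -> np.ndarray:
    return np.asarray(x, dtype=float).reshape(3)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValidationError("cannot normalize near-zero vector")
    return v / n


def points_in_mesh(
    mesh: trimesh.Trimesh, points: np.ndarray, chunk: int = 512
) -> np.ndarray:
    """Point-in-solid test by the generalized winding number.

    Sums the signed solid angle subtended by every (outward-oriented)
    triangle at each query point (Van Oosterom-Strackee formula); points
    with winding number > 1/2 are inside.  Exact for watertight meshes and
    robust near edges, with no spatial index required.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    # single precision is ample: the decision threshold (winding 1/2) sits
    # far from the accumulated rounding error for any sane mesh
    scale = float(np.abs(mesh.triangles).max()) or 1.0
    tri = (mesh.triangles / scale).astype(np.float32)  # (m, 3, 3)
    pts = (points / scale).astype(np.float32)
    out = np.empty(len(points), dtype=bool)
    for start in range(0, len(points), chunk):
        p = pts[start : start + chunk]
        # vectors from each point to the triangle vertices: (n, m, 3)
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        num = np.einsum("nmi,nmi->nm", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("nmi,nmi->nm", a, b) * lc
            + np.einsum("nmi,nmi->nm", b, c) * la
            + np.einsum("nmi,nmi->nm", c, a) * lb
        )
        winding = np.arctan2(num, den).sum(axis=1) / (2.0 * np.pi)
        out[start : start + chunk] = winding > 0.5
    return out


@dataclass(frozen=True)
class SphereSurface:
    """Analytic sphere (e.g. an idealized carpal articular surface)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _vec(self.center))
        if self.radius <= 0:
            raise ValidationError(f"sphere radius must be > 0, got {self.radius}")

    def translated(self, v) -> "SphereSurface":
        return replace(self, center=self.center + _vec(v))

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm(points - self.center, axis=-1) <= self.radius

    @property
    def aabb(self):
        r = self.radius
        return self.center - r, self.center + r

    @property
    def reference_point(self) -> np.ndarray:
        return self.center


@dataclass(frozen=True)
class HalfSpaceSurface:
    """Analytic half-space: material on the side opposite ``normal``.

    Models a locally flat articular facet (e.g. a fossa on the distal
    radius).  ``normal`` is the outward normal, pointing away from bone.
    """

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", _vec(self.point))
        object.__setattr__(self, "normal", _unit(_vec(self.normal)))

    def translated(self, v) -> "HalfSpaceSurface":
        return replace(self, point=self.point + _vec(v))

    def contains(self, points: np.ndarray) -> np.ndarray:
        return (points - self.point) @ self.normal <= 0.0

    @property
    def aabb(self):
        return None  # unbounded

    @property
    def reference_point(self) -> np.ndarray:
        return self.point


@dataclass(frozen=True)
class MeshSurface:
    """Watertight triangulated surface (STL import path)."""

    mesh: trimesh.Trimesh
    name: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.mesh, trimesh.Trimesh):
            raise ValidationError("MeshSurface requires a trimesh.Trimesh")
        if not self.mesh.is_watertight:
            raise ValidationError(
                f"mesh {self.name or '<unnamed>'} is not watertight"
            )
        lo, hi = self.mesh.bounds
        center = (np.asarray(lo) + np.asarray(hi)) / 2.0
        radius = float(
            np.linalg.norm(self.mesh.vertices - center, axis=1).max()
        )
        object.__setattr__(self, "_bsphere", (center, radius))

    @classmethod
    def from_stl(cls, path, name: str = "") -> "MeshSurface":
        mesh = trimesh.load_mesh(path)
        return cls(mesh, name=name or str(path))

    def translated(self, v) -> "MeshSurface":
        m = self.mesh.copy()
        m.apply_translation(_vec(v))
        return replace(self, mesh=m)

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        center, radius = self._bsphere
        out = np.zeros(len(points), dtype=bool)
        near = np.linalg.norm(points - center, axis=1) <= radius
        if near.any():
            out[near] = points_in_mesh(self.mesh, points[near])
        return out

    @property
    def aabb(self):
        lo, hi = self.mesh.bounds
        return np.asarray(lo, float), np.asarray(hi, float)

    @property
    def reference_point(self) -> np.ndarray:
        return np.asarray(self.mesh.center_mass, float)


Surface = SphereSurface | HalfSpaceSurface | MeshSurface


def _sphere_sphere_volume(a: SphereSurface, b: SphereSurface) -> float:
    d = float(np.linalg.norm(a.center - b.center))
    r1, r2 = a.radius, b.radius
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * np.pi * r**3
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12.0 * d)
    )


def spherical_cap_volume(radius: float, depth: float) -> float:
    """Volume of a spherical cap of height ``depth`` cut from a sphere."""
    h = float(np.clip(depth, 0.0, 2.0 * radius))
    if h >= 2.0 * radius:
        return 4.0 / 3.0 * np.pi * radius**3
    return np.pi * h * h * (3.0 * radius - h) / 3.0


def _sphere_halfspace(sphere: SphereSurface, half: HalfSpaceSurface) -> float:
    depth = sphere.radius - float((sphere.center - half.point) @ half.normal)
    return spherical_cap_volume(sphere.radius, depth)


def _voxel_volume(a: Surface, b: Surface, pitch: float) -> float:
    boxes = [s.aabb for s in (a, b) if s.aabb is not None]
    if not boxes:
        raise ValidationError("voxel overlap needs at least one bounded surface")
    lo = np.max([box[0] for box in boxes], axis=0)
    hi = np.min([box[1] for box in boxes], axis=0)
    if np.any(hi <= lo):
        return 0.0
    axes = [np.arange(lo[i] + pitch / 2.0, hi[i], pitch) for i in range(3)]
    if any(len(ax) == 0 for ax in axes):
        return 0.0
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    # winnow through the cheap membership tests first so the expensive
    # winding-number mesh test only sees candidate points
    surfaces = sorted(
        (a, b),
        key=lambda s: len(s.mesh.faces) if isinstance(s, MeshSurface) else 0,
    )
    candidates = grid
    for s in surfaces:
        if len(candidates) == 0:
            return 0.0
        candidates = candidates[s.contains(candidates)]
    return float(len(candidates)) * pitch**3


def _mean_normal(a: Surface, b: Surface) -> np.ndarray:
    """Unit direction pushing surface ``a`` away from surface ``b``."""
    if isinstance(b, HalfSpaceSurface):
        return b.normal
    if isinstance(a, HalfSpaceSurface):
        return -a.normal
    return _unit(a.reference_point - b.reference_point)


def penetration_volume(
    surface_a: Surface,
    surface_b: Surface,
    displacement_a=(0.0, 0.0, 0.0),
    pitch: float = 2e-4,
) -> tuple[float, np.ndarray | None]:
    """Overlap volume [m^3] and mean contact normal of two surfaces.

    ``displacement_a`` rigidly translates ``surface_a`` before the test.
    The normal (unit, pushing ``surface_a`` away from ``surface_b``) is
    None when the volume is zero.  Sphere-sphere and sphere-halfspace pairs
    use closed forms; any pair involving a mesh is voxel-sampled at grid
    ``pitch`` [m].
    """
    a = surface_a.translated(displacement_a)
    b = surface_b
    if isinstance(a, SphereSurface) and isinstance(b, SphereSurface):
        vol = _sphere_sphere_volume(a, b)
    elif isinstance(a, SphereSurface) and isinstance(b, HalfSpaceSurface):
        vol = _sphere_halfspace(a, b)
    elif isinstance(a, HalfSpaceSurface) and isinstance(b, SphereSurface):
        vol = _sphere_halfspace(b, a)
    elif isinstance(a, HalfSpaceSurface) and isinstance(b, HalfSpaceSurface):
        raise ValidationError("two half-spaces have no finite overlap volume")
    else:
        vol = _voxel_volume(a, b, pitch)
    if vol <= 0.0:
        return 0.0, None
    return vol, _mean_normal(a, b)


def contact_force(
    pressure_module: float, volume_m3: float, normal
) -> np.ndarray:
    """Elastic-foundation contact force vector: PM * volume along ``normal``."""
    if volume_m3 < 0:
        raise ValidationError(f"penetration volume must be >= 0, got {volume_m3}")
    if pressure_module <= 0:
        raise ValidationError(
            f"pressure module must be > 0, got {pressure_module}"
        )
    if volume_m3 == 0.0:
        return np.zeros(3)
    return pressure_module * volume_m3 * _unit(_vec(normal))


@dataclass(frozen=True)
class ContactPair:
    """Two articulating surfaces plus their pressure module [N/m^3]."""

    name: str
    surface_a: Surface
    surface_b: Surface
    pressure_module: float
    pitch: float = 2e-4

    def __post_init__(self) -> None:
        if self.pressure_module <= 0:
            raise ValidationError(
                f"pair {self.name}: pressure module must be > 0"
            )

    def with_pressure_module(self, pm: float) -> "ContactPair":
        return replace(self, pressure_module=pm)

    def force(self, displacement_a=(0.0, 0.0, 0.0)) -> tuple[np.ndarray, float]:
        """Contact force vector on surface_a and the overlap volume."""
        vol, normal = penetration_volume(
            self.surface_a, self.surface_b, displacement_a, pitch=self.pitch
        )
        if vol == 0.0:
            return np.zeros(3), 0.0
        return contact_force(self.pressure_module, vol, normal), vol
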