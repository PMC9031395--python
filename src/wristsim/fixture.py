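"""Deterministic synthetic wrist fixture.

Generates a complete, self-consistent wrist for testing and demonstration
with no external data: the five-muscle Cardan model plus three articular
contact pairs mirroring the radiocarpal/ulnocarpal joints

    Scaphoid-Radius, Lunate-Radius, Lunate-Ulna.

The carpal articular surfaces are spheres seated over planar facets on the
distal radius/ulna, which keeps penetration volumes closed-form (fast exact
oracles) while the same geometry can be exported as watertight STL meshes
to exercise the mesh contact path.  The facet normals are tilted slightly
out of the forearm axis so that the three translational FDK coordinates are
all statically determinate.

The generator is a pure function of its parameters: the same parameters
(including the seed) always produce byte-identical meshes and configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .contact import ContactPair, HalfSpaceSurface, MeshSurface, SphereSurface
from .errors import ValidationError
from .fdk import FdkProblem
from .mbs import build_default_model
from .model import WristModel

#: Per-pair fixture geometry at scale 1 (all lengths in mm):
#: sphere radius, initial clearance, facet point, facet outward normal.
_PAIR_GEOMETRY = {
    "Scaphoid-Radius": (9.0, 0.0, (15.0, 0.0, -2.0), (0.15, 0.0, 1.0)),
    "Lunate-Radius": (5.0, 0.1, (-2.0, 0.0, -2.0), (-0.10, 0.08, 1.0)),
    "Lunate-Ulna": (3.5, 0.3, (-18.0, 0.0, -3.0), (-0.20, -0.10, 1.0)),
}

#: Default pressure module [N/m^3].
DEFAULT_PM = 0.6e10

#: Default axial forearm load [N].
DEFAULT_AXIAL_LOAD = 140.0


@dataclass(frozen=True)
class WristFixtureParams:
    """Parameters of the synthetic wrist fixture.

    ``scale`` applies geometric similarity to every length (sphere radii,
    clearances, facet positions, muscle paths); ``perturb_mm`` adds a
    reproducible Gaussian jitter (seeded) to the muscle path points.
    """

    scale: float = 1.0
    pressure_module: float = DEFAULT_PM
    axial_load_N: float = DEFAULT_AXIAL_LOAD
    radii_mm: dict = field(
        default_factory=lambda: {k: v[0] for k, v in _PAIR_GEOMETRY.items()}
    )
    clearances_mm: dict = field(
        default_factory=lambda: {k: v[1] for k, v in _PAIR_GEOMETRY.items()}
    )
    strengths_N: dict = field(default_factory=dict)
    seed: int = 42
    perturb_mm: float = 0.0
    mesh_subdivisions: int = 3

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0, got {self.scale}")
        for name, r in self.radii_mm.items():
            if r <= 0:
                raise ValidationError(f"pair {name}: radius must be > 0, got {r}")
        for name, c in self.clearances_mm.items():
            if c < 0:
                raise ValidationError(
                    f"pair {name}: clearance must be >= 0, got {c}"
                )
        if self.pressure_module <= 0:
            raise ValidationError("pressure module must be > 0")
        if self.axial_load_N < 0:
            raise ValidationError("axial load must be >= 0")


def _analytic_pair(params: WristFixtureParams, name: str) -> tuple[SphereSurface, HalfSpaceSurface]:
    s = params.scale
    _r0, _c0, point_mm, normal = _PAIR_GEOMETRY[name]
    radius = params.radii_mm[name] * 1e-3 * s
    clearance = params.clearances_mm[name] * 1e-3 * s
    point = np.asarray(point_mm, float) * 1e-3 * s
    half = HalfSpaceSurface(point, normal)
    center = half.point + (radius + clearance) * half.normal
    return SphereSurface(center, radius), half


def make_fixture(
    params: WristFixtureParams | None = None,
    out_dir: str | Path | None = None,
    use_meshes: bool = False,
) -> tuple[WristModel, FdkProblem]:
    """Build the synthetic wrist model and its FDK contact problem.

    With ``out_dir`` set, one ASCII STL per bone surface plus a YAML
    fixture config are written there.  ``use_meshes=True`` swaps the
    analytic carpal spheres for their exported icosphere meshes in the
    returned contact pairs (the radius/ulna facets stay analytic).
    """
    params = params or WristFixtureParams()
    model = build_default_model(
        {
            "strengths": params.strengths_N,
            "scale": params.scale,
            "perturb_mm": params.perturb_mm,
            "seed": params.seed,
        }
    )

    pairs = []
    meshes: dict[str, trimesh.Trimesh] = {}
    for name in _PAIR_GEOMETRY:
        sphere, half = _analytic_pair(params, name)
        mesh = trimesh.creation.icosphere(
            subdivisions=params.mesh_subdivisions, radius=sphere.radius
        )
        mesh.apply_translation(sphere.center)
        meshes[name.split("-")[0] + "_" + name.split("-")[1]] = mesh
        surface_a = MeshSurface(mesh, name=name) if use_meshes else sphere
        pairs.append(
            ContactPair(name, surface_a, half, params.pressure_module)
        )

    problem = FdkProblem(
        model=model,
        pairs=tuple(pairs),
        axial_load_N=params.axial_load_N,
    )

    if out_dir is not None:
        _export(params, meshes, Path(out_dir))
    return model, problem


def _export(params: WristFixtureParams, meshes: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for stem, mesh in meshes.items():
        (out_dir / f"{stem.lower()}.stl").write_text(
            mesh.export(file_type="stl_ascii")
        )
    config = {
        "scale": params.scale,
        "pressure_module_N_per_m3": params.pressure_module,
        "axial_load_N": params.axial_load_N,
        "seed": params.seed,
        "perturb_mm": params.perturb_mm,
        "pairs": [
            {
                "name": name,
                "sphere_radius_mm": params.radii_mm[name],
                "clearance_mm": params.clearances_mm[name],
                "facet_point_mm": list(_PAIR_GEOMETRY[name][2]),
                "facet_normal": list(_PAIR_GEOMETRY[name][3]),
                "mesh": name.replace("-", "_").lower() + ".stl",
            }
            for name in _PAIR_GEOMETRY
        ],
    }
    (out_dir / "fixture.yaml").write_text(
        yaml.safe_dump(config, sort_keys=True)
    )
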