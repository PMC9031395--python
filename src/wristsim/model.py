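"""Domain types of the quasi-static rigid-body wrist model.

Two rigid segments: the *forearm* (radius + ulna, fixed, defines the global
frame) and the *hand* (carpus, metacarpals and fingers collapsed into one
segment).  They are connected by a Cardan joint: two perpendicular revolute
axes through a common wrist center, one for flexion-extension (FE) and one
for radial-ulnar deviation (RUD).

Frame convention (right-handed, forearm frame == global frame):
    z  forearm long axis, proximal -> distal
    x  FE rotation axis, pointing radially (thumb side)
    y  dorso-palmar axis, palmar -> dorsal

Sign convention: flexion positive about the FE axis, ulnar deviation
positive about the RUD axis (the default RUD axis is -y so that a positive
angle deviates the hand ulnarly).  The FE motion protocol therefore spans
[-60, +80] deg (extension negative) and RUD spans [-20, +40] deg (radial
negative).

Five wrist-crossing muscles are modeled: ECU, ECRB, ECRL, FCR, FCU.  Each
muscle is a polyline from an origin on the forearm, through optional via
points (retinaculum pulleys, fixed to the forearm), to an insertion on the
hand segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

MUSCLE_NAMES = ("ECU", "ECRB", "ECRL", "FCR", "FCU")

#: Admissible joint ranges [deg]: flexion +80 / extension -60,
#: ulnar +40 / radial -20.
FE_RANGE = (-60.0, 80.0)
RUD_RANGE = (-20.0, 40.0)


def _vec(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


@dataclass(frozen=True)
class Segment:
    """A rigid body with a pose and named landmarks (points in body frame)."""

    name: str
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    landmarks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", _vec(self.translation))
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-9
        ):
            raise ValidationError(f"segment {self.name!r}: rotation not proper orthonormal")

    def pose_point(self, p) -> np.ndarray:
        return self.rotation @ _vec(p) + self.translation


@dataclass(frozen=True)
class CardanWristJoint:
    """Two perpendicular revolute axes through the wrist center."""

    fe_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    rud_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        fe = _vec(self.fe_axis)
        rud = _vec(self.rud_axis)
        object.__setattr__(self, "fe_axis", fe)
        object.__setattr__(self, "rud_axis", rud)
        object.__setattr__(self, "center", _vec(self.center))
        if not np.isclose(np.linalg.norm(fe), 1.0, atol=1e-9):
            raise ValidationError("fe_axis must be unit length")
        if not np.isclose(np.linalg.norm(rud), 1.0, atol=1e-9):
            raise ValidationError("rud_axis must be unit length")
        if abs(float(fe @ rud)) > 1e-9:
            raise ValidationError("FE and RUD axes must be perpendicular")


@dataclass(frozen=True)
class PathPoint:
    """One station of a muscle path, attached to a named segment."""

    point: np.ndarray
    segment: str = "forearm"

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", _vec(self.point))
        if self.segment not in ("forearm", "hand"):
            raise ValidationError(f"unknown segment {self.segment!r}")


@dataclass(frozen=True)
class Muscle:
    """A wrist-crossing muscle: polyline path plus isometric strength."""

    name: str
    path: tuple[PathPoint, ...]
    strength_N: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "path", tuple(self.path))
        if len(self.path) < 2:
            raise ValidationError(f"muscle {self.name}: path needs >= 2 points")
        if self.strength_N <= 0:
            raise ValidationError(
                f"muscle {self.name}: strength must be > 0, got {self.strength_N}"
            )


@dataclass(frozen=True)
class WristModel:
    """The full quasi-static model: joint, muscles, external load."""

    joint: CardanWristJoint
    muscles: tuple[Muscle, ...]
    external_force_N: np.ndarray = field(default_factory=lambda: np.array([0.0, 100.0, 0.0]))
    load_point: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.08]))
    fe_range: tuple[float, float] = FE_RANGE
    rud_range: tuple[float, float] = RUD_RANGE

    def __post_init__(self) -> None:
        object.__setattr__(self, "muscles", tuple(self.muscles))
        object.__setattr__(self, "external_force_N", _vec(self.external_force_N))
        object.__setattr__(self, "load_point", _vec(self.load_point))
        zc = float(self.joint.center[2])
        for m in self.muscles:
            z0 = float(m.path[0].point[2])
            z1 = float(m.path[-1].point[2])
            if m.path[0].segment != "forearm" or m.path[-1].segment != "hand":
                raise ValidationError(
                    f"muscle {m.name}: origin must sit on the forearm, insertion on the hand"
                )
            if not (z0 < zc <= z1 + 1e-12):
                raise ValidationError(
                    f"muscle {m.name}: path must span the wrist (origin proximal, "
                    f"insertion distal), got z0={z0}, z1={z1}"
                )

    @property
    def muscle_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.muscles)

    @property
    def strengths(self) -> np.ndarray:
        return np.array([m.strength_N for m in self.muscles])

    def with_external_load(self, force_N, point=None) -> "WristModel":
        return replace(
            self,
            external_force_N=_vec(force_N),
            load_point=self.load_point if point is None else _vec(point),
        )


@dataclass(frozen=True)
class MotionCycle:
    """A time-parameterized joint-angle trajectory in one motion plane."""

    plane: str  # "FE" or "RUD"
    time: np.ndarray  # normalized, increasing, [0, 1]
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.angles_deg, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "angles_deg", a)
        if self.plane not in ("FE", "RUD"):
            raise ValidationError(f"plane must be 'FE' or 'RUD', got {self.plane!r}")
        if t.shape != a.shape or t.ndim != 1 or t.size < 3:
            raise ValidationError("time and angle arrays must be 1-D, equal length >= 3")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time samples must be strictly increasing")
        lo, hi = FE_RANGE if self.plane == "FE" else RUD_RANGE
        if a.min() < lo - 1e-9 or a.max() > hi + 1e-9:
            raise ValidationError(
                f"{self.plane} angles outside [{lo}, {hi}] deg: "
                f"[{a.min()}, {a.max()}]"
            )

    def reversed(self) -> "MotionCycle":
        return MotionCycle(self.plane, 1.0 - self.time[::-1], self.angles_deg[::-1])


@dataclass(frozen=True)
class RecruitmentSolution:
    """Muscle forces distributing a joint torque demand."""

    muscles: tuple[str, ...]
    forces_N: np.ndarray
    objective: float
    residual_Nm: float

    def as_dict(self) -> dict:
        return dict(zip(self.muscles, (float(f) for f in self.forces_N)))
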