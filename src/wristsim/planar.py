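"""Planar static wrist model with summarized flexor/extensor muscles.

The wrist is reduced to a single hinge in the sagittal plane.  All flexors
(or, for the mirrored sweep, all extensors) are lumped into one equivalent
muscle whose lever arm A shortens with wrist deviation alpha as

    A' = A * cos(alpha)

so that the static moment balance  F * D = F_M * A'  yields the summarized
muscle force

    F_M = F * D / (A * cos(alpha)).

The external load F_E applied at the third metacarpal decomposes in the
fixed (laboratory) frame into F_X = F_E sin(alpha) and F_Y = F_E cos(alpha),
whose resultant sqrt(F_X^2 + F_Y^2) equals F_E for every angle.  This style
of single-hinge free-body analysis is the classical entry point for joint
load estimation (Pauwels' hip construction is the archetype) and serves as
the sanity bound for the multi-body models in :mod:`wristsim.mbs`.

Angles are degrees at every public interface, radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError

#: Below this effective lever arm [m] the moment balance is considered
#: degenerate and an error is raised instead of returning huge forces.
MIN_LEVER_ARM = 1e-6


@dataclass(frozen=True)
class PlanarConfig:
    """Geometry and loading of the summarized flexor/extensor model.

    Parameters
    ----------
    lever_arm_flexor_m
        Lever arm A of the lumped flexor group at neutral position [m].
    lever_arm_extensor_m
        Mirror lever arm of the lumped extensor group at neutral [m].
    load_lever_arm_m
        Lever arm D of the external load about the wrist hinge [m]; the
        load acts at the third metacarpal.
    external_load_N
        Magnitude of the external load F_E [N].
    """

    lever_arm_flexor_m: float = 0.010
    lever_arm_extensor_m: float = 0.010
    load_lever_arm_m: float = 0.080
    external_load_N: float = 100.0

    def __post_init__(self) -> None:
        for name in ("lever_arm_flexor_m", "lever_arm_extensor_m", "load_lever_arm_m"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.external_load_N < 0:
            raise ValidationError(
                f"external_load_N must be >= 0, got {self.external_load_N}"
            )

    def lever_arm(self, group: str) -> float:
        if group == "flexor":
            return self.lever_arm_flexor_m
        if group == "extensor":
            return self.lever_arm_extensor_m
        raise ValidationError(f"unknown muscle group {group!r}")


@dataclass(frozen=True)
class PlanarState:
    """Posture of the planar model: deviation angle and posed lever arm."""

    angle_deg: float
    effective_lever_arm_m: float


@dataclass(frozen=True)
class PlanarResult:
    """Muscle force and external joint reaction at one posture."""

    muscle_force_N: float
    reaction_x_N: float
    reaction_y_N: float
    reaction_resultant_N: float


def effective_lever_arm(lever_arm_m: float, angle_deg: float) -> float:
    """Lever arm of the lumped muscle group at deviation ``angle_deg``.

    Returns ``A * cos(alpha)``.  Raises :class:`GeometryError` for angles at
    or beyond 90 degrees, where the lever arm vanishes or flips sign.
    """
    if lever_arm_m <= 0:
        raise ValidationError(f"lever arm must be > 0, got {lever_arm_m}")
    if not 0.0 <= angle_deg < 90.0:
        raise GeometryError(
            f"deviation angle must lie in [0, 90) deg, got {angle_deg}"
        )
    eff = lever_arm_m * math.cos(math.radians(angle_deg))
    if eff < MIN_LEVER_ARM:
        raise GeometryError(
            f"effective lever arm {eff:.3e} m below {MIN_LEVER_ARM} m"
        )
    return eff


def summarized_muscle_force(
    external_torque_Nm: float, lever_arm_m: float, angle_deg: float
) -> float:
    """Summarized muscle force balancing ``external_torque_Nm``.

    Solves the moment balance F*D = F_M*A' for F_M with A' = A cos(alpha).
    """
    if external_torque_Nm < 0:
        raise ValidationError(
            f"external torque must be >= 0, got {external_torque_Nm}"
        )
    return external_torque_Nm / effective_lever_arm(lever_arm_m, angle_deg)


def external_reaction(
    external_load_N: float, angle_deg: float
) -> tuple[float, float, float]:
    """Decompose the external load into fixed-frame components.

    Returns ``(F_X, F_Y, F_R)`` with F_X = F_E sin(alpha),
    F_Y = F_E cos(alpha) and resultant F_R = F_E.
    """
    if external_load_N < 0:
        raise ValidationError(f"external load must be >= 0, got {external_load_N}")
    a = math.radians(angle_deg)
    fx = external_load_N * math.sin(a)
    fy = external_load_N * math.cos(a)
    return fx, fy, math.hypot(fx, fy)


def evaluate(
    config: PlanarConfig,
    angle_deg: float,
    external_torque_Nm: float | None = None,
    group: str = "flexor",
) -> PlanarResult:
    """Full planar solution at one posture.

    If ``external_torque_Nm`` is None it is taken as F_E * D from the config.
    """
    if external_torque_Nm is None:
        external_torque_Nm = config.external_load_N * config.load_lever_arm_m
    fm = summarized_muscle_force(external_torque_Nm, config.lever_arm(group), angle_deg)
    fx, fy, fr = external_reaction(config.external_load_N, angle_deg)
    return PlanarResult(fm, fx, fy, fr)


def sweep_planar(
    config: PlanarConfig,
    angles_deg: Sequence[float] | np.ndarray,
    torques_Nm: Iterable[float] | None = None,
    group: str = "flexor",
) -> pd.DataFrame:
    """Force curves over an angle grid for one or more external torques.

    One row per (torque, angle) with columns ``torque_Nm, angle_deg, F_M_N,
    F_X_N, F_Y_N, F_R_N``.  The reaction columns use the configured external
    load, which is independent of the torque list (the torque sweep mirrors
    varying the load lever arm).
    """
    angles = np.asarray(list(angles_deg), dtype=float)
    if angles.size == 0:
        raise ValidationError("angle grid is empty")
    if torques_Nm is None:
        torques_Nm = [config.external_load_N * config.load_lever_arm_m]
    torques = [float(t) for t in torques_Nm]
    if len(torques) == 0:
        raise ValidationError("torque list is empty")

    lever = config.lever_arm(group)
    rows = []
    for tq in torques:
        for ang in angles:
            fm = summarized_muscle_force(tq, lever, float(ang))
            fx, fy, fr = external_reaction(config.external_load_N, float(ang))
            rows.append((tq, float(ang), fm, fx, fy, fr))
    return pd.DataFrame(
        rows, columns=["torque_Nm", "angle_deg", "F_M_N", "F_X_N", "F_Y_N", "F_R_N"]
    )
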