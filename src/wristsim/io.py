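"""Config and result file handling.

Configs travel as YAML with lengths in millimetres, forces in newtons and
angles in degrees (the units practitioners write); the in-memory model is
strictly SI.  Result tables are plain CSV with the documented headers.
Loading and saving the same config round-trips bit-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .model import MUSCLE_NAMES, Muscle, PathPoint, WristModel
from .planar import PlanarConfig

log = logging.getLogger("wristsim")


def _mm(value_m: float) -> float:
    """Metres to millimetres, rounded to nm so round trips are exact."""
    return round(float(value_m) * 1e3, 6)


# -- planar config ----------------------------------------------------------


def planar_config_to_dict(config: PlanarConfig) -> dict:
    return {
        "lever_arm_flexor_mm": _mm(config.lever_arm_flexor_m),
        "lever_arm_extensor_mm": _mm(config.lever_arm_extensor_m),
        "load_lever_arm_mm": _mm(config.load_lever_arm_m),
        "external_load_N": config.external_load_N,
    }


def planar_config_from_dict(data: dict) -> PlanarConfig:
    try:
        return PlanarConfig(
            lever_arm_flexor_m=float(data["lever_arm_flexor_mm"]) * 1e-3,
            lever_arm_extensor_m=float(data["lever_arm_extensor_mm"]) * 1e-3,
            load_lever_arm_m=float(data["load_lever_arm_mm"]) * 1e-3,
            external_load_N=float(data["external_load_N"]),
        )
    except KeyError as key:
        raise ValidationError(f"planar config missing field {key}") from None


def save_planar_config(config: PlanarConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(planar_config_to_dict(config), sort_keys=True))


def load_planar_config(path) -> PlanarConfig:
    return planar_config_from_dict(yaml.safe_load(Path(path).read_text()))


# -- wrist model config -----------------------------------------------------


def model_to_dict(model: WristModel) -> dict:
    return {
        "joint": {
            "fe_axis": [float(x) for x in model.joint.fe_axis],
            "rud_axis": [float(x) for x in model.joint.rud_axis],
            "center_mm": [_mm(x) for x in model.joint.center],
        },
        "external_load": {
            "force_N": [float(x) for x in model.external_force_N],
            "point_mm": [_mm(x) for x in model.load_point],
        },
        "muscles": [
            {
                "name": m.name,
                "strength_N": float(m.strength_N),
                "path": [
                    {
                        "point_mm": [_mm(x) for x in pp.point],
                        "segment": pp.segment,
                    }
                    for pp in m.path
                ],
            }
            for m in model.muscles
        ],
    }


def model_from_dict(data: dict) -> WristModel:
    from .model import CardanWristJoint  # local to keep import graph flat

    try:
        joint = CardanWristJoint(
            fe_axis=data["joint"]["fe_axis"],
            rud_axis=data["joint"]["rud_axis"],
            center=[x * 1e-3 for x in data["joint"]["center_mm"]],
        )
        muscles = tuple(
            Muscle(
                m["name"],
                tuple(
                    PathPoint([x * 1e-3 for x in pp["point_mm"]], pp["segment"])
                    for pp in m["path"]
                ),
                float(m["strength_N"]),
            )
            for m in data["muscles"]
        )
        return WristModel(
            joint=joint,
            muscles=muscles,
            external_force_N=data["external_load"]["force_N"],
            load_point=[x * 1e-3 for x in data["external_load"]["point_mm"]],
        )
    except KeyError as key:
        raise ValidationError(f"model config missing field {key}") from None


def save_model(model: WristModel, path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=True))


def load_model(path) -> WristModel:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))


# -- result tables ----------------------------------------------------------

MOTION_COLUMNS = (
    ["time", "fe_deg", "rud_deg", "torque_fe_Nm", "torque_rud_Nm"]
    + [f"{m}_N" for m in MUSCLE_NAMES]
    + ["reaction_x_N", "reaction_y_N", "reaction_z_N"]
)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table as CSV with a stable header order."""
    df.to_csv(path, index=False)
    log.info("wrote %d rows to %s (columns: %s)", len(df), path, ", ".join(df.columns))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
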