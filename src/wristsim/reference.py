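"""Literature reference muscle forces and the validation report.

The reference values are average peak and average mean forces [N] of the
five wrist-crossing muscles during the fourth cycle of cyclic FE and RUD
motion, measured in a cadaveric wrist-motion study with servo-controlled
tendon actuation (DeBottis and co-workers); standard deviations in
parentheses in the original tables are carried along.  They are the
standard yardstick for wrist muscle-force simulations: simulated series
are compared muscle by muscle and flagged when they fall outside the
reference +/- 2 SD band.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .model import MUSCLE_NAMES

#: Average peak muscle force [N] as (mean, SD) per motion plane.
PEAK_FORCES_N = {
    "FE": {"ECU": (54, 15), "ECRB": (26, 7), "ECRL": (60, 22), "FCR": (32, 12), "FCU": (33, 5)},
    "RUD": {"ECU": (34, 9), "ECRB": (16, 7), "ECRL": (51, 9), "FCR": (12, 7), "FCU": (34, 12)},
}

#: Average mean muscle force [N] as (mean, SD) per motion plane.
MEAN_FORCES_N = {
    "FE": {"ECU": (23, 2), "ECRB": (11, 6), "ECRL": (25, 6), "FCR": (17, 3), "FCU": (15, 5)},
    "RUD": {"ECU": (21, 4), "ECRB": (5, 3), "ECRL": (27, 3), "FCR": (6, 4), "FCU": (18, 3)},
}

#: Trend reported for inverse-dynamics wrist simulations against these
#: cadaver values: most simulated muscle forces land above the reference,
#: the ECU below it.  Reported for context, never enforced.
LITERATURE_TREND = {
    "ECU": "simulated below reference",
    "ECRB": "simulated above reference",
    "ECRL": "simulated above reference",
    "FCR": "simulated above reference",
    "FCU": "simulated above reference",
}


@dataclass(frozen=True)
class ReferenceMuscleForces:
    """Reference peak and mean forces for one motion plane."""

    motion: str
    peak_N: dict
    mean_N: dict

    @classmethod
    def from_literature(cls, motion: str) -> "ReferenceMuscleForces":
        if motion not in PEAK_FORCES_N:
            raise ValidationError(f"motion must be 'FE' or 'RUD', got {motion!r}")
        return cls(motion, PEAK_FORCES_N[motion], MEAN_FORCES_N[motion])


def validation_report(
    simulated: pd.DataFrame, reference: ReferenceMuscleForces
) -> pd.DataFrame:
    """Compare a simulated muscle-force series with the reference values.

    ``simulated`` must carry one ``<muscle>_N`` column per muscle (the
    layout written by :func:`wristsim.mbs.simulate_motion`).  Per muscle
    the report lists the simulated peak (max |force|) and mean of the
    series against the reference (mean, SD), the simulated/reference
    ratios, and a flag when the simulated value falls outside the
    reference +/- 2 SD band.
    """
    rows = []
    for name in MUSCLE_NAMES:
        col = f"{name}_N"
        if col not in simulated.columns:
            raise ValidationError(f"simulated series is missing column {col!r}")
        series = simulated[col].abs()
        sim_peak = float(series.max())
        sim_mean = float(series.mean())
        ref_peak, sd_peak = reference.peak_N[name]
        ref_mean, sd_mean = reference.mean_N[name]
        rows.append(
            {
                "muscle": name,
                "sim_peak_N": sim_peak,
                "ref_peak_N": float(ref_peak),
                "ref_peak_sd_N": float(sd_peak),
                "peak_ratio": sim_peak / ref_peak,
                "peak_outside_2sd": abs(sim_peak - ref_peak) > 2 * sd_peak,
                "sim_mean_N": sim_mean,
                "ref_mean_N": float(ref_mean),
                "ref_mean_sd_N": float(sd_mean),
                "mean_ratio": sim_mean / ref_mean,
                "mean_outside_2sd": abs(sim_mean - ref_mean) > 2 * sd_mean,
                "literature_trend": LITERATURE_TREND[name],
            }
        )
    return pd.DataFrame(rows)
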