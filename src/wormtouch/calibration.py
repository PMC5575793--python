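"""Membrane displacement vs. actuation pressure calibration.

The stimulating PDMS membrane deflects roughly linearly with the applied
pressure over the working range (10-60 psi), so a per-device calibration is
an ordinary least-squares line through measured (pressure, displacement)
pairs, reported with its R-squared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CalibrationTable", "CalibrationFit", "linear_fit"]


@dataclass(frozen=True)
class CalibrationTable:
    """Paired (pressure psi, displacement um) measurements."""

    pressure: np.ndarray
    displacement: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pressure", np.asarray(self.pressure, dtype=float))
        object.__setattr__(
            self, "displacement", np.asarray(self.displacement, dtype=float)
        )
        if self.pressure.shape != self.displacement.shape:
            raise ValueError("pressure and displacement must be paired")
        if self.pressure.size < 3:
            raise ValueError("need at least 3 calibration points")
        if (self.pressure < 0).any():
            raise ValueError("pressures must be nonnegative")

    @classmethod
    def from_csv(cls, path) -> "CalibrationTable":
        df = pd.read_csv(path)
        return cls(
            pressure=df["pressure_psi"].to_numpy(float),
            displacement=df["displacement_um"].to_numpy(float),
        )


@dataclass(frozen=True)
class CalibrationFit:
    slope: float  # um per psi
    intercept: float  # um
    r_squared: float  # NaN when degenerate
    degenerate: bool  # SS_tot == 0 (constant displacement)
    through_origin: bool
    n: int

    def predict(self, pressure) -> np.ndarray:
        return self.slope * np.asarray(pressure, dtype=float) + self.intercept

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope_um_per_psi": self.slope,
                    "intercept_um": self.intercept,
                    "r_squared": None if self.degenerate else self.r_squared,
                    "degenerate": self.degenerate,
                    "through_origin": self.through_origin,
                    "n": self.n,
                },
                fh,
                indent=2,
            )


def linear_fit(
    table: CalibrationTable, through_origin: bool = False
) -> CalibrationFit:
    """OLS line displacement = slope * pressure (+ intercept).

    ``r_squared = 1 - SS_res/SS_tot`` with SS_tot about the mean; a constant
    displacement (SS_tot = 0) is flagged degenerate instead of reporting a
    0 or 1.  Raises when all pressures are identical (slope unidentifiable).
    """
    x, y = table.pressure, table.displacement
    if np.ptp(x) == 0:
        raise ValueError("all pressures identical: slope is unidentifiable")
    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
    else:
        A = np.column_stack([x, np.ones_like(x)])
        (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
        slope, intercept = float(slope), float(intercept)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    degenerate = ss_tot == 0.0
    r2 = np.nan if degenerate else 1.0 - ss_res / ss_tot
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        r_squared=float(r2),
        degenerate=degenerate,
        through_origin=through_origin,
        n=int(x.size),
    )
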