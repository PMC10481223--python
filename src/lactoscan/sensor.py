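"""Device-level conductivity model: conductance -> calibrated conductivity at 25 degC.

The sensing device holds a small milk sample between two fixed electrodes
(cell constant K, 1/cm) and reports conductance in mS together with the
sample temperature.  Conductivity is obtained by multiplying conductance by
the cell constant, compensating to the 25 degC reference with a linear
temperature model, and inverting a per-device affine distortion fitted from
potassium-chloride standard solutions.

Units: conductance mS; conductivity mS/cm; temperature degC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientCalibrationError,
    InvalidCalibrationError,
    OutOfRangeTemperatureError,
    SchemaError,
    ValidationError,
)

#: KCl standards conventionally used for two-point conductivity calibration
#: (0.01 M and 0.1 M at 25 degC), in mS/cm.
DEFAULT_KCL_STANDARDS = (1.413, 12.88)

#: Linear temperature-compensation coefficient for KCl-like aqueous
#: electrolytes, fraction per degC.
DEFAULT_TEMP_COEFFICIENT = 0.020

#: Sample-cell volumes (ml) the device was characterised with.
TESTED_SAMPLE_VOLUMES = (0.2, 0.5, 1.0, 2.0)

READINGS_COLUMNS = [
    "device_id",
    "timestamp",
    "breast_side",
    "conductance_mS",
    "temperature_C",
    "sample_volume_ml",
]

CALIBRATION_COLUMNS = ["device_id", "true_mS_cm", "measured_mS_cm"]


@dataclass(frozen=True)
class RawSensorReading:
    """One raw device measurement.

    Parameters
    ----------
    conductance:
        Measured conductance in mS, strictly positive.
    temperature:
        Sample temperature in degC, in (0, 50).
    """

    device_id: str
    conductance: float
    temperature: float
    timestamp: datetime
    breast_side: str
    sample_volume: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.conductance) or self.conductance <= 0:
            raise ValidationError(
                f"conductance must be positive and finite, got {self.conductance}"
            )
        if not 0 < self.temperature < 50:
            raise ValidationError(
                f"temperature must be in (0, 50) degC, got {self.temperature}"
            )
        if self.breast_side not in ("left", "right"):
            raise ValidationError(f"breast_side must be left|right, got {self.breast_side!r}")
        if self.sample_volume is not None:
            if self.sample_volume <= 0:
                raise ValidationError(f"sample_volume must be positive, got {self.sample_volume}")
            if not any(np.isclose(self.sample_volume, v) for v in TESTED_SAMPLE_VOLUMES):
                warnings.warn(
                    f"sample_volume {self.sample_volume} ml outside the tested set "
                    f"{TESTED_SAMPLE_VOLUMES}",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class DeviceCalibration:
    """Per-device measurement model.

    ``measured = gain * true + offset`` is the fitted distortion of the
    device relative to KCl standards; :func:`apply_calibration` inverts it.
    ``cell_constant`` (K, 1/cm) converts conductance to conductivity and
    ``temp_coefficient`` (fraction per degC) drives the linear compensation
    to 25 degC.
    """

    device_id: str
    cell_constant: float = 1.0
    temp_coefficient: float = DEFAULT_TEMP_COEFFICIENT
    gain: float = 1.0
    offset: float = 0.0
    standards_used: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.cell_constant <= 0:
            raise InvalidCalibrationError(f"cell_constant must be > 0, got {self.cell_constant}")
        if self.gain <= 0:
            raise InvalidCalibrationError(f"gain must be > 0, got {self.gain}")
        if not 0 <= self.temp_coefficient < 0.1:
            raise InvalidCalibrationError(
                f"temp_coefficient must be in [0, 0.1), got {self.temp_coefficient}"
            )


@dataclass(frozen=True)
class ConductivitySample:
    """Calibrated, temperature-corrected conductivity at 25 degC.

    ``non_physical`` flags values clipped up to 0 after calibration so batch
    pipelines can keep running while auditing degenerate readings.
    """

    conductivity_25C: float
    device_id: str
    timestamp: datetime
    breast_side: str
    non_physical: bool = False


def conductance_to_conductivity(reading: RawSensorReading, cal: DeviceCalibration) -> float:
    """Convert measured conductance (mS) to raw conductivity (mS/cm).

    Pure geometry: conductivity = conductance x cell constant.  Strictly
    monotone increasing in conductance.
    """
    return reading.conductance * cal.cell_constant


def temperature_correct(
    conductivity: float, temperature: float, temp_coefficient: float = DEFAULT_TEMP_COEFFICIENT
) -> float:
    """Compensate conductivity measured at ``temperature`` to 25 degC.

    Linear model: sigma_T = sigma_25 * (1 + alpha * (T - 25)), inverted here
    as sigma_25 = sigma_T / (1 + alpha * (T - 25)).  Identity at T = 25.
    """
    denom = 1.0 + temp_coefficient * (temperature - 25.0)
    if denom <= 0:
        raise OutOfRangeTemperatureError(
            f"temperature {temperature} degC degenerates the linear compensation "
            f"(1 + alpha*(T-25) = {denom:.4g} <= 0)"
        )
    return conductivity / denom


def fit_calibration(
    standards: Sequence[tuple[float, float]],
    device_id: str,
    *,
    cell_constant: float = 1.0,
    temp_coefficient: float = DEFAULT_TEMP_COEFFICIENT,
) -> DeviceCalibration:
    """Fit the affine measured = gain*true + offset map by least squares.

    ``standards`` is a sequence of (true mS/cm, measured mS/cm) pairs, e.g.
    KCl standard solutions read on the device.  With exactly two distinct
    standards the fit is exact (2x2 linear solve).
    """
    standards = [(float(t), float(m)) for t, m in standards]
    true_vals = np.array([t for t, _ in standards])
    meas_vals = np.array([m for _, m in standards])
    if len(standards) < 2 or len(np.unique(true_vals)) < 2:
        raise InsufficientCalibrationError(
            f"device {device_id!r}: need >= 2 standards with distinct true values, "
            f"got {len(standards)}"
        )
    gain, offset = np.polyfit(true_vals, meas_vals, 1)
    if gain <= 0:
        raise InvalidCalibrationError(
            f"device {device_id!r}: fitted gain {gain:.4g} is non-positive"
        )
    return DeviceCalibration(
        device_id=device_id,
        cell_constant=cell_constant,
        temp_coefficient=temp_coefficient,
        gain=float(gain),
        offset=float(offset),
        standards_used=tuple(standards),
    )


def apply_calibration(raw: float, cal: DeviceCalibration) -> float:
    """Invert the fitted device distortion: true = (measured - offset) / gain."""
    if cal.gain <= 0:
        raise InvalidCalibrationError(f"gain must be > 0, got {cal.gain}")
    return (raw - cal.offset) / cal.gain


def process_reading(reading: RawSensorReading, cal: DeviceCalibration) -> ConductivitySample:
    """Full chain: conductance -> calibrated conductivity at 25 degC.

    Order mirrors the device/app split: geometry (firmware), per-device
    calibration (app), then temperature compensation.  Non-physical results
    (<= 0 after calibration) are clipped to 0 and flagged rather than raised.
    """
    raw = conductance_to_conductivity(reading, cal)
    calibrated = apply_calibration(raw, cal)
    corrected = temperature_correct(calibrated, reading.temperature, cal.temp_coefficient)
    non_physical = corrected <= 0
    return ConductivitySample(
        conductivity_25C=max(corrected, 0.0),
        device_id=reading.device_id,
        timestamp=reading.timestamp,
        breast_side=reading.breast_side,
        non_physical=non_physical,
    )


# ---------------------------------------------------------------------------
# CSV / JSON interfaces


def read_readings_csv(path) -> list[RawSensorReading]:
    """Parse a readings CSV (see README schema) into RawSensorReading objects."""
    df = pd.read_csv(path)
    missing = [c for c in READINGS_COLUMNS if c not in df.columns and c != "sample_volume_ml"]
    if missing:
        raise SchemaError(f"readings CSV missing columns: {missing}")
    readings = []
    for row in df.itertuples(index=False):
        vol = getattr(row, "sample_volume_ml", None)
        readings.append(
            RawSensorReading(
                device_id=str(row.device_id),
                conductance=float(row.conductance_mS),
                temperature=float(row.temperature_C),
                timestamp=pd.Timestamp(row.timestamp).to_pydatetime(),
                breast_side=str(row.breast_side),
                sample_volume=None if vol is None or pd.isna(vol) else float(vol),
            )
        )
    return readings


def fit_calibrations_from_csv(path, **kwargs) -> dict[str, DeviceCalibration]:
    """Fit one DeviceCalibration per device from a standards CSV."""
    df = pd.read_csv(path)
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"calibration CSV missing columns: {missing}")
    out: dict[str, DeviceCalibration] = {}
    for device_id, grp in df.groupby("device_id", sort=True):
        pairs = list(zip(grp["true_mS_cm"], grp["measured_mS_cm"]))
        out[str(device_id)] = fit_calibration(pairs, str(device_id), **kwargs)
    return out


def save_calibrations(cals: dict[str, DeviceCalibration], path) -> None:
    payload = {
        dev: {
            "cell_constant": c.cell_constant,
            "temp_coefficient": c.temp_coefficient,
            "gain": c.gain,
            "offset": c.offset,
            "standards_used": [list(s) for s in c.standards_used],
        }
        for dev, c in cals.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_calibrations(path) -> dict[str, DeviceCalibration]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        dev: DeviceCalibration(
            device_id=dev,
            cell_constant=d["cell_constant"],
            temp_coefficient=d["temp_coefficient"],
            gain=d["gain"],
            offset=d["offset"],
            standards_used=tuple(tuple(s) for s in d["standards_used"]),
        )
        for dev, d in payload.items()
    }
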