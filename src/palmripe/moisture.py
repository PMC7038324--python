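"""Ripeness labelling from moisture content, moisture-voltage regression, and
moisture-content resolution.

Oil-palm fruit ripeness is defined by mesocarp moisture content: fruit at or
below 30% moisture are ripe (maximum oil content), fruit above 53% have not
started to mature and are unripe, and the band in between is under-ripe.
The fruit-battery sensor reads a load-resistance voltage that varies roughly
linearly with moisture, so an ordinary least-squares fit of moisture (%) on
voltage (mV) calibrates the sensor; the magnitude of its slope, in % per mV,
is the moisture-content *resolution* — multiplied by the digitizer's voltage
step it gives the moisture change one ADC count can resolve.  A slope below
1 %/mV is considered fine enough for field grading.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RipenessLabel",
    "RegressionFit",
    "MoistureResolution",
    "DegenerateDesignError",
    "label_ripeness",
    "fit_moisture_regression",
    "adc_voltage_resolution",
    "moisture_resolution",
    "RIPE_MAX_MOISTURE",
    "UNDER_RIPE_MAX_MOISTURE",
]

#: Moisture (%) at or below which a fruit is graded ripe.
RIPE_MAX_MOISTURE = 30.0
#: Moisture (%) at or below which (and above RIPE_MAX_MOISTURE) a fruit is under-ripe.
UNDER_RIPE_MAX_MOISTURE = 53.0


class RipenessLabel(enum.Enum):
    """Three-way ripeness grade defined on moisture content."""

    RIPE = "ripe"
    UNDER_RIPE = "under_ripe"
    UNRIPE = "unripe"

    def __str__(self) -> str:  # friendly CSV serialization
        return self.value


class DegenerateDesignError(ValueError):
    """Raised when a regression design has no spread in the predictor."""


def label_ripeness(moisture: float) -> RipenessLabel:
    """Grade a fruit from its moisture content (%).

    Moisture of 30% or less is ripe, more than 30% up to 53% is under-ripe,
    and above 53% is unripe.  Both boundaries belong to the lower class
    (30 -> ripe, 53 -> under-ripe).

    Parameters
    ----------
    moisture : float
        Moisture content in percent, in [0, 100].
    """
    if not math.isfinite(moisture) or not 0.0 <= moisture <= 100.0:
        raise ValueError(f"moisture must be within [0, 100] %, got {moisture!r}")
    if moisture <= RIPE_MAX_MOISTURE:
        return RipenessLabel.RIPE
    if moisture <= UNDER_RIPE_MAX_MOISTURE:
        return RipenessLabel.UNDER_RIPE
    return RipenessLabel.UNRIPE


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares fit of moisture (%) on load voltage (mV).

    Attributes
    ----------
    slope : float
        Moisture change per mV of load voltage (%/mV).
    intercept : float
        Moisture at zero voltage (%).
    r_squared : float
        Coefficient of determination, in [0, 1].
    n : int
        Number of (voltage, moisture) pairs fitted.
    """

    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, v_l_mv: float | np.ndarray) -> float | np.ndarray:
        """Predicted moisture (%) at a load voltage (mV)."""
        return self.intercept + self.slope * np.asarray(v_l_mv)


def fit_moisture_regression(
    pairs: Iterable[tuple[float, float]] | Sequence[Sequence[float]],
) -> RegressionFit:
    """Least-squares regression of moisture content on load-resistance voltage.

    Parameters
    ----------
    pairs : iterable of (v_l_mv, moisture_pct)
        Voltage in mV (predictor) and moisture in percent (response).  Each
        fruit contributes its replicate-averaged voltage once.

    Returns
    -------
    RegressionFit

    Raises
    ------
    ValueError
        Fewer than two pairs.
    DegenerateDesignError
        All voltages identical (slope undefined).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (v_l_mv, moisture_pct) tuples")
    n = arr.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 pairs to fit a line, got {n}")
    x, y = arr[:, 0], arr[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateDesignError("all voltage values identical; slope undefined")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    ss_res = float(np.sum((y - (intercept + slope * x)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # Constant response is fitted exactly by the horizontal line: report R^2 = 1.
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return RegressionFit(slope=slope, intercept=intercept, r_squared=float(np.clip(r2, 0.0, 1.0)), n=n)


def adc_voltage_resolution(drive_voltage: float, bits: int) -> float:
    """Voltage step of an analog-to-digital converter, in mV per count.

    A ``bits``-wide converter spans ``drive_voltage`` volts over ``2**bits``
    codes; e.g. a 12-bit converter at 3.3 V resolves ~0.8 mV per count.
    """
    if bits < 1:
        raise ValueError(f"bits must be >= 1, got {bits}")
    if drive_voltage <= 0:
        raise ValueError(f"drive_voltage must be positive, got {drive_voltage}")
    return drive_voltage / (2**bits) * 1000.0


@dataclass(frozen=True)
class MoistureResolution:
    """Moisture resolution of the sensor chain.

    ``percent_per_mv`` is the magnitude of the calibration slope;
    ``percent_per_lsb`` is the moisture change corresponding to one ADC count.
    ``acceptable`` flags a resolution finer than 1 %/mV.
    """

    percent_per_mv: float
    percent_per_lsb: float
    acceptable: bool


#: Resolution (%/mV) below which the sensor is considered accurate enough.
RESOLUTION_CRITERION = 1.0


def moisture_resolution(fit: RegressionFit, adc_step_mv: float) -> MoistureResolution:
    """Combine a calibration slope with the ADC step into moisture resolution.

    Parameters
    ----------
    fit : RegressionFit
        Calibration of moisture on voltage at the chosen load resistance.
    adc_step_mv : float
        ADC voltage step in mV (see :func:`adc_voltage_resolution`).
    """
    if adc_step_mv <= 0:
        raise ValueError(f"adc_step_mv must be positive, got {adc_step_mv}")
    per_mv = abs(fit.slope)
    return MoistureResolution(
        percent_per_mv=per_mv,
        percent_per_lsb=per_mv * adc_step_mv,
        acceptable=per_mv < RESOLUTION_CRITERION,
    )
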