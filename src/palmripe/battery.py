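"""Equivalent-circuit model of the fruit battery and load-resistance selection.

Zinc and copper electrodes pierced into a fruit form a galvanic cell whose
electrolyte is the fruit's moisture.  The cell is modelled as an electromotive
force ``v_i`` in series with an internal resistance ``r_i``; the voltage across
an external load ``r_l`` follows the voltage divider

    V_L = r_l / (r_i + r_l) * v_i.

Drier (riper) fruit has higher internal resistance and hence lower load
voltage.  Sweeping the load resistance and comparing ripe/unripe class means
with the percentage statistic |d_VL| identifies loads that discriminate the
classes; among those, the load whose moisture calibration has the smallest
|slope| (%/mV, i.e. the finest moisture resolution) is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .moisture import RipenessLabel

__all__ = [
    "BatteryCircuit",
    "SweepSummary",
    "FruitSample",
    "InsufficientClassError",
    "NoCandidateError",
    "load_voltage",
    "voltage_difference_pct",
    "sweep_analysis",
    "select_load_resistance",
    "DEFAULT_DVL_FLOOR",
]

#: Default |d_VL| floor (%) for shortlisting load resistances.
DEFAULT_DVL_FLOOR = 70.0


class InsufficientClassError(ValueError):
    """A required ripeness class has no samples."""


class NoCandidateError(ValueError):
    """No load resistance passed the |d_VL| shortlist floor."""


@dataclass(frozen=True)
class BatteryCircuit:
    """Equivalent circuit of one fruit: EMF ``v_i`` (V) and internal resistance ``r_i`` (Ω)."""

    v_i: float
    r_i: float

    def __post_init__(self) -> None:
        if not self.v_i > 0:
            raise ValueError(f"v_i must be positive, got {self.v_i}")
        if self.r_i < 0:
            raise ValueError(f"r_i must be non-negative, got {self.r_i}")


@dataclass(frozen=True)
class SweepSummary:
    """Class-mean load voltages and their percentage difference at one load.

    ``dvl_pct`` is |(mean ripe − mean unripe) / mean unripe| × 100.
    """

    r_l: float
    mean_vl_ripe: float
    mean_vl_unripe: float
    dvl_pct: float


@dataclass
class FruitSample:
    """One measured fruit.

    Attributes
    ----------
    sample_id : str
    label : RipenessLabel
    moisture : float or None
        Moisture content (%), if determined.
    voltages : dict
        Replicate-averaged load voltage in volts, keyed by load resistance (Ω).
    r_over_g : float or None
        Color feature R_ave/G_ave from the corrected image, if available.
    """

    sample_id: str
    label: RipenessLabel
    moisture: float | None = None
    voltages: dict[float, float] = field(default_factory=dict)
    r_over_g: float | None = None


def load_voltage(circuit: BatteryCircuit, r_l: float) -> float:
    """Voltage (V) across a load resistance ``r_l`` (Ω) connected to the fruit cell.

    Strictly increasing in ``r_l``, bounded by ``v_i``; equals ``v_i / 2``
    when the load matches the internal resistance.
    """
    if r_l <= 0:
        raise ValueError(f"r_l must be positive, got {r_l}")
    return r_l / (circuit.r_i + r_l) * circuit.v_i


def voltage_difference_pct(v_l_ripe: float, v_l_unripe: float) -> float:
    """Percentage load-voltage difference |d_VL| between ripe and unripe fruit.

    |d_VL| = |(V_L,ripe − V_L,unripe) / V_L,unripe| × 100.  Large values mean
    the load discriminates the classes well.
    """
    if v_l_unripe == 0:
        raise ZeroDivisionError("unripe load voltage is zero; |d_VL| undefined")
    return abs((v_l_ripe - v_l_unripe) / v_l_unripe) * 100.0


def sweep_analysis(
    samples: Iterable[FruitSample], r_l_values: Sequence[float]
) -> list[SweepSummary]:
    """Class-mean load voltages and |d_VL| at each swept load resistance.

    Only ripe and unripe samples enter the sweep (under-ripe fruit are
    excluded from load-resistance determination); per load, the ripe and
    unripe class means are computed first and |d_VL| is applied to the means.

    Raises
    ------
    InsufficientClassError
        If either the ripe or the unripe class is empty.
    KeyError
        If a sample lacks a voltage at a requested load.
    """
    ripe = [s for s in samples if s.label is RipenessLabel.RIPE]
    unripe = [s for s in samples if s.label is RipenessLabel.UNRIPE]
    for name, group in (("ripe", ripe), ("unripe", unripe)):
        if not group:
            raise InsufficientClassError(f"no samples in class {name!r}")
    out = []
    for r_l in r_l_values:
        mean_ripe = sum(s.voltages[r_l] for s in ripe) / len(ripe)
        mean_unripe = sum(s.voltages[r_l] for s in unripe) / len(unripe)
        out.append(
            SweepSummary(
                r_l=r_l,
                mean_vl_ripe=mean_ripe,
                mean_vl_unripe=mean_unripe,
                dvl_pct=voltage_difference_pct(mean_ripe, mean_unripe),
            )
        )
    return out


def select_load_resistance(
    summaries: Iterable[SweepSummary],
    slopes: Mapping[float, float],
    dvl_floor: float = DEFAULT_DVL_FLOOR,
) -> float:
    """Choose the load resistance for moisture estimation.

    Loads whose |d_VL| is at least ``dvl_floor`` percent form the shortlist;
    among them the load with the smallest calibration-slope magnitude (finest
    moisture resolution, %/mV) wins.  Ties go to the smallest resistance.

    Parameters
    ----------
    summaries : iterable of SweepSummary
    slopes : mapping r_l -> slope (%/mV)
        Moisture-calibration slope at each shortlisted load.
    dvl_floor : float
        Shortlist threshold in percent.

    Raises
    ------
    NoCandidateError
        Empty shortlist.
    KeyError
        A shortlisted load has no slope entry.
    """
    shortlist = [s.r_l for s in summaries if s.dvl_pct >= dvl_floor]
    if not shortlist:
        raise NoCandidateError(f"no load resistance reached |d_VL| >= {dvl_floor}%")
    missing = [r for r in shortlist if r not in slopes]
    if missing:
        raise KeyError(f"no calibration slope for shortlisted load(s) {missing}")
    return min(shortlist, key=lambda r: (abs(slopes[r]), r))
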