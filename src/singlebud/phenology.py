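"""Dormancy-stage assessment: budbreak forcing ratios and Utah chilling.

Dormancy status is scored operationally: excised shoots are forced under
warm long days and a stage is called *released* when at least half of its
buds open within the assay window.  Chilling exposure in the field is
summarized as Utah-model chill units — each hour contributes a weight
that peaks for moderate cold and turns negative for warm hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ForcingAssay",
    "ChillSeries",
    "UTAH_WEIGHT_BANDS",
    "budbreak_ratio",
    "utah_chill_units",
]

#: Utah-model temperature bands as (lower, upper, weight), evaluated in
#: order with closed intervals as listed (temperatures in deg C).  These
#: are the classical band boundaries; pass an alternative table to
#: :func:`utah_chill_units` to use another dialect.
UTAH_WEIGHT_BANDS: tuple[tuple[float, float, float], ...] = (
    (-float("inf"), 1.4, 0.0),
    (1.5, 2.4, 0.5),
    (2.5, 9.1, 1.0),
    (9.2, 12.4, 0.5),
    (12.5, 15.9, 0.0),
    (16.0, 18.0, -0.5),
    (18.0, float("inf"), -1.0),
)


@dataclass(frozen=True)
class ForcingAssay:
    """Budbreak-forcing outcome for one sampling date.

    ``opened`` of ``total`` scored buds reached the green stage after the
    forcing incubation; a ratio of 0.5 or higher calls the stage
    dormancy-released.
    """

    date: str
    opened: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValueError("total must be >= 1")
        if not 0 <= self.opened <= self.total:
            raise ValueError(
                f"opened={self.opened} outside [0, total={self.total}]")

    @property
    def ratio(self) -> float:
        return self.opened / self.total

    @property
    def released(self) -> bool:
        return self.ratio >= 0.5


def budbreak_ratio(opened: int, total: int) -> tuple[float, str]:
    """Forcing ratio and the dormancy call it implies.

    Returns ``(ratio, call)`` with ``call`` being ``"released"`` when the
    ratio reaches 0.5 (boundary inclusive) and ``"dormant"`` otherwise.
    """
    assay = ForcingAssay(date="", opened=opened, total=total)
    return assay.ratio, "released" if assay.released else "dormant"


@dataclass(frozen=True)
class ChillSeries:
    """Hourly temperatures with their cumulative Utah chill units."""

    hourly_temps: tuple[float, ...]
    cu: tuple[float, ...]  # cumulative, same length as hourly_temps

    @property
    def total(self) -> float:
        return self.cu[-1] if self.cu else 0.0


def _utah_weight(temp: float,
                 bands: Sequence[tuple[float, float, float]]) -> float:
    for low, high, weight in bands:
        if low <= temp <= high:
            return weight
    raise ValueError(f"temperature {temp} matches no band")


def utah_chill_units(
    hourly_temps: Sequence[float],
    bands: Sequence[tuple[float, float, float]] = UTAH_WEIGHT_BANDS,
) -> ChillSeries:
    """Cumulative Utah chill units over an hourly temperature series.

    Each hour's increment is the weight of the band containing its
    temperature; between-band temperatures (possible because the classic
    table is written to one decimal) take the nearest lower band's
    weight.  An empty series yields total 0.
    """
    temps = [float(t) for t in hourly_temps]
    if any(not np.isfinite(t) for t in temps):
        raise ValueError("temperatures must be finite")
    increments = []
    for t in temps:
        try:
            increments.append(_utah_weight(t, bands))
        except ValueError:
            # e.g. 1.45 deg C with the classic one-decimal band table
            lows = [b for b in bands if b[0] <= t]
            increments.append(lows[-1][2] if lows else bands[0][2])
    return ChillSeries(hourly_temps=tuple(temps),
                       cu=tuple(np.cumsum(increments)) if temps else ())
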