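"""Reconstruction of monthly per-well pumping schedules.

Historical well operations are documented only as capacities and
in/out-of-service dates, while the treatment plant's total monthly
demand is known.  The reconstruction rule distributes each month's
demand across the wells in service in proportion to rated capacity:

    rate_i(m) = demand(m) * capacity_i / sum_j capacity_j   (j in service)

which is the minimal rule consistent with the documented constraints and
conserves demand exactly every month.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DemandSeries, WellRecord
from .timeline import MonthIndex, MonthlySeries

__all__ = [
    "PumpingSchedule",
    "reconstruct_schedule",
    "service_matrix",
    "CapacityShortfallError",
    "CoverageError",
]


class CapacityShortfallError(ValueError):
    """Demand exceeds total in-service capacity in some month."""


class CoverageError(ValueError):
    """Demand is positive in a month with no well in service."""


@dataclass
class PumpingSchedule:
    """Monthly pumping rate (m³/day) per well; zero outside service.

    ``clock`` is only needed when ``rates`` is empty (a site with no
    wells still has a clock to cover).
    """

    rates: dict[str, MonthlySeries]
    clock: tuple[MonthIndex, MonthIndex] | None = None

    def __post_init__(self) -> None:
        starts = {s.start for s in self.rates.values()}
        lengths = {len(s) for s in self.rates.values()}
        if len(starts) > 1 or len(lengths) > 1:
            raise ValueError("all well series must share the same clock")
        if not self.rates and self.clock is None:
            raise ValueError("an empty schedule needs an explicit clock")
        for wid, s in self.rates.items():
            if np.any(np.isnan(s.values)):
                raise ValueError(f"well {wid}: schedule has missing months (use 0)")

    @property
    def start(self) -> MonthIndex:
        if not self.rates:
            return self.clock[0]
        return next(iter(self.rates.values())).start

    @property
    def end(self) -> MonthIndex:
        if not self.rates:
            return self.clock[1]
        return next(iter(self.rates.values())).end

    def covers(self, when: MonthIndex) -> bool:
        return self.start <= when <= self.end

    def rates_for(self, when: MonthIndex) -> dict[str, float]:
        return {wid: s.value_at(when) for wid, s in self.rates.items()}

    def total(self, when: MonthIndex) -> float:
        return sum(self.rates_for(when).values())

    def to_frame(self) -> pd.DataFrame:
        """Month × well matrix of rates with ISO month index."""
        from .timeline import month_range

        months = [str(m) for m in month_range(self.start, self.end)]
        return pd.DataFrame(
            {wid: s.values for wid, s in self.rates.items()}, index=pd.Index(months, name="month")
        )

    def scaled(self, factor: float) -> "PumpingSchedule":
        return PumpingSchedule(
            {wid: MonthlySeries(s.start, s.values * factor) for wid, s in self.rates.items()},
            clock=self.clock,
        )


def service_matrix(wells: list[WellRecord], clock: list[MonthIndex]) -> pd.DataFrame:
    """Boolean in-service table, months as rows, wells as columns.

    Service intervals are inclusive of both the start and the end month.
    """
    data = {
        w.id: [w.in_service(m) for m in clock] for w in wells
    }
    return pd.DataFrame(data, index=pd.Index([str(m) for m in clock], name="month"), dtype=bool)


def reconstruct_schedule(wells: list[WellRecord], demand: DemandSeries) -> PumpingSchedule:
    """Capacity-proportional monthly pumping schedule meeting WTP demand.

    Raises :class:`CoverageError` if a month has demand but no in-service
    well, and :class:`CapacityShortfallError` if the in-service capacity
    cannot meet demand (the month is named in either case).
    """
    clock = demand.series.months()
    rates = {w.id: np.zeros(len(clock)) for w in wells}
    for i, month in enumerate(clock):
        d = demand.at(month)
        active = [w for w in wells if w.in_service(month)]
        if d <= 0:
            continue
        if not active:
            raise CoverageError(f"demand {d:.1f} m³/day in {month} but no well in service")
        total_cap = sum(w.capacity for w in active)
        if total_cap < d:
            raise CapacityShortfallError(
                f"month {month}: demand {d:.1f} m³/day exceeds in-service capacity {total_cap:.1f}"
            )
        for w in active:
            rates[w.id][i] = d * w.capacity / total_cap
    start = clock[0]
    return PumpingSchedule(
        {wid: MonthlySeries(start, v) for wid, v in rates.items()},
        clock=(clock[0], clock[-1]),
    )
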