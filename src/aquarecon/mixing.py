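"""Materials mass-balance mixing at the water treatment plant.

All supply wells discharge to a common WTP where their water mixes; by
continuity and conservation of mass the treated-water concentration in
month *m* is the pumping-weighted mean over the wells that pumped:

    C_wtp(m) = sum_i Q_i(m) C_i(m) / sum_i Q_i(m)

No treatment removal is applied — the mixed concentration is taken to
represent drinking water anywhere in the WTP's service area.  Months
with no pumping have no defined mixture and are flagged missing.

Exceedance classification finds maximal runs of consecutive months whose
concentration strictly exceeds the contaminant's MCL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeline import MonthIndex, MonthlySeries
from .wells import PumpingSchedule

__all__ = ["WTPSeries", "ExceedancePeriod", "mix_at_wtp", "find_exceedances", "DataAlignmentError"]


class DataAlignmentError(ValueError):
    """A pumping month lacks a well concentration."""


@dataclass
class WTPSeries:
    """Treated-water concentration series with per-month well provenance.

    ``provenance`` maps each month's position to the contributing wells'
    share of delivered water (weights sum to 1).
    """

    series: MonthlySeries
    provenance: dict[int, dict[str, float]]


@dataclass(frozen=True)
class ExceedancePeriod:
    """A maximal run of consecutive months strictly above the MCL."""

    start: MonthIndex
    end: MonthIndex
    mcl: float

    @property
    def n_months(self) -> int:
        return self.end - self.start + 1


def mix_at_wtp(schedule: PumpingSchedule, well_conc: dict[str, MonthlySeries]) -> WTPSeries:
    """Flow-weighted mixing of well concentrations into the WTP series.

    ``well_conc`` maps well id to its monthly flow-weighted concentration
    series (missing in months the well did not pump).  Raises
    :class:`DataAlignmentError` if a well pumps in a month for which its
    concentration is missing.
    """
    months = next(iter(schedule.rates.values())).months()
    values = np.full(len(months), np.nan)
    provenance: dict[int, dict[str, float]] = {}
    for i, month in enumerate(months):
        rates = schedule.rates_for(month)
        total = sum(q for q in rates.values() if q > 0)
        if total <= 0:
            continue
        mass = 0.0
        shares: dict[str, float] = {}
        for wid, q in rates.items():
            if q <= 0:
                continue
            series = well_conc.get(wid)
            if series is None or month < series.start or month > series.end or series.is_missing(month):
                raise DataAlignmentError(f"well {wid} pumps in {month} but has no concentration")
            mass += q * series.value_at(month)
            shares[wid] = q / total
        values[i] = mass / total
        provenance[i] = shares
    return WTPSeries(series=MonthlySeries(months[0], values), provenance=provenance)


def find_exceedances(series: MonthlySeries, mcl: float) -> list[ExceedancePeriod]:
    """Maximal runs of consecutive months with value strictly above *mcl*.

    Missing months break runs; a value exactly equal to the MCL is not an
    exceedance.
    """
    if mcl <= 0:
        raise ValueError("mcl must be > 0")
    periods: list[ExceedancePeriod] = []
    run_start: int | None = None
    vals = series.values
    for i in range(len(vals) + 1):
        above = i < len(vals) and not np.isnan(vals[i]) and vals[i] > mcl
        if above and run_start is None:
            run_start = i
        elif not above and run_start is not None:
            periods.append(
                ExceedancePeriod(series.start.plus(run_start), series.start.plus(i - 1), mcl)
            )
            run_start = None
    return periods
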