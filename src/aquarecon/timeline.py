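"""Monthly clock used by every pipeline stage.

All concentration and pumping series in the package are monthly.  A value
stored at a :class:`MonthIndex` represents the state on the *last day* of
that calendar month; this is the convention used throughout for
"monthly mean" concentrations, and it is what downstream consumers
(mixing, exceedance classification, exposure tables) assume.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = ["MonthIndex", "MonthlySeries", "month_range"]


@dataclass(frozen=True, order=True)
class MonthIndex:
    """A calendar month, totally ordered by (year, month)."""

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")

    @property
    def ordinal(self) -> int:
        """Months since year 0; differences of ordinals are month counts."""
        return self.year * 12 + (self.month - 1)

    @classmethod
    def from_ordinal(cls, ordinal: int) -> "MonthIndex":
        return cls(ordinal // 12, ordinal % 12 + 1)

    @classmethod
    def parse(cls, stamp: str) -> "MonthIndex":
        """Parse an ISO ``YYYY-MM`` stamp."""
        year, month = stamp.split("-")
        return cls(int(year), int(month))

    def __sub__(self, other: "MonthIndex") -> int:
        return self.ordinal - other.ordinal

    def plus(self, months: int) -> "MonthIndex":
        return MonthIndex.from_ordinal(self.ordinal + months)

    @property
    def days(self) -> int:
        """Number of days in this calendar month."""
        return calendar.monthrange(self.year, self.month)[1]

    @property
    def hours(self) -> int:
        return self.days * 24

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


def month_range(start: MonthIndex, end: MonthIndex) -> list[MonthIndex]:
    """Inclusive contiguous list of months from *start* to *end*.

    Raises ``ValueError`` if ``start > end``.
    """
    if start > end:
        raise ValueError(f"month_range start {start} is after end {end}")
    return [start.plus(i) for i in range(end - start + 1)]


@dataclass
class MonthlySeries:
    """A contiguous monthly series of non-negative values with explicit gaps.

    Missing months are NaN, never zero: a month in which a well pumped no
    water has *no* concentration, which is not the same as clean water.

    Parameters
    ----------
    start
        Month of the first value.
    values
        One value per month; NaN marks missing.
    """

    start: MonthIndex
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("MonthlySeries needs a 1-D array of length >= 1")
        finite = self.values[~np.isnan(self.values)]
        if np.any(finite < 0):
            raise ValueError("MonthlySeries values must be >= 0 or NaN")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end(self) -> MonthIndex:
        return self.start.plus(len(self.values) - 1)

    def months(self) -> list[MonthIndex]:
        return month_range(self.start, self.end)

    def index_of(self, when: MonthIndex) -> int:
        i = when - self.start
        if not 0 <= i < len(self.values):
            raise KeyError(f"{when} outside series [{self.start}, {self.end}]")
        return i

    def value_at(self, when: MonthIndex) -> float:
        return float(self.values[self.index_of(when)])

    def is_missing(self, when: MonthIndex) -> bool:
        return bool(np.isnan(self.values[self.index_of(when)]))

    def items(self) -> Iterator[tuple[MonthIndex, float]]:
        for i, v in enumerate(self.values):
            yield self.start.plus(i), float(v)

    @classmethod
    def constant(cls, start: MonthIndex, end: MonthIndex, value: float) -> "MonthlySeries":
        return cls(start, np.full(end - start + 1, float(value)))

    @classmethod
    def from_items(cls, items: Iterable[tuple[MonthIndex, float]]) -> "MonthlySeries":
        pairs = sorted(items, key=lambda p: p[0])
        if not pairs:
            raise ValueError("no items")
        start, end = pairs[0][0], pairs[-1][0]
        values = np.full(end - start + 1, np.nan)
        for when, v in pairs:
            values[when - start] = v
        return cls(start, values)
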