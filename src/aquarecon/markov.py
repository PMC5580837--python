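"""Two-state Markov model of intermittent system interconnections.

Two water-distribution systems can exchange water through a booster
pump or bypass valve.  Whether a transfer happened in a given month is
only partially documented, and transfers cluster in the dry season
(April–August here by default).  The model is a two-state (transfer /
no-transfer) Markov chain at monthly resolution:

* :func:`fit_chain` estimates the transition probabilities by maximum
  likelihood from documented consecutive-month pairs within a season;
* :func:`simulate_events` imputes the undocumented months by exact
  bridge sampling — each unknown month is drawn conditional on its last
  known predecessor *and* the next documented month in the same season,
  so records on both sides of a gap inform it;
* :func:`blend_monthly` converts event probabilities and per-event
  transfer hours into a monthly mean concentration series.

Seasons are independent chains: the dry-season conditions that drive
transfers reset annually, so no memory crosses from one season to the
next.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeline import MonthIndex, MonthlySeries

__all__ = [
    "InterconnectionRecord",
    "TwoStateChain",
    "EventSummary",
    "fit_chain",
    "simulate_events",
    "blend_monthly",
    "InsufficientDataError",
]

DOCUMENTED_ON = "documented_on"
DOCUMENTED_OFF = "documented_off"
UNKNOWN = "unknown"


class InsufficientDataError(ValueError):
    """A transition row has no documented pairs to estimate from."""


@dataclass(frozen=True)
class InterconnectionRecord:
    """Documentation status of one month: on, off, or unknown.

    ``transfer_hours`` is required exactly when the month is
    ``documented_on`` and is bounded by the hours in that month.
    """

    month: MonthIndex
    status: str
    transfer_hours: float | None = None

    def __post_init__(self) -> None:
        if self.status not in (DOCUMENTED_ON, DOCUMENTED_OFF, UNKNOWN):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == DOCUMENTED_ON:
            if self.transfer_hours is None:
                raise ValueError(f"{self.month}: documented_on needs transfer_hours")
            if not 0 <= self.transfer_hours <= self.month.hours:
                raise ValueError(
                    f"{self.month}: transfer_hours {self.transfer_hours} outside [0, {self.month.hours}]"
                )
        elif self.transfer_hours is not None:
            raise ValueError(f"{self.month}: transfer_hours only allowed when documented_on")


@dataclass(frozen=True)
class TwoStateChain:
    """Monthly transfer chain: stay probabilities and initial on-probability."""

    p_stay_on: float
    p_stay_off: float
    initial_p_on: float

    def __post_init__(self) -> None:
        for name in ("p_stay_on", "p_stay_off", "initial_p_on"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    @property
    def matrix(self) -> np.ndarray:
        """Transition matrix, state order (off, on)."""
        return np.array(
            [[self.p_stay_off, 1 - self.p_stay_off], [1 - self.p_stay_on, self.p_stay_on]]
        )


@dataclass
class EventSummary:
    """Across-draw monthly transfer probabilities plus the retained draws."""

    months: list[MonthIndex]
    probability_on: np.ndarray  # per month, in [0,1]
    draws: np.ndarray  # (n_sims, n_months) bool
    records: dict[MonthIndex, InterconnectionRecord]
    seed: int

    def expected_on_months(self) -> dict[int, float]:
        """Expected number of transfer months per year."""
        out: dict[int, float] = {}
        for m, p in zip(self.months, self.probability_on):
            out[m.year] = out.get(m.year, 0.0) + float(p)
        return out


def _season_runs(months: list[MonthIndex]) -> list[list[int]]:
    """Indices of maximal runs of consecutive months in the same year."""
    runs: list[list[int]] = []
    for i, m in enumerate(months):
        if runs and months[runs[-1][-1]].plus(1) == m and months[runs[-1][-1]].year == m.year:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


def fit_chain(records: list[InterconnectionRecord], pseudocount: float = 0.0) -> TwoStateChain:
    """Maximum-likelihood transition probabilities from documented pairs.

    Only consecutive-month pairs that are both documented and lie within
    the same seasonal run count; pairs spanning unknown months or season
    gaps carry no transition information and are excluded.  A transition
    row with zero pairs raises :class:`InsufficientDataError` unless a
    ``pseudocount`` > 0 regularizes it.
    """
    by_month = {r.month: r for r in records}
    months = sorted(by_month)
    documented = [m for m in months if by_month[m].status != UNKNOWN]
    if not documented:
        raise InsufficientDataError("no documented months at all")
    n = {("on", "on"): 0, ("on", "off"): 0, ("off", "on"): 0, ("off", "off"): 0}
    for run in _season_runs(months):
        for a, b in zip(run, run[1:]):
            ra, rb = by_month[months[a]], by_month[months[b]]
            if ra.status == UNKNOWN or rb.status == UNKNOWN:
                continue
            sa = "on" if ra.status == DOCUMENTED_ON else "off"
            sb = "on" if rb.status == DOCUMENTED_ON else "off"
            n[(sa, sb)] += 1
    rows = {}
    for state in ("on", "off"):
        total = n[(state, "on")] + n[(state, "off")] + 2 * pseudocount
        if total == 0:
            raise InsufficientDataError(
                f"no documented consecutive pairs leaving state {state!r}; "
                "supply more records or a pseudocount > 0"
            )
        rows[state] = (n[(state, state)] + pseudocount) / total
    on_frac = sum(1 for m in documented if by_month[m].status == DOCUMENTED_ON) / len(documented)
    return TwoStateChain(p_stay_on=rows["on"], p_stay_off=rows["off"], initial_p_on=on_frac)


def _sample_season(
    chain: TwoStateChain,
    statuses: list[int],  # -1 unknown, 0 off, 1 on
    rng: np.random.Generator,
    powers: list[np.ndarray],
) -> np.ndarray:
    """One exact draw of a season conditioned on its documented months.

    Forward sampling with the right-hand documented neighbor folded in:
    P(s_t | s_{t-1}, next documented state b at lag d) ∝
    P(s_t | s_{t-1}) · P^{d-1}[s_t, b].
    """
    T = len(statuses)
    P = chain.matrix
    # next documented constraint for each position
    next_doc = [None] * T
    last: tuple[int, int] | None = None
    for t in range(T - 1, -1, -1):
        next_doc[t] = last
        if statuses[t] >= 0:
            last = (t, statuses[t])
    out = np.empty(T, dtype=np.int64)
    prev = None
    for t in range(T):
        if statuses[t] >= 0:
            out[t] = statuses[t]
            prev = out[t]
            continue
        if prev is None:
            p1 = np.array([1 - chain.initial_p_on, chain.initial_p_on])
        else:
            p1 = P[prev]
        if next_doc[t] is not None:
            tb, b = next_doc[t]
            lik = powers[tb - t][:, b]  # P(documented state b at lag tb-t | s_t)
            p1 = p1 * lik
        total = p1.sum()
        if total == 0:
            # documented constraint unreachable (degenerate chain); fall back
            p1 = P[prev] if prev is not None else np.array([0.5, 0.5])
            total = p1.sum()
        out[t] = 1 if rng.random() < p1[1] / total else 0
        prev = out[t]
    return out


def simulate_events(
    chain: TwoStateChain,
    years: range,
    months_active: list[int],
    records: list[InterconnectionRecord],
    n_sims: int = 1000,
    seed: int = 0,
) -> EventSummary:
    """Impute undocumented months by conditional simulation of the chain.

    Documented months are fixed in every draw; unknown months are bridge
    sampled within their season.  Probabilities are across-draw means.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not len(years) or not months_active:
        raise ValueError("years and months_active must be non-empty")
    months = [MonthIndex(y, m) for y in years for m in sorted(months_active)]
    by_month = {r.month: r for r in records}
    status_code = []
    for m in months:
        r = by_month.get(m)
        if r is None or r.status == UNKNOWN:
            status_code.append(-1)
        else:
            status_code.append(1 if r.status == DOCUMENTED_ON else 0)
    runs = _season_runs(months)
    max_len = max(len(r) for r in runs)
    powers = [np.linalg.matrix_power(chain.matrix, k) for k in range(max_len + 1)]
    rng = np.random.default_rng(seed)
    draws = np.empty((n_sims, len(months)), dtype=bool)
    for s in range(n_sims):
        for run in runs:
            st = [status_code[i] for i in run]
            draws[s, run[0] : run[-1] + 1] = _sample_season(chain, st, rng, powers).astype(bool)
    return EventSummary(
        months=months,
        probability_on=draws.mean(axis=0),
        draws=draws,
        records=by_month,
        seed=seed,
    )


def blend_monthly(
    event: EventSummary,
    on_conc,
    off_conc,
    event_hours: float,
) -> MonthlySeries:
    """Monthly mean concentration implied by intermittent transfer events.

    In an on-month a transfer runs for *h* hours at concentration
    ``on_conc`` and the rest of the month sits at ``off_conc``; the
    monthly mean is the hour-weighted average, then averaged across
    simulation draws.  Documented transfer hours override the default
    ``event_hours``.  ``on_conc``/``off_conc`` are scalars or
    :class:`~aquarecon.timeline.MonthlySeries`.  Months between the
    event months (and any month the chain never connects) sit at
    ``off_conc``, giving a contiguous series.
    """

    def level(source, m: MonthIndex) -> float:
        if isinstance(source, MonthlySeries):
            return source.value_at(m)
        return float(source)

    first, last = event.months[0], event.months[-1]
    n = last - first + 1
    values = np.empty(n)
    for i in range(n):
        values[i] = level(off_conc, first.plus(i))
    for j, m in enumerate(event.months):
        H = m.hours
        rec = event.records.get(m)
        h = rec.transfer_hours if rec is not None and rec.status == DOCUMENTED_ON else event_hours
        if h > H:
            raise ValueError(f"{m}: event hours {h} exceed hours in month {H}")
        on_mean = (h * level(on_conc, m) + (H - h) * level(off_conc, m)) / H
        p = event.probability_on[j]
        values[m - first] = p * on_mean + (1 - p) * level(off_conc, m)
    return MonthlySeries(first, values)
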