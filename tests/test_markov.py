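"""Two-state interconnection chain: fitting, bridge sampling, blending."""

import itertools

import numpy as np
import pytest

from aquarecon.markov import (
    DOCUMENTED_OFF,
    DOCUMENTED_ON,
    UNKNOWN,
    InsufficientDataError,
    InterconnectionRecord,
    TwoStateChain,
    blend_monthly,
    fit_chain,
    simulate_events,
)
from aquarecon.synthetic import generate_interconnection_history
from aquarecon.timeline import MonthIndex, MonthlySeries


def rec(year, month, status, hours=None):
    if status == DOCUMENTED_ON and hours is None:
        hours = 48.0
    return InterconnectionRecord(MonthIndex(year, month), status, hours)


def seq_records(year, statuses, start_month=4):
    out = []
    for i, s in enumerate(statuses):
        out.append(rec(year, start_month + i, s))
    return out


class TestRecordValidation:
    def test_hours_required_iff_on(self):
        with pytest.raises(ValueError):
            InterconnectionRecord(MonthIndex(1975, 5), DOCUMENTED_ON, None)
        with pytest.raises(ValueError):
            InterconnectionRecord(MonthIndex(1975, 5), DOCUMENTED_OFF, 10.0)

    def test_hours_bounded_by_month(self):
        with pytest.raises(ValueError):
            InterconnectionRecord(MonthIndex(1975, 2), DOCUMENTED_ON, 700.0)  # Feb has 672 h


class TestFitChain:
    def test_all_on_gives_degenerate_stay_on(self):
        records = seq_records(1975, [DOCUMENTED_ON] * 5)
        with pytest.raises(InsufficientDataError):
            fit_chain(records)  # off row has no pairs
        chain = fit_chain(records, pseudocount=1e-12)
        assert chain.p_stay_on == pytest.approx(1.0)
        assert chain.initial_p_on == 1.0

    def test_pair_counting_example(self):
        """On,On,Off,On,Off,Off: p_stay_on = 1/3, p_stay_off = 1/2."""
        statuses = [
            DOCUMENTED_ON, DOCUMENTED_ON, DOCUMENTED_OFF,
            DOCUMENTED_ON, DOCUMENTED_OFF, DOCUMENTED_OFF,
        ]
        chain = fit_chain(seq_records(1975, statuses, start_month=3))
        assert chain.p_stay_on == pytest.approx(1 / 3)
        assert chain.p_stay_off == pytest.approx(1 / 2)
        assert chain.initial_p_on == pytest.approx(3 / 6)

    def test_matches_brute_force_pair_count_across_seasons(self):
        """Hand-counted pairs over two seasons, with unknowns excluded."""
        records = (
            seq_records(1975, [DOCUMENTED_ON, UNKNOWN, DOCUMENTED_ON, DOCUMENTED_OFF, DOCUMENTED_OFF])
            + seq_records(1976, [DOCUMENTED_OFF, DOCUMENTED_ON, DOCUMENTED_ON, DOCUMENTED_OFF, DOCUMENTED_OFF])
        )
        # usable pairs: 75: (on,off)@7-8? months 4..8: ON,?,ON,OFF,OFF ->
        #   (6,7)=on->off, (7,8)=off->off; 76: off->on, on->on, on->off, off->off
        chain = fit_chain(records)
        assert chain.p_stay_on == pytest.approx(1 / 3)  # on->on 1 of 3
        assert chain.p_stay_off == pytest.approx(2 / 3)  # off->off 2 of 3

    def test_pairs_never_span_season_gaps(self):
        records = seq_records(1975, [DOCUMENTED_ON] * 2) + seq_records(1976, [DOCUMENTED_OFF] * 2)
        chain = fit_chain(records, pseudocount=0.0)
        # only within-season pairs: on->on and off->off, one each
        assert chain.p_stay_on == 1.0
        assert chain.p_stay_off == 1.0

    def test_masked_refit_recovers_parameters(self):
        """50 % masking of a long synthetic record: estimates within ±0.05."""
        hist = generate_interconnection_history(
            range(1000, 2000), [4, 5, 6, 7, 8], p_on=0.45, persistence=0.6,
            frac_documented=0.5, seed=13,
        )
        assert len(hist.records) == 5000
        truth_chain = fit_chain(hist.truth)  # empirical truth transitions
        fitted = fit_chain(hist.records)
        p_on_on = 0.6 + 0.4 * 0.45  # generating values
        p_off_off = 1 - 0.4 * 0.45
        assert abs(fitted.p_stay_on - p_on_on) < 0.05
        assert abs(fitted.p_stay_off - p_off_off) < 0.05
        assert abs(truth_chain.p_stay_on - p_on_on) < 0.05


class TestSimulateEvents:
    def test_fully_documented_is_deterministic(self):
        records = seq_records(1975, [DOCUMENTED_ON, DOCUMENTED_OFF, DOCUMENTED_ON, DOCUMENTED_OFF, DOCUMENTED_ON])
        chain = TwoStateChain(0.5, 0.5, 0.5)
        ev = simulate_events(chain, range(1975, 1976), [4, 5, 6, 7, 8], records, n_sims=7, seed=0)
        assert list(ev.probability_on) == [1.0, 0.0, 1.0, 0.0, 1.0]

    def test_fair_coin_probabilities(self):
        """p_stay = 0.5 both rows is i.i.d.; monthly p within ±0.03 of 0.5."""
        chain = TwoStateChain(0.5, 0.5, 0.5)
        ev = simulate_events(chain, range(1970, 1972), [4, 5, 6, 7, 8], [], n_sims=10_000, seed=2)
        assert np.all(np.abs(ev.probability_on - 0.5) < 0.03)

    def test_bridge_between_two_on_months(self):
        """Unknown month flanked by documented-on months, p_stay_on = 0.9."""
        records = [
            rec(1975, 4, DOCUMENTED_ON),
            rec(1975, 5, UNKNOWN),
            rec(1975, 6, DOCUMENTED_ON),
        ]
        chain = TwoStateChain(p_stay_on=0.9, p_stay_off=0.5, initial_p_on=0.5)
        ev = simulate_events(chain, range(1975, 1976), [4, 5, 6], records, n_sims=4000, seed=3)
        assert ev.probability_on[1] > 0.8

    @pytest.mark.parametrize("pattern", [
        (1, -1, 0), (-1, -1, 1), (0, -1, -1), (-1, -1, -1), (1, -1, -1), (-1, 1, -1),
    ])
    def test_bridge_matches_path_enumeration(self, pattern):
        """Conditional probabilities agree with exact enumeration of all
        state paths for seasons with up to 3 unknown months."""
        chain = TwoStateChain(p_stay_on=0.8, p_stay_off=0.65, initial_p_on=0.4)
        records = []
        for i, s in enumerate(pattern):
            if s == 1:
                records.append(rec(1975, 4 + i, DOCUMENTED_ON))
            elif s == 0:
                records.append(rec(1975, 4 + i, DOCUMENTED_OFF))
        ev = simulate_events(chain, range(1975, 1976), [4, 5, 6], records, n_sims=60_000, seed=5)

        # oracle: enumerate all 2^3 paths, weight by chain probability,
        # zero out paths violating the documented months
        P = chain.matrix
        pi = np.array([1 - chain.initial_p_on, chain.initial_p_on])
        post = np.zeros(3)
        norm = 0.0
        for path in itertools.product((0, 1), repeat=3):
            if any(doc >= 0 and path[i] != doc for i, doc in enumerate(pattern)):
                continue
            w = pi[path[0]] * P[path[0], path[1]] * P[path[1], path[2]]
            norm += w
            for i in range(3):
                post[i] += w * path[i]
        post /= norm
        assert np.max(np.abs(ev.probability_on - post)) < 0.012

    def test_monotone_in_stay_on(self):
        """Raising p_stay_on never lowers an unknown month's probability
        (common random numbers via a shared seed)."""
        records = [rec(1975, 4, DOCUMENTED_ON), rec(1975, 5, UNKNOWN), rec(1975, 6, UNKNOWN)]
        probs = []
        for p in (0.3, 0.6, 0.9):
            chain = TwoStateChain(p, 0.5, 0.5)
            ev = simulate_events(chain, range(1975, 1976), [4, 5, 6], records, n_sims=20_000, seed=9)
            probs.append(ev.probability_on[1:].copy())
        assert np.all(probs[1] >= probs[0] - 0.01)
        assert np.all(probs[2] >= probs[1] - 0.01)

    def test_seed_determinism(self):
        chain = TwoStateChain(0.7, 0.6, 0.4)
        records = [rec(1975, 4, DOCUMENTED_ON)]
        a = simulate_events(chain, range(1975, 1977), [4, 5, 6], records, n_sims=200, seed=4)
        b = simulate_events(chain, range(1975, 1977), [4, 5, 6], records, n_sims=200, seed=4)
        assert np.array_equal(a.draws, b.draws)

    def test_expected_on_months_sums_probabilities(self):
        chain = TwoStateChain(0.5, 0.5, 0.5)
        ev = simulate_events(chain, range(1975, 1977), [4, 5, 6], [], n_sims=500, seed=1)
        per_year = ev.expected_on_months()
        assert per_year[1975] == pytest.approx(float(ev.probability_on[:3].sum()))


class TestBlendMonthly:
    def _events(self, probs, records=None, year=1975):
        from aquarecon.markov import EventSummary

        months = [MonthIndex(year, 4 + i) for i in range(len(probs))]
        return EventSummary(
            months=months,
            probability_on=np.asarray(probs, dtype=float),
            draws=np.tile(np.asarray(probs) >= 1.0, (4, 1)),
            records={r.month: r for r in (records or [])},
            seed=0,
        )

    def test_never_connected_is_background(self):
        ev = self._events([0.0, 0.0, 0.0])
        s = blend_monthly(ev, on_conc=60.0, off_conc=1.5, event_hours=100.0)
        assert np.allclose(s.values, 1.5)

    def test_fully_connected_month_is_on_concentration(self):
        m = MonthIndex(1975, 4)
        ev = self._events([1.0], records=[InterconnectionRecord(m, DOCUMENTED_ON, float(m.hours))])
        s = blend_monthly(ev, on_conc=60.0, off_conc=0.0, event_hours=10.0)
        assert s.value_at(m) == pytest.approx(60.0)

    def test_half_probability_half_month(self):
        """p = 0.5, h = H/2, on 60, off 0 -> expected 15."""
        m = MonthIndex(1975, 4)
        ev = self._events([0.5])
        s = blend_monthly(ev, on_conc=60.0, off_conc=0.0, event_hours=m.hours / 2)
        assert s.value_at(m) == pytest.approx(15.0)

    def test_documented_hours_override_default(self):
        m = MonthIndex(1975, 4)
        ev = self._events([1.0], records=[InterconnectionRecord(m, DOCUMENTED_ON, m.hours / 4)])
        s = blend_monthly(ev, on_conc=80.0, off_conc=0.0, event_hours=m.hours)
        assert s.value_at(m) == pytest.approx(20.0)

    def test_excess_hours_rejected(self):
        ev = self._events([1.0])
        with pytest.raises(ValueError, match="hours"):
            blend_monthly(ev, on_conc=10.0, off_conc=0.0, event_hours=1e5)


class TestHistoryGenerator:
    def test_full_documentation_has_no_unknowns(self):
        hist = generate_interconnection_history(range(1972, 1976), [4, 5, 6, 7, 8], frac_documented=1.0, seed=1)
        assert all(r.status != UNKNOWN for r in hist.records)

    def test_p_on_zero_is_all_off(self):
        hist = generate_interconnection_history(range(1972, 1986), [4, 5, 6, 7, 8], p_on=0.0, seed=2)
        assert all(r.status == DOCUMENTED_OFF for r in hist.truth)

    def test_fair_chain_on_fraction(self):
        """persistence 0.5, p_on 0.5, 10 000 months: on-fraction within ±0.02."""
        hist = generate_interconnection_history(
            range(0, 2000), [4, 5, 6, 7, 8], p_on=0.5, persistence=0.5, seed=3
        )
        assert abs(hist.truth_on_fraction() - 0.5) < 0.02

    def test_masking_preserves_truth(self):
        hist = generate_interconnection_history(range(1972, 1980), [4, 5, 6, 7, 8], frac_documented=0.3, seed=4)
        for masked, true in zip(hist.records, hist.truth):
            assert masked.month == true.month
            if masked.status != UNKNOWN:
                assert masked.status == true.status
                assert masked.transfer_hours == true.transfer_hours

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_interconnection_history(range(0), [4], seed=0)
        with pytest.raises(ValueError):
            generate_interconnection_history(range(1972, 1975), [], seed=0)
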