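"""Groundwater-flow solver against closed forms and conservation laws."""

import numpy as np
import pytest
from scipy.special import exp1

from aquarecon.flow import (
    BoundaryConditionError,
    cell_flows,
    compute_residuals,
    flow_fields_for_schedule,
    solve_steady_flow,
    solve_transient_flow,
)
from aquarecon.model import GridSpec, LayerProperties, SiteModel, WellRecord
from aquarecon.synthetic import ObservationSet
from aquarecon.timeline import MonthIndex, MonthlySeries
from aquarecon.wells import PumpingSchedule

from conftest import box_site, strip_site


class TestSteady:
    def test_laplace_strip_is_linear(self):
        site = strip_site(ncol=30, head_left=10.0, head_right=0.0)
        hf = solve_steady_flow(site)
        h = hf.heads[0, 0, 0]
        expect = np.linspace(10.0, 0.0, 30)
        assert np.max(np.abs(h - expect)) < 1e-8

    def test_recharge_parabola_matches_closed_form(self):
        # confined 1-D with recharge W: T h'' + W = 0 between fixed heads
        kh, b, dx, n, W = 10.0, 10.0, 10.0, 81, 1e-3
        site = strip_site(ncol=n, dx=dx, kh=kh, thickness=b, head_left=5.0, head_right=5.0, recharge=W)
        hf = solve_steady_flow(site)
        h = hf.heads[0, 0, 0]
        T = kh * b
        L = (n - 1) * dx
        x = np.arange(n) * dx
        expect = 5.0 + W * x * (L - x) / (2 * T)
        assert np.max(np.abs(h - expect)) / (expect.max() - 5.0) < 0.01

    def test_budget_closes(self):
        site = strip_site(ncol=30, recharge=5e-4)
        hf = solve_steady_flow(site)
        assert hf.budgets[0]["discrepancy"] < 0.005

    def test_maximum_principle(self):
        # no recharge, no wells: interior heads bounded by boundary heads
        site = strip_site(ncol=25, nrow=5, head_left=7.0, head_right=2.0)
        hf = solve_steady_flow(site)
        assert hf.heads.min() >= 2.0 - 1e-9
        assert hf.heads.max() <= 7.0 + 1e-9

    def test_no_boundary_is_singular(self):
        with pytest.raises((BoundaryConditionError, ValueError)):
            site = strip_site(ncol=10)
            object.__setattr__(site, "constant_head_cells", ())
            solve_steady_flow(site)

    def test_grid_refinement_second_order(self):
        """Halving dx cuts the sinusoidal-recharge error by >= 3x.

        T h'' + W0 sin(pi x / L) = 0 with h(0)=h(L)=h0 has the closed form
        h = h0 + W0 L^2 / (T pi^2) sin(pi x / L); unlike a parabola it is
        not reproduced exactly by the 5-point stencil, so the error decays
        at the scheme's true order.
        """
        L, T, W0, h0 = 400.0, 100.0, 1e-3, 5.0
        errs = []
        for n in (21, 41):
            dx = L / (n - 1)
            x = np.arange(n) * dx
            site = strip_site(
                ncol=n, dx=dx, kh=10.0, thickness=10.0, head_left=h0, head_right=h0,
                recharge=0.0,
            )
            site.recharge[:] = W0 * np.sin(np.pi * x / L)
            h = solve_steady_flow(site).heads[0, 0, 0]
            expect = h0 + W0 * L**2 / (T * np.pi**2) * np.sin(np.pi * x / L)
            errs.append(np.max(np.abs(h - expect)))
        assert errs[0] / max(errs[1], 1e-300) >= 3.0


def constant_schedule(site, rates: dict[str, float]) -> PumpingSchedule:
    months = site.n_months
    return PumpingSchedule(
        {wid: MonthlySeries(site.clock_start, np.full(months, q)) for wid, q in rates.items()},
        clock=(site.clock_start, site.clock_end),
    )


class TestTransient:
    def test_zero_schedule_stays_steady(self):
        site = strip_site(ncol=20, months=12)
        steady = solve_steady_flow(site)
        hf = solve_transient_flow(site, constant_schedule(site, {}), steady, substeps_per_month=2)
        assert np.max(np.abs(hf.heads - steady.heads[0])) < 1e-8

    def test_theis_drawdown(self):
        """Single constant-rate well in a confined layer: Theis within 5 %.

        The domain is large enough that the month-1 radius of influence
        (~sqrt(2.25 T t / S) ≈ 840 m) stays well inside the constant-head
        rim at 2000 m, so the boundary's image effect is negligible.
        """
        n, dx = 81, 50.0
        kh, b, ss = 5.0, 10.0, 5e-3  # T = 50 m²/day, S = 0.005
        Q = 500.0
        well = WellRecord(
            id="PW",
            row=n // 2,
            col=n // 2,
            screened_layers=(0,),
            capacity=Q,
            service_intervals=((MonthIndex(1970, 1), MonthIndex(1970, 12)),),
        )
        site = box_site(n=n, dx=dx, kh=kh, thickness=b, specific_storage=ss / b, boundary_head=50.0, wells=(well,))
        steady = solve_steady_flow(site)
        hf = solve_transient_flow(
            site, constant_schedule(site, {"PW": Q}), steady, substeps_per_month=31
        )
        t = 31.0  # days, end of January
        T, S = kh * b, ss
        h0 = steady.heads[0, 0]
        sim = h0 - hf.heads[0, 0]
        errs = []
        for r_cells in (2, 4, 6, 10):
            s_sim = sim[n // 2, n // 2 + r_cells]
            r = r_cells * dx
            u = r * r * S / (4 * T * t)
            s_theis = Q / (4 * np.pi * T) * exp1(u)
            errs.append(abs(s_sim - s_theis) / s_theis)
        assert max(errs) < 0.05, errs

    def test_substep_refinement_converges(self):
        site = strip_site(ncol=20, months=12, recharge=5e-4)
        steady = solve_steady_flow(site)
        h2 = solve_transient_flow(site, constant_schedule(site, {}), steady, 2).heads[-1]
        h4 = solve_transient_flow(site, constant_schedule(site, {}), steady, 4).heads[-1]
        denom = max(np.abs(h2).max(), 1e-12)
        assert np.max(np.abs(h2 - h4)) / denom < 1e-3

    def test_transient_budget_includes_storage(self, industrial_truth):
        assert industrial_truth.result.heads.max_budget_discrepancy() < 0.005

    def test_missing_schedule_month_rejected(self):
        site = strip_site(ncol=10, months=12)
        steady = solve_steady_flow(site)
        short = PumpingSchedule(
            {"X": MonthlySeries(site.clock_start, np.zeros(6))}
        )
        with pytest.raises(ValueError, match="cover"):
            solve_transient_flow(site, short, steady)


class TestCellFlows:
    def test_uniform_strip_flow_and_divergence(self):
        site = strip_site(ncol=30, nrow=4, head_left=10.0, head_right=0.0)
        hf = solve_steady_flow(site)
        ff = cell_flows(site, hf.heads[0])
        inner = ff.right[0, :, 1:-2]
        assert np.allclose(inner, inner[0, 0], rtol=1e-9)
        div = ff.divergence()
        assert np.max(np.abs(div[:, :, 1:-1])) < 1e-7

    def test_pumping_cell_divergence_equals_rate(self):
        n = 15
        well = WellRecord(
            id="W",
            row=n // 2,
            col=n // 2,
            screened_layers=(0,),
            capacity=300.0,
            service_intervals=((MonthIndex(1970, 1), MonthIndex(1970, 12)),),
        )
        site = box_site(n=n, wells=(well,))
        steady = solve_steady_flow(site)
        sched = constant_schedule(site, {"W": 300.0})
        hf = solve_transient_flow(site, sched, steady, substeps_per_month=4)
        ffs = flow_fields_for_schedule(site, hf, sched, steady)
        ff = ffs[-1]
        # continuity: with the well term included, divergence vanishes there
        div = ff.divergence()
        assert abs(div[0, n // 2, n // 2]) < 0.005 * 300.0
        assert ff.well[0, n // 2, n // 2] == pytest.approx(300.0)

    def test_closed_box_no_sources_has_no_flow(self):
        site = box_site(n=9, boundary_head=20.0)
        hf = solve_steady_flow(site)
        ff = cell_flows(site, hf.heads[0])
        assert np.max(np.abs(ff.right)) < 1e-10
        assert np.max(np.abs(ff.front)) < 1e-10


class TestResiduals:
    def _obs_from_field(self, site, hf, noise, n, rng):
        months = site.clock
        obs = []
        for _ in range(n):
            r = int(rng.integers(0, site.grid.nrow))
            c = int(rng.integers(0, site.grid.ncol))
            mi = int(rng.integers(0, len(months)))
            val = hf.heads[mi, 0, r, c] + (rng.normal(0, noise) if noise else 0.0)
            obs.append((0, r, c, months[mi], val))
        return ObservationSet(head_obs=obs, conc_obs=[], noise_sd={"head": noise, "conc": 0.0})

    def test_perfect_fit_all_within(self):
        site = strip_site(ncol=20, months=12)
        steady = solve_steady_flow(site)
        hf = solve_transient_flow(site, constant_schedule(site, {}), steady, 2)
        obs = self._obs_from_field(site, hf, 0.0, 40, np.random.default_rng(0))
        rep = compute_residuals(obs, hf, band=1.5)
        assert rep.fraction_within == 1.0
        assert all(r == 0.0 for *_, r in rep.residuals)

    def test_noisy_fraction_matches_normal_tail(self):
        """SD 0.5 m noise vs a 1.5 m band: ~Φ(3)−Φ(−3) ≈ 0.9973 of residuals inside."""
        site = strip_site(ncol=20, months=12)
        steady = solve_steady_flow(site)
        hf = solve_transient_flow(site, constant_schedule(site, {}), steady, 2)
        obs = self._obs_from_field(site, hf, 0.5, 200, np.random.default_rng(1))
        rep = compute_residuals(obs, hf, band=1.5)
        # binomial 99% lower bound at p=0.9973, n=200 is ~0.985
        assert rep.fraction_within >= 0.985

    def test_empty_report_rejected(self):
        site = strip_site(ncol=20)
        hf = solve_steady_flow(site)
        empty = ObservationSet(head_obs=[], conc_obs=[], noise_sd={"head": 0, "conc": 0})
        with pytest.raises(ValueError):
            compute_residuals(empty, hf)
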