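"""Network hydraulics and Lagrangian water quality."""

import numpy as np
import pytest

from aquarecon.network import (
    ConnectivityError,
    EventScenario,
    InpFormatError,
    Junction,
    Pipe,
    PipeNetwork,
    Pump,
    Reservoir,
    Valve,
    area_mean,
    read_inp,
    run_event_scenario,
    simulate_quality,
    solve_hydraulics,
)
from aquarecon.synthetic import two_system_network

HW_EXP = 1.852


def single_pipe_net(demand=500.0, length=1000.0, diameter=0.2, roughness=120.0):
    junctions = {"J1": Junction("J1", elevation=0.0, base_demand=demand, area="town")}
    reservoir = Reservoir("R", head=100.0)
    return PipeNetwork(junctions, reservoir, [Pipe("P1", "R", "J1", length, diameter, roughness)])


class TestHydraulics:
    def test_single_pipe_closed_form(self):
        """Flow equals demand; head loss matches Hazen–Williams by hand."""
        demand = 500.0  # m³/day
        net = single_pipe_net(demand=demand)
        flows, heads = solve_hydraulics(net, hour=0)
        assert flows["P1"] == pytest.approx(demand, rel=1e-6)
        q_si = demand / 86400.0
        hl = 10.667 * 1000.0 / (120.0**HW_EXP * 0.2**4.871) * q_si**HW_EXP
        assert heads["R"] - heads["J1"] == pytest.approx(hl, rel=1e-4)

    def test_symmetric_loop_splits_evenly(self):
        junctions = {
            "A": Junction("A", 0.0, 0.0),
            "B": Junction("B", 0.0, 800.0, area="town"),
        }
        net = PipeNetwork(
            junctions,
            Reservoir("R", 50.0),
            [
                Pipe("feed", "R", "A", 300.0, 0.3),
                Pipe("left", "A", "B", 500.0, 0.2),
                Pipe("right", "A", "B", 500.0, 0.2),
            ],
        )
        flows, _ = solve_hydraulics(net, 0)
        assert flows["left"] == pytest.approx(flows["right"], abs=1e-9 * 800)
        assert flows["left"] + flows["right"] == pytest.approx(800.0, rel=1e-6)

    def test_zero_demand_zero_flow_uniform_heads(self):
        net = single_pipe_net(demand=0.0)
        flows, heads = solve_hydraulics(net, 0)
        assert flows["P1"] == pytest.approx(0.0, abs=1e-9)
        assert heads["J1"] == pytest.approx(100.0)

    def test_closed_valve_disconnects_demand_node(self):
        junctions = {"J1": Junction("J1", 0.0, 100.0)}
        net = PipeNetwork(
            junctions, Reservoir("R", 50.0), [], valves=[Valve("V", "R", "J1", open=False)]
        )
        with pytest.raises(ConnectivityError):
            solve_hydraulics(net, 0)

    def test_relabeling_invariance(self):
        def build(names):
            a, b = names
            junctions = {
                a: Junction(a, 0.0, 300.0, area="x"),
                b: Junction(b, 0.0, 500.0, area="y"),
            }
            return PipeNetwork(
                junctions,
                Reservoir("R", 40.0),
                [Pipe("p1", "R", a, 400.0, 0.25), Pipe("p2", a, b, 600.0, 0.2)],
            )

        f1, h1 = solve_hydraulics(build(("n1", "n2")), 0)
        f2, h2 = solve_hydraulics(build(("zz", "aa")), 0)
        assert f1["p1"] == pytest.approx(f2["p1"], rel=1e-9)
        assert h1["n2"] == pytest.approx(h2["aa"], rel=1e-9)

    def test_pump_adds_head_per_curve(self):
        junctions = {"J1": Junction("J1", 0.0, 2000.0, area="town")}
        pump = Pump("BP", "R", "J1", shutoff_head=30.0, design_flow=3000.0, design_head=15.0)
        net = PipeNetwork(junctions, Reservoir("R", 10.0), [], pumps=[pump])
        flows, heads = solve_hydraulics(net, 0)
        assert flows["BP"] == pytest.approx(2000.0, rel=1e-6)
        gain = pump.shutoff_head - pump.r * 2000.0**2
        assert heads["J1"] - heads["R"] == pytest.approx(gain, rel=1e-6)


class TestQuality:
    def test_plug_flow_delay(self):
        """Outlet is clean before one travel time, at source level after."""
        net = single_pipe_net(demand=500.0, length=1000.0, diameter=0.2)
        hyd = solve_hydraulics(net, 0)
        pipe = net.pipes[0]
        tau_hours = pipe.volume / 500.0 * 24.0  # travel time
        step = 0.25
        res = simulate_quality(net, [hyd] * 200, source_conc=80.0, duration=50.0, step=step)
        for si, t in enumerate(res.times):
            c = res.node_conc[si]["J1"]
            if t < tau_hours - step:
                assert c == 0.0
            if t > tau_hours + step:
                assert c == pytest.approx(80.0, rel=1e-9)

    def test_junction_mixing_of_two_inflows(self):
        """Two parallel paths of different travel times: while only the
        short path has broken through, the junction concentration is the
        flow-weighted mixture computed by hand from the flow split."""
        junctions = {
            "A": Junction("A", 0.0, 0.0),
            "B": Junction("B", 0.0, 600.0, area="town"),
        }
        short = Pipe("short", "A", "B", 200.0, 0.15)
        long = Pipe("long", "A", "B", 2000.0, 0.15)
        net = PipeNetwork(
            junctions, Reservoir("R", 80.0), [Pipe("feed", "R", "A", 10.0, 0.3), short, long]
        )
        hyd = solve_hydraulics(net, 0)
        flows = hyd[0]
        res = simulate_quality(net, [hyd] * 400, source_conc=100.0, duration=40.0, step=0.1)
        tau_short = short.volume / flows["short"] * 24.0
        tau_long = long.volume / flows["long"] * 24.0
        window = [
            si for si, t in enumerate(res.times) if tau_short + 0.3 < t < tau_long - 0.3
        ]
        assert window, "paths must have distinct travel times"
        expect = flows["short"] * 100.0 / (flows["short"] + flows["long"])
        for si in window:
            assert res.node_conc[si]["B"] == pytest.approx(expect, rel=1e-6)

    def test_mass_balance_closes(self):
        net = two_system_network("small", 3).with_valve_states({"bypass": False})
        hyd = [solve_hydraulics(net, h // 4) for h in range(4 * 48)]
        res = simulate_quality(net, hyd, source_conc=50.0, duration=48.0, step=0.25)
        assert res.mass_closure() < 0.005

    def test_concentration_bounded_by_source(self):
        net = two_system_network("small", 1)
        areas = run_event_scenario(net, EventScenario("pump", 48.0, 0.5), 75.0)
        assert all(0.0 <= v <= 75.0 + 1e-9 for v in areas.values())

    def test_step_halving_changes_area_means_little(self):
        net = two_system_network("small", 2)
        a1 = run_event_scenario(net, EventScenario("pump", 24.0, 0.5), 100.0)
        a2 = run_event_scenario(net, EventScenario("pump", 24.0, 0.25), 100.0)
        for area in a1:
            assert a1[area] == pytest.approx(a2[area], rel=0.01)


class TestAreaMean:
    def test_uniform_concentration(self):
        net = single_pipe_net(demand=500.0)
        hyd = solve_hydraulics(net, 0)
        res = simulate_quality(net, [hyd] * 300, source_conc=42.0, duration=60.0, step=0.25)
        assert area_mean(res, net, "town", window=(40.0, 60.0)) == pytest.approx(42.0, rel=1e-6)

    def test_window_before_arrival_is_zero(self):
        net = single_pipe_net(demand=500.0, length=2000.0)
        hyd = solve_hydraulics(net, 0)
        res = simulate_quality(net, [hyd] * 100, source_conc=42.0, duration=10.0, step=0.1)
        assert area_mean(res, net, "town", window=(0.0, 0.5)) == 0.0

    def test_demand_weighting(self):
        from aquarecon.network import EPSResult

        net = PipeNetwork(
            {
                "A": Junction("A", 0.0, 100.0, area="z"),
                "B": Junction("B", 0.0, 300.0, area="z"),
            },
            Reservoir("R", 50.0),
            [Pipe("p1", "R", "A", 100.0, 0.3), Pipe("p2", "R", "B", 100.0, 0.3)],
        )
        res = EPSResult(
            times=np.array([1.0]),
            step=1.0,
            link_flows=[{}],
            node_heads=[{}],
            node_conc=[{"A": 40.0, "B": 0.0}],
            mass_in=0.0,
            mass_delivered=0.0,
            mass_stored=0.0,
        )
        assert area_mean(res, net, "z") == pytest.approx(10.0)

    def test_unknown_area_lists_known(self):
        net = single_pipe_net()
        hyd = solve_hydraulics(net, 0)
        res = simulate_quality(net, [hyd] * 10, 1.0, 1.0, 0.1)
        with pytest.raises(ValueError, match="town"):
            area_mean(res, net, "nowhere")


class TestEventScenarios:
    def test_zero_duration_all_zero(self):
        net = two_system_network("small", 1)
        areas = run_event_scenario(net, EventScenario("pump", 0.0), 100.0)
        assert set(areas.values()) == {0.0}

    def test_long_event_saturates_to_source(self):
        """Event much longer than any travel time: every area's mean
        approaches the source concentration (the start-up ramp is the
        only deficit, and it amortizes away)."""
        net = two_system_network("small", 1)
        areas = run_event_scenario(net, EventScenario("pump", 24.0 * 60, 1.0), 100.0)
        for v in areas.values():
            assert v == pytest.approx(100.0, rel=0.01)

    def test_near_area_at_least_distal_area(self):
        for seed in (0, 1, 5):
            net = two_system_network("small", seed)
            areas = run_event_scenario(net, EventScenario("pump", 24.0, 0.5), 100.0)
            assert areas["near"] >= areas["far"]

    def test_valve_scenario_feeds_by_gravity(self):
        net = two_system_network("small", 1)
        areas = run_event_scenario(net, EventScenario("valve", 48.0, 0.5), 60.0)
        assert all(v > 0 for v in areas.values())


INP_TEXT = """\
[RESERVOIRS]
R  30.0
[JUNCTIONS]
; id  elev  demand  pattern  area
J1  9.0  800.0  diurnal  near
J2  10.0  1200.0  diurnal  far
[PIPES]
P1  R  J1  2500  300  130
P2  J1  J2  4000  250  130
[PATTERNS]
diurnal  1.0  0.8  1.2
[VALVES]
V1  R  J1
[STATUS]
V1  Closed
"""


class TestInpReader:
    def test_minimal_dialect_round_trip(self, tmp_path):
        p = tmp_path / "net.inp"
        p.write_text(INP_TEXT)
        net = read_inp(p)
        assert net.reservoir.head == 30.0
        assert net.junctions["J1"].pattern == (1.0, 0.8, 1.2)
        assert net.junctions["J2"].area == "far"
        assert net.pipes[0].diameter == pytest.approx(0.3)  # mm -> m
        assert not net.valves[0].open
        flows, _ = solve_hydraulics(net, 0)
        assert flows["P2"] == pytest.approx(net.junctions["J2"].demand_at(0), rel=1e-6)

    def test_unsupported_section_rejected_by_name(self, tmp_path):
        p = tmp_path / "bad.inp"
        p.write_text("[TANKS]\nT1 10\n")
        with pytest.raises(InpFormatError, match="TANKS"):
            read_inp(p)

    def test_two_reservoirs_rejected(self, tmp_path):
        p = tmp_path / "two.inp"
        p.write_text("[RESERVOIRS]\nR1 10\nR2 20\n[JUNCTIONS]\nJ1 0 5\n[PIPES]\nP1 R1 J1 100 200\n")
        with pytest.raises(InpFormatError, match="reservoir"):
            read_inp(p)
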