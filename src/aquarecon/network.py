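"""Extended-period simulation of the receiving distribution network.

During an interconnection event, contaminated water enters an otherwise
clean distribution system through a booster pump or a bypass valve.  The
sending system is abstracted as an infinite reservoir at fixed head and
fixed concentration on the upstream side of that connection.

Hydraulics are demand-driven: nodal continuity with Hazen–Williams head
loss, solved per time step by damped Newton iteration on nodal heads
(the global-gradient linearization).  Water quality is Lagrangian plug
flow: each pipe carries an ordered queue of parcels, nodes mix their
inflows completely and instantaneously, and no decay is applied — VOC
loss over the hours-to-days of an event is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Junction",
    "Reservoir",
    "Pipe",
    "Pump",
    "Valve",
    "PipeNetwork",
    "EPSResult",
    "EventScenario",
    "solve_hydraulics",
    "simulate_quality",
    "area_mean",
    "run_event_scenario",
    "read_inp",
    "ConnectivityError",
    "InpFormatError",
]

HW_EXP = 1.852
SEC_PER_DAY = 86400.0


class ConnectivityError(ValueError):
    """A demand node is disconnected from the boundary."""


class InpFormatError(ValueError):
    """The INP file uses an unsupported section or malformed line."""


@dataclass(frozen=True)
class Junction:
    id: str
    elevation: float = 0.0
    base_demand: float = 0.0  # m³/day
    pattern: tuple[float, ...] = (1.0,)  # hourly multipliers, cycled
    area: str = "default"

    def demand_at(self, hour: int) -> float:
        return self.base_demand * self.pattern[hour % len(self.pattern)]


@dataclass(frozen=True)
class Reservoir:
    """The fixed-head, fixed-concentration boundary (the sending system)."""

    id: str
    head: float
    concentration: float = 0.0  # μg/L, overridable per scenario


@dataclass(frozen=True)
class Pipe:
    id: str
    start: str
    end: str
    length: float  # m
    diameter: float  # m
    roughness: float = 130.0  # Hazen-Williams C

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0 or self.roughness <= 0:
            raise ValueError(f"pipe {self.id}: length, diameter, roughness must be > 0")

    @property
    def k(self) -> float:
        """Head loss = k * Q^1.852 with Q in m³/day."""
        k_si = 10.667 * self.length / (self.roughness**HW_EXP * self.diameter**4.871)
        return k_si / SEC_PER_DAY**HW_EXP

    @property
    def volume(self) -> float:
        return math.pi * self.diameter**2 / 4 * self.length


@dataclass(frozen=True)
class Pump:
    """Head gain h(Q) = h0 - r Q², r from the design point (q1, h1)."""

    id: str
    start: str
    end: str
    shutoff_head: float  # m
    design_flow: float  # m³/day
    design_head: float  # m

    def __post_init__(self) -> None:
        if not 0 < self.design_head < self.shutoff_head or self.design_flow <= 0:
            raise ValueError(f"pump {self.id}: need 0 < design_head < shutoff_head, design_flow > 0")

    @property
    def r(self) -> float:
        return (self.shutoff_head - self.design_head) / self.design_flow**2


@dataclass(frozen=True)
class Valve:
    id: str
    start: str
    end: str
    open: bool = True
    # an open valve behaves as a short, wide pipe
    k_equiv: float = 1e-10


@dataclass
class PipeNetwork:
    """Distribution network with exactly one boundary reservoir."""

    junctions: dict[str, Junction]
    reservoir: Reservoir
    pipes: list[Pipe]
    pumps: list[Pump] = field(default_factory=list)
    valves: list[Valve] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = set(self.junctions) | {self.reservoir.id}
        for link in self.links():
            for n in (link.start, link.end):
                if n not in ids:
                    raise ValueError(f"link {link.id}: unknown node {n!r}")
        g = nx.Graph()
        g.add_nodes_from(ids)
        for link in self.links():
            if isinstance(link, Valve) and not link.open:
                continue
            g.add_edge(link.start, link.end)
        # with all valves open, the network must be connected
        g_all = nx.Graph()
        g_all.add_nodes_from(ids)
        for link in self.links():
            g_all.add_edge(link.start, link.end)
        if not nx.is_connected(g_all):
            raise ValueError("network is not connected even with all valves open")

    def links(self) -> list:
        return [*self.pipes, *self.pumps, *self.valves]

    def with_valve_states(self, states: dict[str, bool]) -> "PipeNetwork":
        valves = [
            Valve(v.id, v.start, v.end, states.get(v.id, v.open), v.k_equiv) for v in self.valves
        ]
        return PipeNetwork(self.junctions, self.reservoir, self.pipes, self.pumps, valves)

    def without_pumps(self) -> "PipeNetwork":
        return PipeNetwork(self.junctions, self.reservoir, self.pipes, [], self.valves)

    def areas(self) -> list[str]:
        return sorted({j.area for j in self.junctions.values()})


# ------------------------------------------------------------- hydraulics


def _active_links(net: PipeNetwork) -> list:
    return [l for l in net.links() if not (isinstance(l, Valve) and not l.open)]


def _link_flow_and_gradient(link, dh: float) -> tuple[float, float]:
    """Flow (start→end, m³/day) and dQ/d(dh) for head difference dh = H_s - H_e."""
    if isinstance(link, Pump):
        # pump moves water start→end with gain g(Q) = h0 - rQ²; Q solves
        # H_e - H_s = g(Q)  =>  Q = sqrt((h0 - (-dh)) / r).  Past shutoff the
        # curve is extended linearly so the iteration never hits a dead zone
        # (the converged solution clips any residual reverse flow to 0).
        lift = -dh  # head the pump must add
        avail = link.shutoff_head - lift
        g_ref = 1.0 / (2 * link.r * link.design_flow)
        if avail <= 0:
            return avail * g_ref, g_ref
        q = math.sqrt(avail / link.r)
        grad = 1.0 / (2 * link.r * max(q, 0.05 * link.design_flow))
        return q, grad
    k = link.k_equiv if isinstance(link, Valve) else link.k
    delta = 1e-4  # linearize below this head difference, m
    if abs(dh) < delta:
        slope = (delta / k) ** (1 / HW_EXP) / delta
        return dh * slope, slope
    q = math.copysign((abs(dh) / k) ** (1 / HW_EXP), dh)
    grad = abs(q) / (HW_EXP * abs(dh))
    return q, grad


def solve_hydraulics(
    net: PipeNetwork, hour: int = 0, max_iter: int = 200, tol: float = 1e-6
) -> tuple[dict[str, float], dict[str, float]]:
    """Flows (per link, positive start→end) and heads for one step.

    Demand-driven: junction demands at this hour are withdrawn regardless
    of pressure.  Converges when the largest nodal imbalance is below
    ``tol`` × total demand (or an absolute floor when demand is zero).
    """
    links = _active_links(net)
    demands = {j.id: j.demand_at(hour) for j in net.junctions.values()}
    if any(d < 0 for d in demands.values()):
        raise ValueError("negative demand")
    # connectivity of demand nodes to the reservoir through open links
    g = nx.Graph()
    g.add_node(net.reservoir.id)
    g.add_nodes_from(net.junctions)
    for l in links:
        g.add_edge(l.start, l.end)
    reachable = nx.node_connected_component(g, net.reservoir.id)
    cut_off = [n for n, d in demands.items() if d > 0 and n not in reachable]
    if cut_off:
        raise ConnectivityError(f"demand nodes disconnected from boundary: {cut_off}")

    solve_nodes = [n for n in net.junctions if n in reachable]
    pos = {n: i for i, n in enumerate(solve_nodes)}
    h0 = net.reservoir.head
    heads = {n: h0 for n in solve_nodes}
    heads[net.reservoir.id] = h0
    total_d = sum(demands[n] for n in solve_nodes)
    scale = max(total_d, 1.0)
    links_in = [l for l in links if l.start in reachable]

    def assemble(hvec: np.ndarray):
        n = len(solve_nodes)
        J = np.zeros((n, n))
        F = np.array([-demands[m] for m in solve_nodes])
        hmap = dict(zip(solve_nodes, hvec))
        hmap[net.reservoir.id] = h0
        for l in links_in:
            dh = hmap[l.start] - hmap[l.end]
            q, grad = _link_flow_and_gradient(l, dh)
            for node, sign in ((l.start, -1.0), (l.end, 1.0)):
                if node in pos:
                    F[pos[node]] += sign * q
                    i = pos[node]
                    J[i, i] += grad
                    other = l.end if node == l.start else l.start
                    if other in pos:
                        J[i, pos[other]] -= grad
        return F, J

    hvec = np.array([heads[m] for m in solve_nodes])
    F, J = assemble(hvec)
    for _ in range(max_iter):
        if np.max(np.abs(F)) < tol * scale:
            heads = dict(zip(solve_nodes, hvec))
            heads[net.reservoir.id] = h0
            flows = {}
            for l in links:
                dh = heads.get(l.start, h0) - heads.get(l.end, h0)
                q = _link_flow_and_gradient(l, dh)[0] if l in links_in else 0.0
                if isinstance(l, Pump):
                    q = max(q, 0.0)  # check valve: no reverse flow through pumps
                flows[l.id] = q
            heads_out = dict(heads)
            for nd in net.junctions:
                heads_out.setdefault(nd, math.nan)  # disconnected, zero-demand
            return flows, heads_out
        try:
            step = np.linalg.solve(J + 1e-12 * np.eye(len(solve_nodes)), F)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"hydraulic Jacobian singular: {exc}") from exc
        step = np.clip(step, -50, 50)
        # backtracking line search on the nodal-imbalance norm
        norm0 = np.max(np.abs(F))
        lam = 1.0
        for _bt in range(25):
            F_new, J_new = assemble(hvec + lam * step)
            if np.max(np.abs(F_new)) < norm0 * (1 - 1e-4 * lam) or _bt == 24:
                hvec = hvec + lam * step
                F, J = F_new, J_new
                break
            lam *= 0.5
    raise RuntimeError(f"hydraulics did not converge in {max_iter} iterations")


# ---------------------------------------------------------------- quality


@dataclass
class EPSResult:
    """Time-resolved link flows, node heads and node concentrations."""

    times: np.ndarray  # hours from event start
    step: float  # hours
    link_flows: list[dict[str, float]]
    node_heads: list[dict[str, float]]
    node_conc: list[dict[str, float]]
    mass_in: float  # μg entering from the boundary over the run
    mass_delivered: float  # μg withdrawn at demand nodes
    mass_stored: float  # μg in pipe parcels at the end

    def mass_closure(self) -> float:
        """Relative mass-balance error over the run."""
        if self.mass_in == 0:
            return 0.0
        return abs(self.mass_in - self.mass_delivered - self.mass_stored) / self.mass_in


def simulate_quality(
    net: PipeNetwork,
    hydraulics: list[tuple[dict[str, float], dict[str, float]]],
    source_conc: float,
    duration: float,
    step: float = 0.25,
) -> EPSResult:
    """Lagrangian plug-flow transport over ``duration`` hours.

    ``hydraulics`` supplies (flows, heads) per step, as from
    :func:`solve_hydraulics`; the network starts clean (concentration 0
    everywhere) and the reservoir feeds at ``source_conc``.
    """
    if source_conc < 0:
        raise ValueError("source_conc must be >= 0")
    n_steps = int(round(duration / step))
    if len(hydraulics) < n_steps:
        raise ValueError(f"need hydraulics for {n_steps} steps, got {len(hydraulics)}")
    # warn when one quality step flushes a pipe many times over: the plug
    # structure inside that pipe is then unresolved
    flows0 = hydraulics[0][0]
    for p in net.pipes:
        q = abs(flows0.get(p.id, 0.0))
        if q > 1e-12 and step > 10.0 * (p.volume / q * 24.0):
            import warnings

            warnings.warn(
                f"quality step {step} h exceeds 10x the travel time of pipe {p.id}; "
                "results will be smeared — reduce the step",
                stacklevel=2,
            )
            break
    dt_day = step / 24.0
    links = {l.id: l for l in _active_links(net) if not isinstance(l, Pump)}
    pumps = {l.id: l for l in _active_links(net) if isinstance(l, Pump)}
    # parcel queues per pipe-like link: list of [volume, conc], index 0 at the
    # current downstream end; pumps have negligible volume (pass-through)
    queues: dict[str, list[list[float]]] = {
        lid: [[l.volume, 0.0]] for lid, l in links.items() if isinstance(l, Pipe)
    }
    queue_dir: dict[str, int] = {lid: +1 for lid in queues}  # +1: flow start→end
    node_conc = {n: 0.0 for n in net.junctions}
    node_conc[net.reservoir.id] = source_conc
    times = np.arange(1, n_steps + 1) * step
    out_conc, mass_in, mass_delivered = [], 0.0, 0.0

    all_links = {**links, **pumps}
    for si in range(n_steps):
        flows, _heads = hydraulics[si]
        dg = nx.MultiDiGraph()  # parallel links between a node pair are distinct
        dg.add_nodes_from([*net.junctions, net.reservoir.id])
        for lid, l in all_links.items():
            q = flows.get(lid, 0.0)
            if abs(q) > 1e-12:
                u, v = (l.start, l.end) if q > 0 else (l.end, l.start)
                dg.add_edge(u, v, link=lid)
        try:
            order = list(nx.topological_sort(dg))
        except nx.NetworkXUnfeasible:
            order = [net.reservoir.id, *net.junctions]  # rare: fall back, 1-step lag
        new_conc = dict(node_conc)
        new_conc[net.reservoir.id] = source_conc
        for node in order:
            if node == net.reservoir.id:
                continue
            vol_in = mass = 0.0
            for u, _v, data in dg.in_edges(node, data=True):
                lid = data["link"]
                l = all_links[lid]
                q = abs(flows[lid])
                vm = q * dt_day
                if lid in queues:
                    want_dir = +1 if flows[lid] > 0 else -1
                    if queue_dir[lid] != want_dir:
                        queues[lid].reverse()
                        queue_dir[lid] = want_dir
                    m_got, v_got = _pop_volume(queues[lid], vm)
                    mass += m_got + (vm - v_got) * new_conc[u] * 1e3
                    queues[lid].append([vm - max(vm - v_got, 0.0), new_conc[u]])
                    _normalize_queue(queues[lid], l.volume)
                else:  # pump: zero volume, pass-through
                    mass += vm * new_conc[u] * 1e3
                vol_in += vm
            if vol_in > 0:
                new_conc[node] = mass / (vol_in * 1e3)
        # advance links whose downstream node is the reservoir or that feed
        # nothing this step: flows through them still move parcels
        node_conc = new_conc
        out_conc.append(dict(node_conc))
        # boundary and demand mass accounting
        for lid, l in all_links.items():
            q = flows.get(lid, 0.0)
            if abs(q) < 1e-12:
                continue
            u = l.start if q > 0 else l.end
            if u == net.reservoir.id:
                mass_in += abs(q) * dt_day * source_conc * 1e3
        hour = int((si * step) // 1)
        for j in net.junctions.values():
            mass_delivered += j.demand_at(hour) * dt_day * node_conc[j.id] * 1e3

    mass_stored = sum(
        sum(v * c for v, c in q) * 1e3 for q in queues.values()
    )
    return EPSResult(
        times=times,
        step=step,
        link_flows=[hydraulics[i][0] for i in range(n_steps)],
        node_heads=[hydraulics[i][1] for i in range(n_steps)],
        node_conc=out_conc,
        mass_in=mass_in,
        mass_delivered=mass_delivered,
        mass_stored=mass_stored,
    )


def _pop_volume(queue: list[list[float]], vm: float) -> tuple[float, float]:
    """Remove up to *vm* volume from the downstream end; return (mass μg, volume)."""
    mass = got = 0.0
    while queue and got < vm - 1e-15:
        v, c = queue[0]
        take = min(v, vm - got)
        mass += take * c * 1e3
        got += take
        if take >= v - 1e-15:
            queue.pop(0)
        else:
            queue[0][0] = v - take
    return mass, got


def _normalize_queue(queue: list[list[float]], volume: float) -> None:
    """Trim/merge so total queue volume equals the pipe volume."""
    total = sum(v for v, _ in queue)
    excess = total - volume
    while excess > 1e-12 and queue:
        v, _c = queue[0]
        take = min(v, excess)
        if take >= v - 1e-15:
            queue.pop(0)
        else:
            queue[0][0] = v - take
        excess -= take
    if len(queue) > 400:  # bound memory on long runs
        merged = [queue[0]]
        for v, c in queue[1:]:
            pv, pc = merged[-1]
            if abs(c - pc) < 1e-9:
                merged[-1] = [pv + v, pc]
            else:
                merged.append([v, c])
        queue[:] = merged


def area_mean(result: EPSResult, net: PipeNetwork, area: str, window: tuple[float, float] | None = None) -> float:
    """Demand-weighted mean concentration over an area and time window (hours)."""
    nodes = [j for j in net.junctions.values() if j.area == area]
    if not nodes:
        raise ValueError(f"unknown area {area!r}; known areas: {net.areas()}")
    lo, hi = window if window is not None else (0.0, float(result.times[-1]))
    num = den = 0.0
    for si, t in enumerate(result.times):
        if not lo <= t <= hi:
            continue
        hour = int(((si) * result.step) // 1)
        for j in nodes:
            d = j.demand_at(hour)
            num += d * result.node_conc[si][j.id]
            den += d
    if den == 0:
        raise ValueError(f"area {area!r} has no demand in window [{lo}, {hi}] h")
    return num / den


@dataclass(frozen=True)
class EventScenario:
    """One interconnection event: pump-driven or continuous open valve."""

    mode: str  # "pump" | "valve"
    duration: float  # hours
    step: float = 0.25  # hours

    def __post_init__(self) -> None:
        if self.mode not in ("pump", "valve"):
            raise ValueError("scenario mode must be 'pump' or 'valve'")
        if self.duration < 0 or self.step <= 0:
            raise ValueError("duration must be >= 0 and step > 0")


def run_event_scenario(
    net: PipeNetwork, scenario: EventScenario, source_conc: float
) -> dict[str, float]:
    """Per-area mean concentrations over one interconnection event.

    ``mode="pump"``: the booster pump runs for the whole event, bypass
    valves closed.  ``mode="valve"``: the pump is absent and the bypass
    valve is open, so the boundary feeds by gravity through the valve.
    """
    if scenario.duration == 0:
        return {a: 0.0 for a in sorted({j.area for j in net.junctions.values() if j.base_demand > 0})}
    if scenario.mode == "valve":
        run_net = net.without_pumps().with_valve_states({v.id: True for v in net.valves})
    else:
        run_net = net.with_valve_states({v.id: False for v in net.valves})
    n_steps = int(round(scenario.duration / scenario.step))
    hydraulics = []
    cache: dict[int, tuple[dict, dict]] = {}
    period = math.lcm(*(len(j.pattern) for j in run_net.junctions.values()))
    for si in range(n_steps):
        hour = int((si * scenario.step) // 1) % period
        if hour not in cache:
            cache[hour] = solve_hydraulics(run_net, hour)
        hydraulics.append(cache[hour])
    result = simulate_quality(run_net, hydraulics, source_conc, scenario.duration, scenario.step)
    demand_areas = sorted(
        {j.area for j in run_net.junctions.values() if j.base_demand > 0}
    )
    return {a: area_mean(result, run_net, a) for a in demand_areas}


# -------------------------------------------------------------- INP reader

_SUPPORTED = {
    "RESERVOIRS",
    "JUNCTIONS",
    "PIPES",
    "PUMPS",
    "VALVES",
    "DEMANDS",
    "PATTERNS",
    "STATUS",
}


def read_inp(path) -> PipeNetwork:
    """Read a minimal EPANET-INP dialect.

    Units: elevation/head m, pipe length m, diameter mm, demand m³/day.
    Sections other than [RESERVOIRS], [JUNCTIONS], [PIPES], [PUMPS],
    [VALVES], [DEMANDS], [PATTERNS], [STATUS] are rejected by name.
    Junction lines: ``id elevation [demand] [pattern] [area]``.
    Pump lines: ``id node1 node2 shutoff_head design_flow design_head``.
    """
    sections: dict[str, list[list[str]]] = {}
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split(";")[0].strip()
            if not line:
                continue
            if line.startswith("["):
                name = line.strip("[]").upper()
                if name not in _SUPPORTED:
                    raise InpFormatError(f"unsupported INP section [{name}]")
                current = name
                sections.setdefault(current, [])
                continue
            if current is None:
                raise InpFormatError(f"data before any section: {line!r}")
            sections[current].append(line.split())

    patterns: dict[str, list[float]] = {}
    for tok in sections.get("PATTERNS", []):
        patterns.setdefault(tok[0], []).extend(float(x) for x in tok[1:])

    res_rows = sections.get("RESERVOIRS", [])
    if len(res_rows) != 1:
        raise InpFormatError(f"need exactly one reservoir, got {len(res_rows)}")
    reservoir = Reservoir(id=res_rows[0][0], head=float(res_rows[0][1]))

    junctions: dict[str, Junction] = {}
    for tok in sections.get("JUNCTIONS", []):
        jid, elev = tok[0], float(tok[1])
        demand = float(tok[2]) if len(tok) > 2 else 0.0
        pat = tuple(patterns[tok[3]]) if len(tok) > 3 and tok[3] in patterns else (1.0,)
        area = tok[4] if len(tok) > 4 else "default"
        junctions[jid] = Junction(jid, elev, demand, pat, area)
    for tok in sections.get("DEMANDS", []):
        jid, demand = tok[0], float(tok[1])
        if jid not in junctions:
            raise InpFormatError(f"[DEMANDS] references unknown junction {jid!r}")
        j = junctions[jid]
        pat = tuple(patterns[tok[2]]) if len(tok) > 2 and tok[2] in patterns else j.pattern
        junctions[jid] = Junction(j.id, j.elevation, demand, pat, j.area)

    pipes = [
        Pipe(t[0], t[1], t[2], float(t[3]), float(t[4]) / 1000.0, float(t[5]) if len(t) > 5 else 130.0)
        for t in sections.get("PIPES", [])
    ]
    pumps = [
        Pump(t[0], t[1], t[2], float(t[3]), float(t[4]), float(t[5]))
        for t in sections.get("PUMPS", [])
    ]
    status = {t[0]: t[1].lower() == "open" for t in sections.get("STATUS", [])}
    valves = [
        Valve(t[0], t[1], t[2], status.get(t[0], True)) for t in sections.get("VALVES", [])
    ]
    return PipeNetwork(junctions, reservoir, pipes, pumps, valves)
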