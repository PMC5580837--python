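"""Multi-layer finite-difference groundwater-flow solver.

Solves confined (linear) flow on the site grid with a 7-point stencil:
harmonic-mean intercell conductances, constant-head cells, head-dependent
stream leakage with fixed stage, areal recharge on the top layer, and
wells whose extraction is apportioned across screened layers by layer
transmissivity.  Aquitard layers carry vertical leakance only (no
horizontal flow), which reproduces the aquifer/semi-confining-unit
stacking of a layered coastal-plain system.

Steady state gives the predevelopment head field; the transient solver
steps monthly stress periods (constant pumping within a month) with
implicit Euler and a confined storage term ``Ss * thickness``.

Every solve closes a volumetric budget; the budget discrepancy
``|in - out| / max(in, out)`` is part of the returned field and is the
primary self-check (< 0.5 % required downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import AQUIFER, SiteModel, WellRecord
from .timeline import MonthIndex

__all__ = [
    "HeadField",
    "FlowField",
    "ResidualReport",
    "solve_steady_flow",
    "solve_transient_flow",
    "cell_flows",
    "compute_residuals",
    "BoundaryConditionError",
]

BUDGET_TOL = 0.005


class BoundaryConditionError(ValueError):
    """The flow system has no head control (singular)."""


@dataclass
class HeadField:
    """Heads per stress period plus the volumetric budget of each period.

    ``heads`` has shape (nper, nlay, nrow, ncol); steady solutions have
    nper == 1.  ``budgets`` holds, per period, inflow/outflow totals in
    m³/day by component (constant_head, stream, recharge, wells, storage)
    and the relative discrepancy.
    """

    heads: np.ndarray
    budgets: list[dict]
    months: list[MonthIndex] | None = None

    @property
    def nper(self) -> int:
        return self.heads.shape[0]

    def max_budget_discrepancy(self) -> float:
        return max(b["discrepancy"] for b in self.budgets)


@dataclass
class FlowField:
    """Face-by-face Darcy flows and per-cell boundary exchanges, m³/day.

    ``right``, ``front``, ``lower`` are flows across the +col, +row and
    +layer faces (positive toward increasing index).  Boundary arrays are
    per-cell net rates with sign convention: positive = water entering
    the cell (recharge, stream gain, storage release, boundary inflow);
    ``well`` is extraction (positive = water leaving).
    """

    right: np.ndarray
    front: np.ndarray
    lower: np.ndarray
    constant_head: np.ndarray
    stream: np.ndarray
    recharge: np.ndarray
    well: np.ndarray
    storage: np.ndarray

    def divergence(self) -> np.ndarray:
        """Net outflow minus sources per cell; ~0 everywhere by continuity."""
        out = np.zeros_like(self.right)
        out += self.right
        out[:, :, 1:] -= self.right[:, :, :-1]
        out += self.front
        out[:, 1:, :] -= self.front[:, :-1, :]
        out += self.lower
        out[1:, :, :] -= self.lower[:-1, :, :]
        return out - (self.constant_head + self.stream + self.recharge + self.storage - self.well)


@dataclass
class ResidualReport:
    """Observed-minus-simulated head residuals and the within-band fraction."""

    residuals: list[tuple[tuple[int, int, int], MonthIndex, float]]
    band: float
    fraction_within: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.residuals:
            raise ValueError("no usable head observations for a residual report")
        inside = sum(1 for *_, r in self.residuals if abs(r) <= self.band)
        self.fraction_within = inside / len(self.residuals)


# ----------------------------------------------------------------- assembly


class _System:
    """Static parts of the linear system for one site."""

    def __init__(self, site: SiteModel):
        self.site = site
        g = site.grid
        self.shape = g.shape
        n = g.ncells
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []

        def idx(l, r, c):
            return (l * g.nrow + r) * g.ncol + c

        self._idx = idx
        # horizontal conductances (aquifer layers only; homogeneous per layer)
        for l in range(g.nlay):
            if g.layer_role[l] != AQUIFER:
                continue
            t = site.transmissivity(l)
            cx = t * g.dy / g.dx
            cy = t * g.dx / g.dy
            for r in range(g.nrow):
                for c in range(g.ncol - 1):
                    self._connect(rows, cols, vals, idx(l, r, c), idx(l, r, c + 1), cx)
            for r in range(g.nrow - 1):
                for c in range(g.ncol):
                    self._connect(rows, cols, vals, idx(l, r, c), idx(l, r + 1, c), cy)
        # vertical conductances between adjacent layers (series resistances)
        for l in range(g.nlay - 1):
            b1, b2 = g.layer_thickness[l], g.layer_thickness[l + 1]
            kv1, kv2 = site.layers[l].kv, site.layers[l + 1].kv
            cv = g.cell_area / (b1 / (2 * kv1) + b2 / (2 * kv2))
            for r in range(g.nrow):
                for c in range(g.ncol):
                    self._connect(rows, cols, vals, idx(l, r, c), idx(l + 1, r, c), cv)

        self.L = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
        )

        # head-dependent stream leakage: diagonal conductance + stage forcing
        self.stream_diag = np.zeros(n)
        self.stream_rhs = np.zeros(n)
        self.stream_cells = []
        for (l, r, c, stage, cond) in site.stream_cells:
            i = idx(l, r, c)
            self.stream_diag[i] += cond
            self.stream_rhs[i] += cond * stage
            self.stream_cells.append((i, stage, cond))

        # constant heads, sorted by linear index so boolean-mask column
        # ordering and the head vector stay aligned
        chd_idx = np.array([idx(l, r, c) for (l, r, c, _h) in site.constant_head_cells], dtype=int)
        chd_head = np.array([h for (*_, h) in site.constant_head_cells])
        if len(np.unique(chd_idx)) != len(chd_idx):
            raise ValueError("duplicate constant-head cells")
        order = np.argsort(chd_idx)
        self.chd_idx = chd_idx[order]
        self.chd_head = chd_head[order]
        self.free = np.ones(n, dtype=bool)
        self.free[self.chd_idx] = False

        # recharge on top layer
        self.recharge_rhs = np.zeros(n)
        self.recharge_rhs[: g.nrow * g.ncol] = (site.recharge * g.cell_area).ravel()

        # confined storage coefficient per cell (m²): Ss * b * area
        sc = np.empty(g.shape)
        for l in range(g.nlay):
            sc[l] = site.layers[l].specific_storage * g.layer_thickness[l] * g.cell_area
        self.storage = sc.ravel()

        if len(self.chd_idx) == 0 and not site.stream_cells:
            raise BoundaryConditionError("site has no constant-head or stream cells")

    @staticmethod
    def _connect(rows, cols, vals, i, j, c):
        rows.append(np.array([i, j, i, j]))
        cols.append(np.array([i, j, j, i]))
        vals.append(np.array([c, c, -c, -c]))

    def well_rates(self, q_by_well: dict[str, float]) -> np.ndarray:
        """Distribute per-well extraction onto cells by transmissivity share."""
        q = np.zeros(self.site.grid.ncells)
        for w in self.site.wells:
            rate = q_by_well.get(w.id, 0.0)
            if rate == 0.0:
                continue
            for l, share in self.site.well_layer_weights(w).items():
                q[self._idx(l, w.row, w.col)] += rate * share
        return q

    def solve(self, wells_q: np.ndarray, storage_dt: float | None = None, h_old: np.ndarray | None = None):
        """Solve one stress step; returns heads (flat) for all cells."""
        n = self.site.grid.ncells
        diag = self.stream_diag.copy()
        rhs = self.stream_rhs + self.recharge_rhs - wells_q
        if storage_dt is not None:
            diag = diag + self.storage / storage_dt
            rhs = rhs + self.storage / storage_dt * h_old
        A = self.L + sp.diags(diag)
        free = self.free
        if len(self.chd_idx):
            rhs_f = rhs[free] - A[free][:, ~free] @ self.chd_head
        else:
            rhs_f = rhs[free]
        A_ff = A[free][:, free].tocsc()
        h = np.empty(n)
        h[~free] = self.chd_head
        try:
            h[free] = spla.spsolve(A_ff, rhs_f)
        except Exception as exc:  # singular system
            raise BoundaryConditionError(f"flow system could not be solved: {exc}") from exc
        if not np.all(np.isfinite(h)):
            raise BoundaryConditionError("flow solution not finite; system is singular")
        res = np.linalg.norm(A_ff @ h[free] - rhs_f)
        scale = np.linalg.norm(rhs_f)
        if scale > 0 and res / scale > 1e-8:
            raise RuntimeError(f"flow solve residual {res / scale:.2e} too large")
        return h

    def budget(self, h: np.ndarray, wells_q: np.ndarray, storage_dt=None, h_old=None) -> dict:
        """Volumetric budget of one solved step, m³/day by component."""
        comp_in = {k: 0.0 for k in ("constant_head", "stream", "recharge", "wells", "storage")}
        comp_out = {k: 0.0 for k in comp_in}
        # constant-head exchange: net flow from each chd cell into its neighbors
        if len(self.chd_idx):
            q_chd = (self.L @ h)[self.chd_idx]
            comp_in["constant_head"] = float(q_chd[q_chd > 0].sum())
            comp_out["constant_head"] = float(-q_chd[q_chd < 0].sum())
        q_str = np.zeros(0)
        if self.stream_cells:
            q_str = np.array([cond * (stage - h[i]) for (i, stage, cond) in self.stream_cells])
            comp_in["stream"] = float(q_str[q_str > 0].sum())
            comp_out["stream"] = float(-q_str[q_str < 0].sum())
        rch = self.recharge_rhs[self.free]
        comp_in["recharge"] = float(rch[rch > 0].sum())
        comp_out["recharge"] = float(-rch[rch < 0].sum())
        comp_out["wells"] = float(wells_q[self.free].sum())
        if storage_dt is not None:
            q_sto = (self.storage * (h_old - h) / storage_dt)[self.free]
            comp_in["storage"] = float(q_sto[q_sto > 0].sum())
            comp_out["storage"] = float(-q_sto[q_sto < 0].sum())
        total_in = sum(comp_in.values())
        total_out = sum(comp_out.values())
        disc = abs(total_in - total_out) / max(total_in, total_out, 1e-300)
        return {
            "in": comp_in,
            "out": comp_out,
            "total_in": total_in,
            "total_out": total_out,
            "discrepancy": disc,
        }


def _check_budget(budget: dict) -> None:
    if budget["total_in"] > 1e-12 and budget["discrepancy"] > BUDGET_TOL:
        raise RuntimeError(f"flow budget discrepancy {budget['discrepancy']:.3%} exceeds 0.5%")


def solve_steady_flow(site: SiteModel) -> HeadField:
    """Predevelopment steady-state heads (no wells pumping)."""
    sys = _System(site)
    wells_q = np.zeros(site.grid.ncells)
    h = sys.solve(wells_q)
    budget = sys.budget(h, wells_q)
    _check_budget(budget)
    return HeadField(heads=h.reshape((1, *site.grid.shape)), budgets=[budget])


def solve_transient_flow(
    site: SiteModel,
    schedule,
    initial: HeadField,
    substeps_per_month: int = 2,
) -> HeadField:
    """Transient heads over the site clock under a monthly pumping schedule.

    Implicit Euler with ``substeps_per_month`` equal sub-steps per monthly
    stress period; rates are constant within a month.  Returns one head
    snapshot per month (the last sub-step, i.e. the last day of the
    month) with a per-month budget that includes storage.
    """
    if substeps_per_month < 1:
        raise ValueError("substeps_per_month must be >= 1")
    sys = _System(site)
    months = site.clock
    for m in months:
        if not schedule.covers(m):
            raise ValueError(f"pumping schedule does not cover month {m}")
    h = initial.heads[-1].ravel().copy()
    heads = np.empty((len(months), *site.grid.shape))
    budgets: list[dict] = []
    factor_cache: dict[float, object] = {}
    for mi, month in enumerate(months):
        dt = month.days / substeps_per_month
        wells_q = sys.well_rates(schedule.rates_for(month))
        # aggregate the exact per-substep budgets into a month-mean budget
        acc_in = {k: 0.0 for k in ("constant_head", "stream", "recharge", "wells", "storage")}
        acc_out = {k: 0.0 for k in acc_in}
        for _ in range(substeps_per_month):
            h_prev = h
            h = _transient_step(sys, wells_q, dt, h, factor_cache)
            sub = sys.budget(h, wells_q, storage_dt=dt, h_old=h_prev)
            w = dt / month.days
            for k in acc_in:
                acc_in[k] += w * sub["in"][k]
                acc_out[k] += w * sub["out"][k]
        heads[mi] = h.reshape(site.grid.shape)
        total_in, total_out = sum(acc_in.values()), sum(acc_out.values())
        budget = {
            "in": acc_in,
            "out": acc_out,
            "total_in": total_in,
            "total_out": total_out,
            "discrepancy": abs(total_in - total_out) / max(total_in, total_out, 1e-300),
        }
        budgets.append(budget)
        _check_budget(budget)
    return HeadField(heads=heads, budgets=budgets, months=months)


def _transient_step(sys: _System, wells_q, dt, h_old, factor_cache):
    """One implicit-Euler sub-step, reusing the LU factor for repeated dt."""
    key = round(dt, 9)
    if key not in factor_cache:
        diag = sys.stream_diag + sys.storage / dt
        A = (sys.L + sp.diags(diag)).tocsr()
        free = sys.free
        A_ff = A[free][:, free].tocsc()
        A_fc = A[free][:, ~free] if len(sys.chd_idx) else None
        factor_cache[key] = (spla.splu(A_ff), A_fc)
    lu, A_fc = factor_cache[key]
    rhs = sys.stream_rhs + sys.recharge_rhs - wells_q + sys.storage / dt * h_old
    free = sys.free
    rhs_f = rhs[free]
    if A_fc is not None:
        rhs_f = rhs_f - A_fc @ sys.chd_head
    h = np.empty_like(h_old)
    h[~free] = sys.chd_head
    h[free] = lu.solve(rhs_f)
    return h


def cell_flows(
    site: SiteModel,
    heads: np.ndarray,
    wells_q_cells: np.ndarray | None = None,
    heads_prev: np.ndarray | None = None,
    dt: float | None = None,
) -> FlowField:
    """Face-by-face Darcy flows for one solved stress period.

    ``heads`` is (nlay, nrow, ncol).  ``wells_q_cells`` is per-cell
    extraction (m³/day, positive out), as produced by the solver's
    transmissivity apportionment.  When ``heads_prev`` and ``dt`` are
    given, the storage exchange is included so that the divergence of the
    returned field closes also for transient periods.
    """
    g = site.grid
    if heads.shape != g.shape:
        raise ValueError(f"heads shape {heads.shape} does not match grid {g.shape}")
    right = np.zeros(g.shape)
    front = np.zeros(g.shape)
    lower = np.zeros(g.shape)
    for l in range(g.nlay):
        if g.layer_role[l] == AQUIFER:
            t = site.transmissivity(l)
            right[l, :, :-1] = t * g.dy / g.dx * (heads[l, :, :-1] - heads[l, :, 1:])
            front[l, :-1, :] = t * g.dx / g.dy * (heads[l, :-1, :] - heads[l, 1:, :])
    for l in range(g.nlay - 1):
        b1, b2 = g.layer_thickness[l], g.layer_thickness[l + 1]
        cv = g.cell_area / (b1 / (2 * site.layers[l].kv) + b2 / (2 * site.layers[l + 1].kv))
        lower[l] = cv * (heads[l] - heads[l + 1])

    stream = np.zeros(g.shape)
    for (l, r, c, stage, cond) in site.stream_cells:
        stream[l, r, c] += cond * (stage - heads[l, r, c])
    recharge = np.zeros(g.shape)
    recharge[0] = site.recharge * g.cell_area
    well = np.zeros(g.shape) if wells_q_cells is None else wells_q_cells.reshape(g.shape).copy()
    storage = np.zeros(g.shape)
    if heads_prev is not None and dt is not None:
        sc = np.empty(g.shape)
        for l in range(g.nlay):
            sc[l] = site.layers[l].specific_storage * g.layer_thickness[l] * g.cell_area
        storage = sc * (heads_prev - heads) / dt

    ff = FlowField(right, front, lower, np.zeros(g.shape), stream, recharge, well, storage)
    # the residual divergence at a constant-head cell is exactly the
    # boundary exchange needed to close continuity there (positive = the
    # boundary supplies water to the cell)
    div = ff.divergence()
    chd = np.zeros(g.shape)
    for (l, r, c, _h) in site.constant_head_cells:
        chd[l, r, c] = div[l, r, c]
    ff.constant_head = chd
    return ff


def flow_fields_for_schedule(
    site: SiteModel, head_series: HeadField, schedule, initial: HeadField
) -> list[FlowField]:
    """Per-month flow fields (with storage closure) for a transient solution."""
    sys = _System(site)
    fields = []
    prev = initial.heads[-1]
    for mi, month in enumerate(head_series.months):
        wq = sys.well_rates(schedule.rates_for(month)).reshape(site.grid.shape)
        fields.append(
            cell_flows(site, head_series.heads[mi], wq, heads_prev=prev, dt=month.days)
        )
        prev = head_series.heads[mi]
    return fields


def compute_residuals(observed, simulated: HeadField, band: float = 1.5) -> ResidualReport:
    """Observed − simulated heads at matching cells and months.

    ``observed`` provides ``head_obs`` tuples (layer, row, col, month,
    head).  For a steady (single-period) field the month is ignored.
    The default ±1.5 m band is the calibration criterion (±5 ft) used
    to judge predevelopment fit.
    """
    residuals = []
    month_pos = {m: i for i, m in enumerate(simulated.months)} if simulated.months else None
    for (l, r, c, month, head) in observed.head_obs:
        if month_pos is None:
            sim = simulated.heads[0, l, r, c]
        else:
            if month not in month_pos:
                continue
            sim = simulated.heads[month_pos[month], l, r, c]
        residuals.append(((l, r, c), month, float(head - sim)))
    return ResidualReport(residuals=residuals, band=band)
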