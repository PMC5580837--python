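"""Dissolved-phase contaminant fate and transport.

Solves advection–dispersion–retardation–first-order-decay on the flow
solver's face-flow fields with an operator-split scheme per sub-step:

1. explicit first-order upwind advection, automatically sub-stepped so
   the cell Courant number never exceeds 1 (monotone, positivity
   preserving; its numerical dispersion is the price);
2. implicit (backward Euler) dispersion with a longitudinal/transverse
   decomposition of the dispersion tensor (diagonal approximation) plus
   molecular diffusion;
3. exact exponential first-order decay.

Retardation R rescales the whole operator: seepage velocities,
dispersion and decay all act at rate 1/R, so a retarded solute follows
the conservative solution with time stretched by R.

Sources are constant-concentration cells: held at their concentration
through their active month window, released afterwards.  Boundary
inflows (recharge, stream leakage, constant-head inflow) carry clean
water; extraction wells and boundary outflows remove water at the cell
concentration; elastic-storage exchange carries the cell concentration,
closing the water balance without altering concentrations.

Monthly snapshots are the state at the final sub-step of each month,
i.e. the last day of the month — the convention every downstream stage
assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .flow import FlowField
from .model import ContaminantSpec, SiteModel, SourceTerm
from .timeline import MonthIndex, MonthlySeries
from .wells import PumpingSchedule

__all__ = ["ConcField", "solve_transport", "extract_well_series", "StabilityError"]


class StabilityError(RuntimeError):
    """Courant sub-stepping exceeded its cap; coarsen the time resolution."""


@dataclass
class ConcField:
    """Concentration snapshots (μg/L) per (layer, row, col) per month."""

    conc: np.ndarray  # (n_months, nlay, nrow, ncol)
    months: list[MonthIndex]
    contaminant: ContaminantSpec

    def at(self, when: MonthIndex) -> np.ndarray:
        return self.conc[when - self.months[0]]

    def total_mass(self, site: SiteModel, month_i: int) -> float:
        """Dissolved + sorbed mass (μg) at a monthly snapshot."""
        g = site.grid
        vol = np.empty(g.shape)
        for l in range(g.nlay):
            vol[l] = g.cell_area * g.layer_thickness[l] * site.layers[l].porosity
        # per-volume retardation folds the sorbed phase into the balance
        return float((self.conc[month_i] * vol).sum() * 1e3 * self.contaminant.retardation)


def _pore_volume(site: SiteModel) -> np.ndarray:
    g = site.grid
    vol = np.empty(g.shape)
    for l in range(g.nlay):
        vol[l] = g.cell_area * g.layer_thickness[l] * site.layers[l].porosity
    return vol


def _shift_from_left(a: np.ndarray, axis: int) -> np.ndarray:
    """Value of the face/cell on the low-index side, 0 past the edge."""
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    src[axis] = slice(None, -1)
    dst[axis] = slice(1, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _shift_from_right(a: np.ndarray, axis: int) -> np.ndarray:
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    src[axis] = slice(1, None)
    dst[axis] = slice(None, -1)
    out[tuple(dst)] = a[tuple(src)]
    return out


class _AdvectionOperator:
    """Vectorized upwind fluxes for one stress period's flow field."""

    def __init__(self, ff: FlowField, ret_volume: np.ndarray):
        faces = {0: ff.lower, 1: ff.front, 2: ff.right}  # +axis direction flows
        self.pos = {ax: np.maximum(f, 0.0) for ax, f in faces.items()}
        self.neg = {ax: np.maximum(-f, 0.0) for ax, f in faces.items()}
        clean_in = (
            np.maximum(ff.constant_head, 0.0)
            + np.maximum(ff.stream, 0.0)
            + np.maximum(ff.recharge, 0.0)
        )
        dirty_out = (
            np.maximum(-ff.constant_head, 0.0)
            + np.maximum(-ff.stream, 0.0)
            + np.maximum(-ff.recharge, 0.0)
            + ff.well
        )
        self.storage = ff.storage
        # total outflow coefficient per cell (faces + sinks); storage release
        # enters as +q_sto*C which cancels the matching dilution exactly
        out = dirty_out - self.storage
        for ax in (0, 1, 2):
            out = out + self.pos[ax] + _shift_from_left(self.neg[ax], ax)
        self.out_coeff = out
        self.ret_volume = ret_volume
        self.max_rate = float(np.max(np.maximum(out, 0.0) / ret_volume))

    def rate(self, c: np.ndarray) -> np.ndarray:
        """dC/dt from advection, μg/L/day."""
        inflow = np.zeros_like(c)
        for ax in (0, 1, 2):
            # face at +side of cell with negative flow brings neighbor's C
            inflow += self.neg[ax] * _shift_from_right(c, ax)
            # face at -side of cell with positive flow brings neighbor's C
            inflow += _shift_from_left(self.pos[ax] * c, ax)
        return (inflow - self.out_coeff * c) / self.ret_volume


def _dispersion_matrix(
    site: SiteModel, ff: FlowField, spec: ContaminantSpec, ret_volume: np.ndarray
) -> sp.csc_matrix | None:
    """Backward-Euler generator L with (L C)_i = dC_i/dt from dispersion."""
    if spec.disp_long == 0 and spec.disp_transv == 0 and spec.mol_diffusion == 0:
        return None
    g = site.grid
    thick = np.array(g.layer_thickness)[:, None, None]
    poro = np.array([l.porosity for l in site.layers])[:, None, None]
    # cell-centered seepage velocities from face-flow averages
    ax_area = {0: g.cell_area, 1: g.dx * thick, 2: g.dy * thick}
    v = {}
    for ax, flows in ((0, ff.lower), (1, ff.front), (2, ff.right)):
        mean_q = 0.5 * (flows + _shift_from_left(flows, ax))
        v[ax] = mean_q / (ax_area[ax] * poro)
    speed = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = {
            ax: np.where(
                speed > 0,
                spec.disp_long * v[ax] ** 2 / np.maximum(speed, 1e-300)
                + spec.disp_transv * (speed**2 - v[ax] ** 2) / np.maximum(speed, 1e-300),
                0.0,
            )
            + spec.mol_diffusion
            for ax in (0, 1, 2)
        }
    dist = {0: None, 1: g.dy, 2: g.dx}
    n = g.ncells
    rows, cols, vals = [], [], []
    lin = np.arange(n).reshape(g.shape)

    def add_faces(ax, cond):
        """cond: conductance (m³/day) of each face toward +ax (last slice invalid)."""
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        i = lin[tuple(sl_lo)].ravel()
        j = lin[tuple(sl_hi)].ravel()
        c = cond[tuple(sl_lo)].ravel()
        rows.extend([i, j, i, j])
        cols.extend([i, j, j, i])
        vals.extend([c, c, -c, -c])

    # horizontal faces within each layer
    for ax in (1, 2):
        d_face = 0.5 * (d[ax] + _shift_from_right(d[ax], ax))
        cond = d_face * poro * ax_area[ax] / dist[ax]
        add_faces(ax, cond)
    # vertical faces: distance between layer centers
    dz_face = np.zeros(g.shape)
    for l in range(g.nlay - 1):
        dz_face[l] = 0.5 * (g.layer_thickness[l] + g.layer_thickness[l + 1])
    dz_face[-1] = 1.0  # unused slice
    d_face_v = 0.5 * (d[0] + _shift_from_right(d[0], 0))
    poro_face = 0.5 * (poro + np.roll(poro, -1, axis=0))
    cond_v = d_face_v * poro_face * g.cell_area / dz_face
    add_faces(0, cond_v)

    L = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return L  # symmetric positive-Laplacian form: Vr dC/dt = -(L C)


def solve_transport(
    site: SiteModel,
    flow_fields: list[FlowField],
    contaminant: ContaminantSpec,
    sources: list[SourceTerm] | None = None,
    substeps_per_month: int = 2,
    initial: np.ndarray | None = None,
    max_courant_substeps: int = 5000,
) -> ConcField:
    """March the contaminant over the site clock and snapshot monthly.

    ``flow_fields`` gives one :class:`~aquarecon.flow.FlowField` per
    month of the site clock (from ``flow_fields_for_schedule``).
    """
    months = site.clock
    if len(flow_fields) != len(months):
        raise ValueError(f"need {len(months)} flow fields, got {len(flow_fields)}")
    if sources is None:
        sources = list(site.sources)
    g = site.grid
    ret_volume = _pore_volume(site) * contaminant.retardation
    c = np.zeros(g.shape) if initial is None else initial.astype(float).copy()
    out = np.empty((len(months), *g.shape))
    lam_eff = contaminant.decay_rate / contaminant.retardation

    prev_ff = None
    adv = None
    disp_L = None
    solver_cache: dict[float, object] = {}
    for mi, month in enumerate(months):
        ff = flow_fields[mi]
        if ff is not prev_ff:
            adv = _AdvectionOperator(ff, ret_volume)
            disp_L = _dispersion_matrix(site, ff, contaminant, ret_volume)
            solver_cache.clear()
            prev_ff = ff
        active = [(s.cells, s.concentration) for s in sources if s.active(month)]

        def apply_sources(carr):
            for cells, conc in active:
                for cell in cells:
                    carr[cell] = conc

        apply_sources(c)
        dt = month.days / substeps_per_month
        n_adv = max(1, int(np.ceil(dt * adv.max_rate * 1.0001)))
        if n_adv > max_courant_substeps:
            raise StabilityError(
                f"month {month}: {n_adv} Courant sub-steps needed (cap {max_courant_substeps}); "
                "coarsen the time resolution or refine the grid"
            )
        dt_adv = dt / n_adv
        disp_solver = None
        if disp_L is not None:
            # backward Euler via CG on the similarity-symmetrized system
            # (I + dt D^-1/2 L D^-1/2) y = D^1/2 c,  c_new = D^-1/2 y
            key = round(dt, 9)
            if key not in solver_cache:
                d_sqrt = np.sqrt(ret_volume.ravel())
                scale = sp.diags(1.0 / d_sqrt)
                A_hat = (sp.identity(g.ncells, format="csr") + dt * (scale @ disp_L @ scale)).tocsr()
                solver_cache[key] = (A_hat, d_sqrt)
            disp_solver = solver_cache[key]
        for _ in range(substeps_per_month):
            for _ in range(n_adv):
                c = c + dt_adv * adv.rate(c)
                apply_sources(c)
            if disp_solver is not None:
                A_hat, d_sqrt = disp_solver
                y0 = d_sqrt * c.ravel()
                y, info = spla.cg(A_hat, y0, x0=y0, rtol=1e-12, atol=0.0, maxiter=500)
                if info != 0:
                    raise RuntimeError(f"dispersion CG failed to converge (info={info})")
                c = (y / d_sqrt).reshape(g.shape)
                apply_sources(c)
            if lam_eff > 0:
                c *= np.exp(-lam_eff * dt)
                apply_sources(c)
        if c.min() < -1e-9 * max(1.0, c.max()):
            raise RuntimeError(f"scheme produced negative concentration {c.min():.3e}")
        c = np.maximum(c, 0.0)
        out[mi] = c
    return ConcField(conc=out, months=months, contaminant=contaminant)


def extract_well_series(
    conc: ConcField, site: SiteModel, schedule: PumpingSchedule
) -> dict[str, MonthlySeries]:
    """Flow-weighted monthly concentration at each supply well.

    For wells screened across multiple water-bearing units the extracted
    concentration is the transmissivity-share weighted mean over screened
    layers — the same weights the flow solver uses to apportion pumping,
    so extraction and flow agree.  Months with zero pumping are missing.
    """
    months = conc.months
    series: dict[str, MonthlySeries] = {}
    for w in site.wells:
        weights = site.well_layer_weights(w)
        vals = np.full(len(months), np.nan)
        for mi, month in enumerate(months):
            if schedule.rates_for(month).get(w.id, 0.0) > 0:
                vals[mi] = sum(
                    share * conc.conc[mi, l, w.row, w.col] for l, share in weights.items()
                )
        series[w.id] = MonthlySeries(months[0], vals)
    return series
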