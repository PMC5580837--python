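"""Physical description of a study area.

A :class:`SiteModel` is the complete input to the groundwater flow and
transport stages: a layered finite-difference grid, hydraulic properties
per layer, head-controlling boundaries (constant-head cells and
head-dependent stream cells), areal recharge, constant-concentration
contaminant sources with start/end months, and supply wells with
documented service intervals.

Conventions
-----------
* Internal units are SI throughout: metres, days, m³/day, μg/L.
* Grid indexing is 0-based ``(layer, row, col)`` with layer 0 on top.
* Layers are either ``aquifer`` (horizontal + vertical flow) or
  ``aquitard`` (vertical leakance only); the default stack is 7 layers
  with layers 0, 2, 4, 6 aquifers, mirroring a coastal-plain sequence of
  water-bearing units separated by semi-confining units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeline import MonthIndex, month_range

__all__ = [
    "ContaminantSpec",
    "GridSpec",
    "LayerProperties",
    "SourceTerm",
    "WellRecord",
    "SiteModel",
    "DemandSeries",
]

AQUIFER = "aquifer"
AQUITARD = "aquitard"


@dataclass(frozen=True)
class ContaminantSpec:
    """Transport properties and regulatory limit of one dissolved VOC.

    retardation : dimensionless factor >= 1 by which sorption slows the
        solute relative to water.
    decay_rate : first-order decay constant, 1/day.
    disp_long, disp_transv : longitudinal / transverse dispersivity, m.
    mol_diffusion : effective molecular diffusion coefficient, m²/day.
    mcl : maximum contaminant level, μg/L.
    """

    name: str
    retardation: float = 1.0
    decay_rate: float = 0.0
    disp_long: float = 10.0
    disp_transv: float = 1.0
    mol_diffusion: float = 0.0
    mcl: float = 5.0

    def __post_init__(self) -> None:
        if self.retardation < 1:
            raise ValueError(f"{self.name}: retardation must be >= 1")
        if self.decay_rate < 0:
            raise ValueError(f"{self.name}: decay_rate must be >= 0")
        if self.disp_long < 0 or self.disp_transv < 0 or self.mol_diffusion < 0:
            raise ValueError(f"{self.name}: dispersivities/diffusion must be >= 0")
        if self.disp_transv > self.disp_long:
            raise ValueError(f"{self.name}: disp_transv must be <= disp_long")
        if self.mcl <= 0:
            raise ValueError(f"{self.name}: mcl must be > 0")


# Regulatory limits for the study's five VOCs (μg/L).
MCLS = {"TCE": 5.0, "PCE": 5.0, "benzene": 5.0, "12tDCE": 100.0, "VC": 2.0}


@dataclass(frozen=True)
class GridSpec:
    """Uniform rectangular finite-difference grid."""

    nlay: int
    nrow: int
    ncol: int
    dx: float
    dy: float
    layer_thickness: tuple[float, ...]
    layer_role: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer_thickness", tuple(float(t) for t in self.layer_thickness))
        object.__setattr__(self, "layer_role", tuple(self.layer_role))
        if min(self.nlay, self.nrow, self.ncol) < 1:
            raise ValueError("grid dimensions must be positive")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be > 0")
        if len(self.layer_thickness) != self.nlay or len(self.layer_role) != self.nlay:
            raise ValueError("need one thickness and one role per layer")
        if any(t <= 0 for t in self.layer_thickness):
            raise ValueError("layer thicknesses must be > 0")
        bad = [r for r in self.layer_role if r not in (AQUIFER, AQUITARD)]
        if bad:
            raise ValueError(f"layer roles must be aquifer|aquitard, got {bad}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nlay, self.nrow, self.ncol)

    @property
    def ncells(self) -> int:
        return self.nlay * self.nrow * self.ncol

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    def aquifer_layers(self) -> list[int]:
        return [k for k, r in enumerate(self.layer_role) if r == AQUIFER]

    def contains(self, layer: int, row: int, col: int) -> bool:
        return 0 <= layer < self.nlay and 0 <= row < self.nrow and 0 <= col < self.ncol


@dataclass(frozen=True)
class LayerProperties:
    """Homogeneous hydraulic properties of one model layer.

    kh, kv : horizontal / vertical hydraulic conductivity, m/day.
    specific_storage : 1/m.
    porosity : effective porosity, dimensionless in (0, 1).
    """

    kh: float
    kv: float
    specific_storage: float
    porosity: float

    def __post_init__(self) -> None:
        if min(self.kh, self.kv, self.specific_storage, self.porosity) <= 0:
            raise ValueError("layer properties must be strictly positive")
        if self.porosity >= 1:
            raise ValueError("porosity must be < 1")


@dataclass(frozen=True)
class SourceTerm:
    """Constant-concentration contaminant source active over a month window.

    Cells are held at *concentration* from *start* through *end*
    inclusive and released afterwards.
    """

    cells: tuple[tuple[int, int, int], ...]
    concentration: float
    start: MonthIndex
    end: MonthIndex

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(tuple(c) for c in self.cells))
        if not self.cells:
            raise ValueError("source has no cells")
        if self.concentration <= 0:
            raise ValueError("source concentration must be > 0")
        if self.start > self.end:
            raise ValueError(f"source start {self.start} after end {self.end}")

    def active(self, when: MonthIndex) -> bool:
        return self.start <= when <= self.end


@dataclass(frozen=True)
class WellRecord:
    """A supply well: location, screened layers, capacity, service history.

    ``service_intervals`` are inclusive (start, end) month pairs, ordered
    and non-overlapping.  Months are atomic: a well entering service
    mid-month counts as in service for the whole month.
    """

    id: str
    row: int
    col: int
    screened_layers: tuple[int, ...]
    capacity: float
    service_intervals: tuple[tuple[MonthIndex, MonthIndex], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "screened_layers", tuple(self.screened_layers))
        object.__setattr__(self, "service_intervals", tuple(tuple(iv) for iv in self.service_intervals))
        if not self.screened_layers:
            raise ValueError(f"well {self.id}: no screened layers")
        if self.capacity <= 0:
            raise ValueError(f"well {self.id}: capacity must be > 0")
        for start, end in self.service_intervals:
            if start > end:
                raise ValueError(f"well {self.id}: interval {start}..{end} reversed")
        for (_, e1), (s2, _) in zip(self.service_intervals, self.service_intervals[1:]):
            if s2 <= e1:
                raise ValueError(f"well {self.id}: service intervals overlap or out of order")

    def in_service(self, when: MonthIndex) -> bool:
        return any(s <= when <= e for s, e in self.service_intervals)


@dataclass
class SiteModel:
    """Complete physical model of a synthetic study area."""

    grid: GridSpec
    layers: tuple[LayerProperties, ...]
    constant_head_cells: tuple[tuple[int, int, int, float], ...]
    stream_cells: tuple[tuple[int, int, int, float, float], ...]
    recharge: np.ndarray  # m/day per (row, col)
    sources: tuple[SourceTerm, ...]
    wells: tuple[WellRecord, ...]
    clock_start: MonthIndex
    clock_end: MonthIndex

    def __post_init__(self) -> None:
        self.layers = tuple(self.layers)
        self.constant_head_cells = tuple(tuple(c) for c in self.constant_head_cells)
        self.stream_cells = tuple(tuple(c) for c in self.stream_cells)
        self.sources = tuple(self.sources)
        self.wells = tuple(self.wells)
        self.recharge = np.asarray(self.recharge, dtype=float)
        g = self.grid
        if len(self.layers) != g.nlay:
            raise ValueError("need one LayerProperties per layer")
        if self.recharge.shape != (g.nrow, g.ncol):
            raise ValueError(f"recharge shape {self.recharge.shape} != {(g.nrow, g.ncol)}")
        for (l, r, c, _h) in self.constant_head_cells:
            if not g.contains(l, r, c):
                raise ValueError(f"constant-head cell {(l, r, c)} outside grid")
        for (l, r, c, _s, cond) in self.stream_cells:
            if not g.contains(l, r, c):
                raise ValueError(f"stream cell {(l, r, c)} outside grid")
            if cond <= 0:
                raise ValueError(f"stream cell {(l, r, c)}: conductance must be > 0")
        for src in self.sources:
            for cell in src.cells:
                if not g.contains(*cell):
                    raise ValueError(f"source cell {cell} outside grid")
        aquifers = set(g.aquifer_layers())
        for w in self.wells:
            if not (0 <= w.row < g.nrow and 0 <= w.col < g.ncol):
                raise ValueError(f"well {w.id} at ({w.row},{w.col}) outside grid")
            bad = [l for l in w.screened_layers if l not in aquifers]
            if bad:
                raise ValueError(f"well {w.id}: screened layers {bad} are not aquifer layers")
        if self.clock_end - self.clock_start + 1 < 12:
            raise ValueError("site clock must span at least 12 months")
        if not self.constant_head_cells and not self.stream_cells:
            raise ValueError("site needs at least one head-controlling boundary")

    @property
    def clock(self) -> list[MonthIndex]:
        return month_range(self.clock_start, self.clock_end)

    @property
    def n_months(self) -> int:
        return self.clock_end - self.clock_start + 1

    def well(self, well_id: str) -> WellRecord:
        for w in self.wells:
            if w.id == well_id:
                return w
        raise KeyError(f"no well {well_id!r}")

    def transmissivity(self, layer: int) -> float:
        """Layer transmissivity kh * thickness, m²/day."""
        return self.layers[layer].kh * self.grid.layer_thickness[layer]

    def well_layer_weights(self, well: WellRecord) -> dict[int, float]:
        """Transmissivity share of each screened layer at the well cell.

        The same weights apportion pumping in the flow solver and average
        concentrations in well-series extraction, so flow and transport
        agree on what the well draws.
        """
        t = {l: self.transmissivity(l) for l in well.screened_layers}
        total = sum(t.values())
        return {l: v / total for l, v in t.items()}


@dataclass
class DemandSeries:
    """Monthly water demand of one treatment plant, m³/day."""

    series: "object"  # MonthlySeries; import cycle avoided at type level

    def __post_init__(self) -> None:
        vals = self.series.values
        if np.any(np.isnan(vals)):
            raise ValueError("demand must cover every month (no gaps)")
        if np.any(vals < 0):
            raise ValueError("demand must be >= 0")

    def at(self, when: MonthIndex) -> float:
        return self.series.value_at(when)
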