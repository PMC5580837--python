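"""YAML site-configuration reading and writing.

Schema (``schema: 1``)::

    schema: 1
    units: si | us          # unit system of the numbers in THIS file
    site:
      grid:
        nlay: 7
        nrow: 20
        ncol: 20
        dx: 90.0            # m (si) or ft (us)
        dy: 90.0
        layer_thickness: [8, 3, 10, 3, 15, 5, 20]
        layer_role: [aquifer, aquitard, aquifer, aquitard, aquifer, aquitard, aquifer]
      layers:               # one mapping per layer
        - {kh: 15.0, kv: 1.5, specific_storage: 1.0e-5, porosity: 0.2}
        - ...
      constant_head:        # list of {layer, row, col, head}
      streams:              # list of {layer, row, col, stage, conductance}
      recharge: 5.0e-4      # scalar or nrow x ncol nested list, m/day | ft/day
      sources:              # list of {cells: [[l,r,c],...], concentration, start, end}
      wells:                # list of {id, row, col, screened_layers, capacity, service}
      clock: {start: "1951-01", end: "1968-12"}
    run:                    # optional run settings
      demand: 5000.0        # scalar m³/day | Mgal/day, or {"YYYY-MM": value, ...}
      contaminants:         # list of ContaminantSpec mappings
      substeps_per_month: 2

Months are ISO ``YYYY-MM`` stamps.  Concentrations are μg/L in both unit
systems.  In ``us`` files, lengths and heads are ft, conductivities and
recharge ft/day, specific storage 1/ft, stream conductance ft²/day, well
capacity and demand Mgal/day; everything is converted to SI on load, so
the returned :class:`~aquarecon.model.SiteModel` is always in m / day /
m³/day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .model import (
    ContaminantSpec,
    DemandSeries,
    GridSpec,
    LayerProperties,
    SiteModel,
    SourceTerm,
    WellRecord,
)
from .timeline import MonthIndex, MonthlySeries

__all__ = ["ConfigError", "RunSettings", "load_config", "parse_config", "save_config", "site_to_doc"]

FT = 0.3048
MGD = 1e6 * 0.003785411784  # Mgal/day -> m³/day


class ConfigError(ValueError):
    """A schema or invariant violation in a site configuration."""


@dataclass
class RunSettings:
    """Pipeline settings that accompany a site description."""

    demand: DemandSeries | None = None
    contaminants: tuple[ContaminantSpec, ...] = ()
    substeps_per_month: int = 2
    extras: dict[str, Any] = field(default_factory=dict)


def _require(doc: dict, key: str, context: str) -> Any:
    if key not in doc:
        raise ConfigError(f"{context}: missing required field {key!r}")
    return doc[key]


def _month(stamp: Any, context: str) -> MonthIndex:
    try:
        return MonthIndex.parse(str(stamp))
    except Exception as exc:
        raise ConfigError(f"{context}: bad month stamp {stamp!r}: {exc}") from exc


class _Units:
    """Field-wise multipliers from the file's unit system to SI."""

    def __init__(self, system: str):
        if system not in ("si", "us"):
            raise ConfigError(f"units must be 'si' or 'us', got {system!r}")
        us = system == "us"
        self.length = FT if us else 1.0          # ft -> m
        self.conductivity = FT if us else 1.0    # ft/day -> m/day
        self.recharge = FT if us else 1.0
        self.inv_length = (1 / FT) if us else 1.0  # 1/ft -> 1/m
        self.area_rate = FT * FT if us else 1.0  # ft²/day -> m²/day
        self.flow = MGD if us else 1.0           # Mgal/day -> m³/day


def parse_config(doc: dict) -> tuple[SiteModel, RunSettings]:
    """Validate a parsed YAML document and build the SI-unit site model."""
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    if doc.get("schema") != 1:
        raise ConfigError(f"unsupported schema version {doc.get('schema')!r}; expected 1")
    u = _Units(doc.get("units", "si"))
    sdoc = _require(doc, "site", "config")

    gdoc = _require(sdoc, "grid", "site")
    try:
        grid = GridSpec(
            nlay=int(_require(gdoc, "nlay", "grid")),
            nrow=int(_require(gdoc, "nrow", "grid")),
            ncol=int(_require(gdoc, "ncol", "grid")),
            dx=float(_require(gdoc, "dx", "grid")) * u.length,
            dy=float(_require(gdoc, "dy", "grid")) * u.length,
            layer_thickness=tuple(t * u.length for t in _require(gdoc, "layer_thickness", "grid")),
            layer_role=tuple(_require(gdoc, "layer_role", "grid")),
        )
    except ValueError as exc:
        raise ConfigError(f"grid: {exc}") from exc

    layers = []
    for k, ldoc in enumerate(_require(sdoc, "layers", "site")):
        try:
            layers.append(
                LayerProperties(
                    kh=float(_require(ldoc, "kh", f"layer {k}")) * u.conductivity,
                    kv=float(_require(ldoc, "kv", f"layer {k}")) * u.conductivity,
                    specific_storage=float(_require(ldoc, "specific_storage", f"layer {k}")) * u.inv_length,
                    porosity=float(_require(ldoc, "porosity", f"layer {k}")),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"layer {k}: {exc}") from exc

    chd = tuple(
        (int(d["layer"]), int(d["row"]), int(d["col"]), float(d["head"]) * u.length)
        for d in sdoc.get("constant_head", [])
    )
    streams = tuple(
        (
            int(d["layer"]),
            int(d["row"]),
            int(d["col"]),
            float(d["stage"]) * u.length,
            float(d["conductance"]) * u.area_rate,
        )
        for d in sdoc.get("streams", [])
    )

    rdoc = sdoc.get("recharge", 0.0)
    if np.isscalar(rdoc):
        recharge = np.full((grid.nrow, grid.ncol), float(rdoc) * u.recharge)
    else:
        recharge = np.asarray(rdoc, dtype=float) * u.recharge

    sources = []
    for i, d in enumerate(sdoc.get("sources", [])):
        try:
            sources.append(
                SourceTerm(
                    cells=tuple(tuple(int(x) for x in c) for c in _require(d, "cells", f"source {i}")),
                    concentration=float(_require(d, "concentration", f"source {i}")),
                    start=_month(_require(d, "start", f"source {i}"), f"source {i}"),
                    end=_month(_require(d, "end", f"source {i}"), f"source {i}"),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"source {i}: {exc}") from exc

    wells = []
    for d in sdoc.get("wells", []):
        wid = str(_require(d, "id", "well"))
        try:
            wells.append(
                WellRecord(
                    id=wid,
                    row=int(_require(d, "row", f"well {wid}")),
                    col=int(_require(d, "col", f"well {wid}")),
                    screened_layers=tuple(int(l) for l in _require(d, "screened_layers", f"well {wid}")),
                    capacity=float(_require(d, "capacity", f"well {wid}")) * u.flow,
                    service_intervals=tuple(
                        (_month(s, f"well {wid}"), _month(e, f"well {wid}"))
                        for s, e in d.get("service", [])
                    ),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"well {wid}: {exc}") from exc

    cdoc = _require(sdoc, "clock", "site")
    try:
        site = SiteModel(
            grid=grid,
            layers=tuple(layers),
            constant_head_cells=chd,
            stream_cells=streams,
            recharge=recharge,
            sources=tuple(sources),
            wells=tuple(wells),
            clock_start=_month(_require(cdoc, "start", "clock"), "clock"),
            clock_end=_month(_require(cdoc, "end", "clock"), "clock"),
        )
    except ValueError as exc:
        raise ConfigError(f"site: {exc}") from exc

    run = _parse_run(doc.get("run", {}) or {}, site, u)
    return site, run


def _parse_run(rdoc: dict, site: SiteModel, u: _Units) -> RunSettings:
    demand = None
    if "demand" in rdoc:
        d = rdoc["demand"]
        if np.isscalar(d):
            series = MonthlySeries.constant(site.clock_start, site.clock_end, float(d) * u.flow)
        else:
            series = MonthlySeries.from_items(
                (_month(k, "demand"), float(v) * u.flow) for k, v in d.items()
            )
        try:
            demand = DemandSeries(series)
        except ValueError as exc:
            raise ConfigError(f"demand: {exc}") from exc
    contaminants = []
    for d in rdoc.get("contaminants", []):
        try:
            contaminants.append(
                ContaminantSpec(
                    name=str(_require(d, "name", "contaminant")),
                    retardation=float(d.get("retardation", 1.0)),
                    decay_rate=float(d.get("decay_rate", 0.0)),
                    disp_long=float(d.get("disp_long", 10.0)) * u.length,
                    disp_transv=float(d.get("disp_transv", 1.0)) * u.length,
                    mol_diffusion=float(d.get("mol_diffusion", 0.0)) * u.length**2,
                    mcl=float(d.get("mcl", 5.0)),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"contaminant: {exc}") from exc
    extras = {
        k: v
        for k, v in rdoc.items()
        if k not in ("demand", "contaminants", "substeps_per_month")
    }
    return RunSettings(
        demand=demand,
        contaminants=tuple(contaminants),
        substeps_per_month=int(rdoc.get("substeps_per_month", 2)),
        extras=extras,
    )


def load_config(path: str | Path) -> tuple[SiteModel, RunSettings]:
    """Read and validate a YAML site configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)


def site_to_doc(site: SiteModel, run: RunSettings | None = None) -> dict:
    """Serialize a site (and optional run settings) to a schema-1 SI document."""
    g = site.grid
    doc: dict[str, Any] = {
        "schema": 1,
        "units": "si",
        "site": {
            "grid": {
                "nlay": g.nlay,
                "nrow": g.nrow,
                "ncol": g.ncol,
                "dx": g.dx,
                "dy": g.dy,
                "layer_thickness": list(g.layer_thickness),
                "layer_role": list(g.layer_role),
            },
            "layers": [
                {
                    "kh": l.kh,
                    "kv": l.kv,
                    "specific_storage": l.specific_storage,
                    "porosity": l.porosity,
                }
                for l in site.layers
            ],
            "constant_head": [
                {"layer": l, "row": r, "col": c, "head": h}
                for (l, r, c, h) in site.constant_head_cells
            ],
            "streams": [
                {"layer": l, "row": r, "col": c, "stage": s, "conductance": cond}
                for (l, r, c, s, cond) in site.stream_cells
            ],
            "recharge": site.recharge.tolist(),
            "sources": [
                {
                    "cells": [list(c) for c in s.cells],
                    "concentration": s.concentration,
                    "start": str(s.start),
                    "end": str(s.end),
                }
                for s in site.sources
            ],
            "wells": [
                {
                    "id": w.id,
                    "row": w.row,
                    "col": w.col,
                    "screened_layers": list(w.screened_layers),
                    "capacity": w.capacity,
                    "service": [[str(s), str(e)] for s, e in w.service_intervals],
                }
                for w in site.wells
            ],
            "clock": {"start": str(site.clock_start), "end": str(site.clock_end)},
        },
    }
    if run is not None:
        rdoc: dict[str, Any] = {"substeps_per_month": run.substeps_per_month}
        if run.demand is not None:
            rdoc["demand"] = {str(m): float(v) for m, v in run.demand.series.items()}
        if run.contaminants:
            rdoc["contaminants"] = [
                {
                    "name": c.name,
                    "retardation": c.retardation,
                    "decay_rate": c.decay_rate,
                    "disp_long": c.disp_long,
                    "disp_transv": c.disp_transv,
                    "mol_diffusion": c.mol_diffusion,
                    "mcl": c.mcl,
                }
                for c in run.contaminants
            ]
        rdoc.update(run.extras)
        doc["run"] = rdoc
    return doc


def save_config(site: SiteModel, path: str | Path, run: RunSettings | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(site_to_doc(site, run), fh, sort_keys=False)
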