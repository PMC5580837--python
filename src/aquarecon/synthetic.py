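"""Seeded generator of synthetic study areas and observations.

No real site data ship with the package; every downstream stage is
exercised on synthetic sites that reproduce the *structure* of the study
area — a 7-layer aquifer/aquitard stack, constant-concentration sources
switched on in a January early in the clock, supply wells with
documented in/out-of-service months (including a late-starting well and
a disjoint replacement pair), a head boundary on one side and a bending
stream on the other so plumes curve, and sparse noisy observations.
Geometry, parameter values and dates are invented; only the structure is
faithful.

Randomness: one global seed fans out to per-component substreams via
``np.random.default_rng([seed, component_id, ...])``, so adding a
component never perturbs the draws of another.

Templates
---------
``industrial-area``
    Multiple sources up-gradient of a 4-well field with a replacement
    pair (disjoint service windows).
``landfill``
    A single source area and exactly one well that starts pumping years
    after the source switches on and is removed before the clock ends.
``two-system``
    The industrial-area site plus a second, uncontaminated receiving
    system: a cutover month, a seasonal interconnection history and a
    small distribution network with near/mid/far service areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunSettings, parse_config
from .markov import DOCUMENTED_OFF, DOCUMENTED_ON, UNKNOWN, InterconnectionRecord
from .model import SiteModel
from .network import Junction, Pipe, PipeNetwork, Pump, Reservoir, Valve
from .pipeline import PipelineResult, run_wtp_pipeline
from .timeline import MonthIndex, MonthlySeries

__all__ = [
    "TEMPLATES",
    "ObservationSet",
    "ScenarioTruth",
    "InterconnectionHistory",
    "generate_config",
    "generate_site",
    "make_truth",
    "sample_observations",
    "generate_interconnection_history",
    "two_system_network",
]

TEMPLATES = ("industrial-area", "landfill", "two-system")

# substream ids for the seed-splitting rule
_SUB_LAYERS, _SUB_BOUNDARY, _SUB_SOURCES, _SUB_WELLS, _SUB_DEMAND = 0, 1, 2, 3, 4
_SUB_OBS_HEAD, _SUB_OBS_CONC = 10, 11
_SUB_IC_TRUTH, _SUB_IC_MASK, _SUB_IC_HOURS = 20, 21, 22


@dataclass
class ObservationSet:
    """Sparse synthetic observations of heads and well concentrations."""

    head_obs: list[tuple[int, int, int, MonthIndex, float]]
    conc_obs: list[tuple[str, MonthIndex, float]]
    noise_sd: dict[str, float]

    def __post_init__(self) -> None:
        if any(c < 0 for *_, c in self.conc_obs):
            raise ValueError("concentration observations must be >= 0")


@dataclass
class ScenarioTruth:
    """A synthetic site plus the fine-resolution truth it generates.

    Truths come from the package's own forward operators run at finer
    time resolution than the default pipeline, so parameter-recovery and
    self-consistency tests have an internal reference.
    """

    template: str
    scale: str
    seed: int
    doc: dict
    site: SiteModel
    run: RunSettings
    result: PipelineResult
    true_params: dict[str, float]
    true_wtp_series: dict[str, MonthlySeries]
    true_area_series: dict[str, MonthlySeries] = field(default_factory=dict)


def _scale_params(template: str, scale: str) -> dict:
    if scale not in ("small", "medium"):
        raise ValueError(f"unknown scale {scale!r}; use 'small' or 'medium'")
    small = scale == "small"
    return {
        "nrowcol": (16 if template == "landfill" else 20) if small else 30,
        "years": 15 if small else 25,
        "start_year": 1950,
    }


def generate_config(template: str, scale: str = "small", seed: int = 0) -> dict:
    """Full configuration document (site + run settings) for a template.

    Deterministic for fixed (template, scale, seed).
    """
    if template not in TEMPLATES:
        raise ValueError(f"unknown template {template!r}; available: {list(TEMPLATES)}")
    p = _scale_params(template, scale)
    n = p["nrowcol"]
    y0 = p["start_year"]
    clock_start = MonthIndex(y0, 1)
    clock_end = MonthIndex(y0 + p["years"] - 1, 12)

    rng_layers = np.random.default_rng([seed, _SUB_LAYERS])
    roles = ["aquifer", "aquitard", "aquifer", "aquitard", "aquifer", "aquitard", "aquifer"]
    thickness = [8.0, 3.0, 10.0, 3.0, 15.0, 5.0, 20.0]
    layers = []
    for role in roles:
        if role == "aquifer":
            kh = float(rng_layers.uniform(10.0, 20.0))
            layers.append(
                {"kh": kh, "kv": kh / 10, "specific_storage": 1.0e-5, "porosity": 0.2}
            )
        else:
            kv = float(rng_layers.uniform(5.0e-4, 5.0e-3))
            layers.append(
                {"kh": 0.05, "kv": kv, "specific_storage": 5.0e-5, "porosity": 0.35}
            )

    rng_b = np.random.default_rng([seed, _SUB_BOUNDARY])
    upland_head = float(rng_b.uniform(11.0, 14.0))
    stage = float(rng_b.uniform(2.5, 3.5))
    constant_head = [
        {"layer": l, "row": r, "col": 0, "head": upland_head}
        for l in (0, 2, 4, 6)
        for r in range(n)
    ]
    # stream along the east edge with a bend along the south edge: plumes
    # drifting east curve toward the bend
    streams = [
        {"layer": 0, "row": r, "col": n - 1, "stage": stage, "conductance": 500.0}
        for r in range(n)
    ] + [
        {"layer": 0, "row": n - 1, "col": c, "stage": stage, "conductance": 500.0}
        for c in range(n // 2, n - 1)
    ]
    recharge = 4.0e-4

    rng_s = np.random.default_rng([seed, _SUB_SOURCES])
    src_start = MonthIndex(y0 + 1, 1)  # sources switch on in a January
    if template == "landfill":
        r0 = n // 2 + int(rng_s.integers(-1, 2))
        sources = [
            {
                "cells": [[l, r0, 3] for l in range(5)] + [[l, r0 + 1, 3] for l in range(5)],
                "concentration": float(rng_s.uniform(4000, 9000)),
                "start": str(src_start),
                "end": str(clock_end),
            }
        ]
    else:
        sources = []
        for i in range(3):
            r = n // 3 + 2 * i + int(rng_s.integers(-1, 2))
            c = 3 + int(rng_s.integers(0, 3))
            sources.append(
                {
                    "cells": [[0, r, c], [0, r, c + 1]],
                    "concentration": float(rng_s.uniform(2000, 8000)),
                    "start": str(src_start),
                    "end": str(clock_end),
                }
            )

    rng_w = np.random.default_rng([seed, _SUB_WELLS])
    mid = n // 2
    if template == "landfill":
        # exactly one well, starting years after the source switches on
        well_start = MonthIndex(y0 + 8, 7)
        well_end = clock_end.plus(-12)
        wells = [
            {
                "id": "LF-1",
                "row": mid,
                "col": mid + 3,
                "screened_layers": [4],
                "capacity": float(rng_w.uniform(800, 1200)),
                "service": [[str(well_start), str(well_end)]],
            }
        ]
    else:
        col_w = int(n * 0.65)
        repl_end = MonthIndex(y0 + 10, 12)
        wells = [
            {
                "id": "W-601",
                "row": mid - 3 + int(rng_w.integers(-1, 2)),
                "col": col_w,
                "screened_layers": [2, 4],
                "capacity": float(rng_w.uniform(750, 1050)),
                "service": [[str(MonthIndex(y0, 7)), str(repl_end)]],
            },
            {
                # replacement pair: disjoint service windows with W-601
                "id": "W-660",
                "row": mid - 3,
                "col": col_w + 1,
                "screened_layers": [2, 4],
                "capacity": float(rng_w.uniform(750, 1050)),
                "service": [[str(repl_end.plus(1)), str(clock_end)]],
            },
            {
                "id": "W-602",
                "row": mid + int(rng_w.integers(0, 2)),
                "col": col_w + 2,
                "screened_layers": [2, 4],
                "capacity": float(rng_w.uniform(950, 1250)),
                "service": [[str(MonthIndex(y0 + 1, 1)), str(clock_end)]],
            },
            {
                "id": "W-608",
                "row": mid - 6,
                "col": col_w + 3,
                "screened_layers": [4],
                "capacity": float(rng_w.uniform(550, 850)),
                "service": [[str(MonthIndex(y0 + 2, 1)), str(clock_end)]],
            },
        ]

    # demand: seasonal variation around half the weakest in-service capacity
    rng_d = np.random.default_rng([seed, _SUB_DEMAND])
    months = []
    m = clock_start
    while m <= clock_end:
        months.append(m)
        m = m.plus(1)

    def cap_in_service(when: MonthIndex) -> float:
        tot = 0.0
        for w in wells:
            for s, e in w["service"]:
                if MonthIndex.parse(s) <= when <= MonthIndex.parse(e):
                    tot += w["capacity"]
        return tot

    caps = [cap_in_service(m) for m in months]
    active_caps = [c for c in caps if c > 0]
    base = 0.5 * min(active_caps)
    amp = float(rng_d.uniform(0.05, 0.10))
    demand = {}
    for i, m in enumerate(months):
        if caps[i] <= 0:
            demand[str(m)] = 0.0
        else:
            demand[str(m)] = round(base * (1 + amp * math.sin(2 * math.pi * (m.month - 3) / 12)), 3)

    contaminants = [
        {
            "name": "TCE",
            "retardation": 2.0,
            "decay_rate": 1.0e-4,
            "disp_long": 30.0,
            "disp_transv": 3.0,
            "mol_diffusion": 0.0,
            "mcl": 5.0,
        }
    ]

    doc = {
        "schema": 1,
        "units": "si",
        "site": {
            "grid": {
                "nlay": 7,
                "nrow": n,
                "ncol": n,
                "dx": 90.0,
                "dy": 90.0,
                "layer_thickness": thickness,
                "layer_role": roles,
            },
            "layers": layers,
            "constant_head": constant_head,
            "streams": streams,
            "recharge": recharge,
            "sources": sources,
            "wells": wells,
            "clock": {"start": str(clock_start), "end": str(clock_end)},
        },
        "run": {
            "demand": demand,
            "contaminants": contaminants,
            "substeps_per_month": 2,
        },
    }
    if template == "two-system":
        cut = MonthIndex(y0 + 8, 6)
        doc["run"]["two_system"] = {
            # the receiving system's own clean WTP comes on line at cutover;
            # before it, the contaminated WTP serves the receiving areas too
            "cutover": str(cut),
            "years": [cut.year, clock_end.year],
            "months_active": [4, 5, 6, 7, 8],
            "event_hours": 120.0,
            "p_on": 0.45,
            "persistence": 0.6,
            "frac_documented": 0.5,
            "n_sims": 500,
            "network_scale": "small",
        }
    return doc


def generate_site(template: str, scale: str = "small", seed: int = 0) -> SiteModel:
    """Validated :class:`SiteModel` for a template (SI units)."""
    site, _run = parse_config(generate_config(template, scale, seed))
    return site


def make_truth(
    template: str, scale: str = "small", seed: int = 0, substeps_per_month: int = 4
) -> ScenarioTruth:
    """Generate a site and compute its fine-resolution truth series."""
    doc = generate_config(template, scale, seed)
    site, run = parse_config(doc)
    result = run_wtp_pipeline(site, run, substeps_per_month=substeps_per_month)
    true_params = {
        f"site.sources.{i}.concentration": s["concentration"]
        for i, s in enumerate(doc["site"]["sources"])
    }
    for k, layer in enumerate(doc["site"]["layers"]):
        true_params[f"site.layers.{k}.kh"] = layer["kh"]
    wtp = {name: w.series for name, w in result.wtp.items()}
    areas = {"service-area": wtp[run.contaminants[0].name]}
    return ScenarioTruth(
        template=template,
        scale=scale,
        seed=seed,
        doc=doc,
        site=site,
        run=run,
        result=result,
        true_params=true_params,
        true_wtp_series=wtp,
        true_area_series=areas,
    )


def sample_observations(
    truth: ScenarioTruth,
    n_head: int = 50,
    samples_per_well: tuple[int, int] = (1, 5),
    noise_sd: dict[str, float] | None = None,
    seed: int = 0,
    conc_noise: str = "truncnorm",
) -> ObservationSet:
    """Draw sparse noisy observations from a scenario's truth fields.

    Head observations are Gaussian around simulated heads at random
    aquifer cells/months; concentration observations are per-well, 1–5
    samples each by default, with centered Gaussian noise truncated at 0
    (or multiplicative log-normal with ``conc_noise="lognormal"``, since
    water-quality data are non-negative and right-skewed).
    """
    noise_sd = dict(noise_sd or {"head": 0.3, "conc": 25.0})
    if any(v < 0 for v in noise_sd.values()):
        raise ValueError("noise_sd must be >= 0")
    site = truth.site
    heads = truth.result.heads
    months = site.clock
    aq = site.grid.aquifer_layers()
    cells = [(l, r, c) for l in aq for r in range(site.grid.nrow) for c in range(site.grid.ncol)]
    n_avail = len(cells) * len(months)
    if n_head > n_avail:
        raise ValueError(f"requested {n_head} head observations, only {n_avail} cell-months")
    rng_h = np.random.default_rng([truth.seed, _SUB_OBS_HEAD, seed])
    picks = rng_h.choice(n_avail, size=n_head, replace=False)
    head_obs = []
    for p in picks:
        ci, mi = divmod(int(p), len(months))
        l, r, c = cells[ci]
        val = heads.heads[mi, l, r, c] + rng_h.normal(0.0, noise_sd["head"]) if noise_sd["head"] > 0 else heads.heads[mi, l, r, c]
        head_obs.append((l, r, c, months[mi], float(val)))

    lo, hi = samples_per_well
    if not 0 <= lo <= hi:
        raise ValueError("samples_per_well range must satisfy 0 <= lo <= hi")
    rng_c = np.random.default_rng([truth.seed, _SUB_OBS_CONC, seed])
    conc_obs = []
    name = truth.run.contaminants[0].name
    for wid, series in truth.result.well_series[name].items():
        avail = [m for m in series.months() if not series.is_missing(m)]
        if not avail:
            continue
        k = min(int(rng_c.integers(lo, hi + 1)), len(avail))
        for i in sorted(rng_c.choice(len(avail), size=k, replace=False)):
            m = avail[int(i)]
            v = series.value_at(m)
            if noise_sd["conc"] > 0:
                if conc_noise == "lognormal":
                    v = v * math.exp(rng_c.normal(0.0, noise_sd["conc"] / max(v, 1e-9)))
                else:
                    v = max(0.0, v + rng_c.normal(0.0, noise_sd["conc"]))
            conc_obs.append((wid, m, float(v)))
    return ObservationSet(head_obs=head_obs, conc_obs=conc_obs, noise_sd=noise_sd)


@dataclass
class InterconnectionHistory:
    """Masked records plus the retained truth sequence."""

    records: list[InterconnectionRecord]  # partially documented
    truth: list[InterconnectionRecord]  # fully documented

    def truth_on_fraction(self) -> float:
        return sum(1 for r in self.truth if r.status == DOCUMENTED_ON) / len(self.truth)


def generate_interconnection_history(
    years: range,
    months_active: list[int],
    p_on: float = 0.45,
    persistence: float = 0.6,
    frac_documented: float = 0.5,
    seed: int = 0,
) -> InterconnectionHistory:
    """Simulate a seasonal transfer history, then hide part of it.

    The truth is a two-state chain with stationary on-probability
    ``p_on`` and autocorrelation ``persistence``:

        P(on | on)  = persistence + (1 - persistence) * p_on
        P(on | off) = (1 - persistence) * p_on

    Each season starts fresh from Bernoulli(``p_on``).  Masking labels
    each month documented with probability ``frac_documented``,
    independently; it never alters the truth sequence.
    """
    if not len(years) or not months_active:
        raise ValueError("years and months_active must be non-empty")
    for nm, v in (("p_on", p_on), ("persistence", persistence), ("frac_documented", frac_documented)):
        if not 0 <= v <= 1:
            raise ValueError(f"{nm} must be in [0,1]")
    p_on_on = persistence + (1 - persistence) * p_on
    p_on_off = (1 - persistence) * p_on
    rng_t = np.random.default_rng([seed, _SUB_IC_TRUTH])
    rng_m = np.random.default_rng([seed, _SUB_IC_MASK])
    rng_h = np.random.default_rng([seed, _SUB_IC_HOURS])
    truth: list[InterconnectionRecord] = []
    records: list[InterconnectionRecord] = []
    for y in years:
        state = rng_t.random() < p_on
        for i, mo in enumerate(sorted(months_active)):
            if i > 0:
                p = p_on_on if state else p_on_off
                state = rng_t.random() < p
            m = MonthIndex(y, mo)
            hours = float(rng_h.uniform(24, min(300, m.hours))) if state else None
            status = DOCUMENTED_ON if state else DOCUMENTED_OFF
            truth.append(InterconnectionRecord(m, status, hours))
            if rng_m.random() < frac_documented:
                records.append(InterconnectionRecord(m, status, hours))
            else:
                records.append(InterconnectionRecord(m, UNKNOWN))
    return InterconnectionHistory(records=records, truth=truth)


def two_system_network(scale: str = "small", seed: int = 0) -> PipeNetwork:
    """Small receiving-system network: boundary, pump + bypass valve, and
    near/mid/far service areas at increasing travel time from the boundary."""
    rng = np.random.default_rng([seed, 30])
    pattern = tuple(
        round(1.0 + 0.3 * math.sin(2 * math.pi * (h - 7) / 24), 3) for h in range(24)
    )
    d_near = float(rng.uniform(700, 900))
    d_mid = float(rng.uniform(1000, 1400))
    d_far = float(rng.uniform(500, 700))
    junctions = {
        "J0": Junction("J0", elevation=8.0, base_demand=0.0, pattern=(1.0,), area="trunk"),
        "J1": Junction("J1", 9.0, d_near, pattern, "near"),
        "J2": Junction("J2", 10.0, d_mid, pattern, "mid"),
        "J3": Junction("J3", 11.0, d_far, pattern, "far"),
        "J4": Junction("J4", 9.5, d_near / 2, pattern, "near"),
    }
    reservoir = Reservoir("boundary", head=30.0)
    pipes = [
        Pipe("P-trunk", "J0", "J1", length=2500.0, diameter=0.30),
        Pipe("P-loop-a", "J1", "J4", length=1800.0, diameter=0.20),
        Pipe("P-loop-b", "J4", "J2", length=2200.0, diameter=0.20),
        Pipe("P-main", "J1", "J2", length=4000.0, diameter=0.25),
        Pipe("P-far", "J2", "J3", length=6000.0, diameter=0.15),
    ]
    pumps = [Pump("booster", "boundary", "J0", shutoff_head=40.0, design_flow=4000.0, design_head=20.0)]
    valves = [Valve("bypass", "boundary", "J0", open=False)]
    return PipeNetwork(junctions, reservoir, pipes, pumps, valves)
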