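"""Composition of the reconstruction stages.

The canonical chain is: reconstruct per-well pumping schedules from WTP
demand → steady predevelopment flow → transient flow under the schedule
→ cell-by-cell flow fields → contaminant transport → flow-weighted well
concentration series → mass-balance mixing at the WTP.  This module
wires those stages together once so the analysis scripts, the
uncertainty machinery and the end-to-end reconstruction all run the
exact same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunSettings, parse_config
from .flow import HeadField, flow_fields_for_schedule, solve_steady_flow, solve_transient_flow
from .mixing import WTPSeries, mix_at_wtp
from .model import SiteModel
from .timeline import MonthlySeries
from .transport import ConcField, extract_well_series, solve_transport
from .wells import PumpingSchedule, reconstruct_schedule

__all__ = ["PipelineResult", "run_wtp_pipeline", "wtp_series_from_doc"]


@dataclass
class PipelineResult:
    """Everything the well-to-WTP chain produces for one site."""

    site: SiteModel
    schedule: PumpingSchedule
    steady: HeadField
    heads: HeadField
    conc_fields: dict[str, ConcField]
    well_series: dict[str, dict[str, MonthlySeries]]  # contaminant -> well -> series
    wtp: dict[str, WTPSeries]  # contaminant -> mixed series


def run_wtp_pipeline(
    site: SiteModel, run: RunSettings, substeps_per_month: int | None = None
) -> PipelineResult:
    """Run schedule → flow → transport → well series → WTP mixing."""
    if run.demand is None:
        raise ValueError("run settings have no demand series")
    if not run.contaminants:
        raise ValueError("run settings list no contaminants")
    substeps = substeps_per_month if substeps_per_month is not None else run.substeps_per_month
    schedule = reconstruct_schedule(list(site.wells), run.demand)
    steady = solve_steady_flow(site)
    heads = solve_transient_flow(site, schedule, steady, substeps_per_month=substeps)
    flows = flow_fields_for_schedule(site, heads, schedule, steady)
    conc_fields: dict[str, ConcField] = {}
    well_series: dict[str, dict[str, MonthlySeries]] = {}
    wtp: dict[str, WTPSeries] = {}
    for spec in run.contaminants:
        conc = solve_transport(site, flows, spec, substeps_per_month=substeps)
        series = extract_well_series(conc, site, schedule)
        conc_fields[spec.name] = conc
        well_series[spec.name] = series
        wtp[spec.name] = mix_at_wtp(schedule, series)
    return PipelineResult(
        site=site,
        schedule=schedule,
        steady=steady,
        heads=heads,
        conc_fields=conc_fields,
        well_series=well_series,
        wtp=wtp,
    )


def wtp_series_from_doc(doc: dict, contaminant: str | None = None) -> MonthlySeries:
    """Config document → mixed WTP series for one contaminant.

    This is the pipeline signature the uncertainty tooling sweeps: any
    numeric field of the document can be perturbed before the call.
    """
    site, run = parse_config(doc)
    result = run_wtp_pipeline(site, run)
    name = contaminant if contaminant is not None else run.contaminants[0].name
    return result.wtp[name].series
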