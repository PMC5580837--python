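"""Shared fixtures: small deterministic sites built programmatically."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from aquarecon.model import (
    GridSpec,
    LayerProperties,
    SiteModel,
    WellRecord,
)
from aquarecon.timeline import MonthIndex


def strip_site(
    ncol: int = 50,
    nrow: int = 1,
    dx: float = 10.0,
    kh: float = 10.0,
    thickness: float = 10.0,
    head_left: float = 10.0,
    head_right: float = 0.0,
    recharge: float = 0.0,
    porosity: float = 0.25,
    wells: tuple[WellRecord, ...] = (),
    months: int = 12,
) -> SiteModel:
    """Single-layer strip with constant heads on both ends: the workhorse
    for closed-form flow and transport comparisons."""
    grid = GridSpec(
        nlay=1,
        nrow=nrow,
        ncol=ncol,
        dx=dx,
        dy=dx,
        layer_thickness=(thickness,),
        layer_role=("aquifer",),
    )
    chd = [(0, r, 0, head_left) for r in range(nrow)] + [
        (0, r, ncol - 1, head_right) for r in range(nrow)
    ]
    return SiteModel(
        grid=grid,
        layers=(LayerProperties(kh=kh, kv=kh / 10, specific_storage=1e-5, porosity=porosity),),
        constant_head_cells=tuple(chd),
        stream_cells=(),
        recharge=np.full((nrow, ncol), recharge),
        sources=(),
        wells=wells,
        clock_start=MonthIndex(1960, 1),
        clock_end=MonthIndex(1960, 1).plus(months - 1),
    )


def box_site(
    n: int = 21,
    dx: float = 50.0,
    kh: float = 5.0,
    thickness: float = 10.0,
    specific_storage: float = 1e-4,
    boundary_head: float = 50.0,
    wells: tuple[WellRecord, ...] = (),
    months: int = 12,
) -> SiteModel:
    """Square single-layer box with constant head all around the rim."""
    grid = GridSpec(
        nlay=1, nrow=n, ncol=n, dx=dx, dy=dx, layer_thickness=(thickness,), layer_role=("aquifer",)
    )
    chd = []
    for r in range(n):
        for c in range(n):
            if r in (0, n - 1) or c in (0, n - 1):
                chd.append((0, r, c, boundary_head))
    return SiteModel(
        grid=grid,
        layers=(
            LayerProperties(
                kh=kh, kv=kh / 10, specific_storage=specific_storage, porosity=0.25
            ),
        ),
        constant_head_cells=tuple(chd),
        stream_cells=(),
        recharge=np.zeros((n, n)),
        sources=(),
        wells=wells,
        clock_start=MonthIndex(1970, 1),
        clock_end=MonthIndex(1970, 1).plus(months - 1),
    )


@pytest.fixture(scope="session")
def industrial_truth():
    """Fine-resolution truth for the industrial-area template (computed once)."""
    from aquarecon.synthetic import make_truth

    return make_truth("industrial-area", "small", seed=11, substeps_per_month=4)
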