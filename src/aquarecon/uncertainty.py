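"""One-at-a-time sensitivity and Monte Carlo / LHS uncertainty propagation.

A *pipeline* here is any deterministic callable mapping a nested site
configuration document (the parsed YAML dict) to a
:class:`~aquarecon.timeline.MonthlySeries`.  Parameters address numeric
fields of that document by dotted path (``site.sources.0.concentration``),
so any field is sweepable without code changes.

Latin hypercube sampling stratifies every parameter into *n*
equal-probability strata with exactly one draw each (scipy's
LatinHypercube engine), then maps the unit hypercube through each
parameter's inverse CDF.  Realization failures (e.g. a capacity
shortfall under an extreme demand draw) are recorded, not dropped
silently — dropped tails would bias the percentile bands.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .timeline import MonthlySeries

__all__ = [
    "ParameterSpec",
    "UncertaintyResult",
    "lhs_sample",
    "oat_sweep",
    "propagate",
    "get_path",
    "set_path",
    "ParameterPathError",
]

PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


class ParameterPathError(KeyError):
    """A dotted parameter path does not resolve in the document."""


def _walk(doc, path: str):
    node = doc
    tokens = path.split(".")
    for tok in tokens[:-1]:
        try:
            node = node[int(tok)] if isinstance(node, list) else node[tok]
        except (KeyError, IndexError, TypeError) as exc:
            raise ParameterPathError(f"path {path!r}: cannot descend at {tok!r}") from exc
    return node, tokens[-1]


def get_path(doc, path: str) -> float:
    node, last = _walk(doc, path)
    try:
        return node[int(last)] if isinstance(node, list) else node[last]
    except (KeyError, IndexError, TypeError) as exc:
        raise ParameterPathError(f"path {path!r} not found") from exc


def set_path(doc, path: str, value: float) -> None:
    node, last = _walk(doc, path)
    key = int(last) if isinstance(node, list) else last
    try:
        node[key]
    except (KeyError, IndexError, TypeError) as exc:
        raise ParameterPathError(f"path {path!r} not found") from exc
    node[key] = value


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain input: where it lives and how it is distributed.

    ``bounds = (lo, hi)`` are finite and truncate every distribution.
    ``params``: normal → mean, sd; log-normal → median, gsd (geometric
    standard deviation); triangular → mode; uniform families need none.
    """

    name: str
    distribution: str
    bounds: tuple[float, float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"{self.name}: bounds must be finite with lo < hi")
        if self.distribution not in ("uniform", "log-uniform", "normal", "log-normal", "triangular"):
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")
        if self.distribution in ("log-uniform", "log-normal") and lo <= 0:
            raise ValueError(f"{self.name}: log-family needs positive support")
        if self.distribution == "triangular":
            mode = self.params.get("mode", (lo + hi) / 2)
            if not lo <= mode <= hi:
                raise ValueError(f"{self.name}: triangular mode outside bounds")

    @property
    def is_log(self) -> bool:
        return self.distribution.startswith("log-")

    def _frozen(self):
        lo, hi = self.bounds
        if self.distribution == "uniform":
            return stats.uniform(lo, hi - lo)
        if self.distribution == "log-uniform":
            return stats.loguniform(lo, hi)
        if self.distribution == "normal":
            return stats.norm(self.params.get("mean", (lo + hi) / 2), self.params["sd"])
        if self.distribution == "log-normal":
            med = self.params.get("median", np.sqrt(lo * hi))
            return stats.lognorm(s=np.log(self.params["gsd"]), scale=med)
        mode = self.params.get("mode", (lo + hi) / 2)
        return stats.triang(c=(mode - lo) / (hi - lo), loc=lo, scale=hi - lo)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Map uniform [0,1) draws to values, truncated to the bounds."""
        d = self._frozen()
        lo, hi = self.bounds
        flo, fhi = d.cdf(lo), d.cdf(hi)
        return np.clip(d.ppf(flo + np.asarray(u) * (fhi - flo)), lo, hi)

    def sweep_values(self, n_points: int) -> np.ndarray:
        lo, hi = self.bounds
        if self.is_log:
            return np.geomspace(lo, hi, n_points)
        return np.linspace(lo, hi, n_points)


def lhs_sample(params: Sequence[ParameterSpec], n: int, seed: int) -> np.ndarray:
    """n × d Latin-hypercube parameter matrix, deterministic given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = qmc.LatinHypercube(d=len(params), seed=seed).random(n)
    return np.column_stack([p.ppf(u[:, j]) for j, p in enumerate(params)])


def oat_sweep(
    pipeline: Callable[[dict], MonthlySeries],
    base_doc: dict,
    param: ParameterSpec,
    n_points: int,
) -> pd.DataFrame:
    """Evaluate the pipeline across one parameter, all others at nominal.

    Returns one row per point: the parameter value, the output peak
    concentration and its month, and the output mean.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    get_path(base_doc, param.name)  # fail fast on a bad path
    rows = []
    for v in param.sweep_values(n_points):
        doc = copy.deepcopy(base_doc)
        set_path(doc, param.name, float(v))
        series = pipeline(doc)
        vals = series.values
        finite = vals[~np.isnan(vals)]
        peak_i = int(np.nanargmax(vals)) if finite.size else 0
        rows.append(
            {
                "value": float(v),
                "peak": float(vals[peak_i]) if finite.size else np.nan,
                "peak_month": str(series.start.plus(peak_i)),
                "mean": float(finite.mean()) if finite.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class UncertaintyResult:
    """Monthly percentile bands over the propagated realizations."""

    percentiles: pd.DataFrame  # index: ISO month, columns: "p2.5".."p97.5"
    n_realizations: int
    n_failures: int
    seed: int
    start: object  # MonthIndex of the first row

    def uncertainty_ratio(self) -> float:
        """97.5th / 2.5th percentile ratio at the month of peak median."""
        med = self.percentiles["p50"]
        peak = med.idxmax()
        lo = self.percentiles.loc[peak, "p2.5"]
        hi = self.percentiles.loc[peak, "p97.5"]
        return float(hi / lo) if lo > 0 else float("inf")

    def band_covers(self, truth: MonthlySeries) -> float:
        """Fraction of months whose true value lies inside the 2.5–97.5 band."""
        inside = total = 0
        for i, stamp in enumerate(self.percentiles.index):
            when = self.start.plus(i)
            if when < truth.start or when > truth.end or truth.is_missing(when):
                continue
            v = truth.value_at(when)
            row = self.percentiles.iloc[i]
            if np.isnan(row["p2.5"]):
                continue
            total += 1
            if row["p2.5"] <= v <= row["p97.5"]:
                inside += 1
        return inside / total if total else float("nan")


def propagate(
    pipeline: Callable[[dict], MonthlySeries],
    base_doc: dict,
    params: Sequence[ParameterSpec],
    n: int,
    seed: int,
    method: str = "lhs",
) -> UncertaintyResult:
    """Propagate parameter uncertainty through the pipeline.

    ``method="lhs"`` stratifies; ``method="mc"`` uses simple random
    sampling.  A realization that raises is recorded as a failure; more
    than 20 % failures abort the batch.
    """
    if method not in ("mc", "lhs"):
        raise ValueError("method must be 'mc' or 'lhs'")
    nominal = pipeline(copy.deepcopy(base_doc))  # must run clean at nominal
    if method == "lhs":
        matrix = lhs_sample(params, n, seed)
    else:
        u = np.random.default_rng(seed).random((n, len(params)))
        matrix = np.column_stack([p.ppf(u[:, j]) for j, p in enumerate(params)])
    outputs = np.full((n, len(nominal)), np.nan)
    failures = 0
    for i in range(n):
        doc = copy.deepcopy(base_doc)
        for j, p in enumerate(params):
            set_path(doc, p.name, float(matrix[i, j]))
        try:
            series = pipeline(doc)
        except Exception:
            failures += 1
            continue
        if series.start != nominal.start or len(series) != len(nominal):
            failures += 1
            continue
        outputs[i] = series.values
    if failures > 0.2 * n:
        raise RuntimeError(f"{failures}/{n} realizations failed; batch aborted")
    ok = ~np.all(np.isnan(outputs), axis=1)
    import warnings

    with warnings.catch_warnings():
        # months no realization covers (e.g. pre-service) are all-NaN slices
        warnings.simplefilter("ignore", RuntimeWarning)
        table = {
            f"p{p:g}": np.nanpercentile(outputs[ok], p, axis=0) for p in PERCENTILES
        }
    index = pd.Index([str(m) for m in nominal.months()], name="month")
    return UncertaintyResult(
        percentiles=pd.DataFrame(table, index=index),
        n_realizations=n,
        n_failures=failures,
        seed=seed,
        start=nominal.start,
    )
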