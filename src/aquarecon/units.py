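"""Exact US/SI unit conversions.

Historical water-supply records mix US customary units (feet, miles,
gallons, Mgal/day) with the SI units the models use internally (m, km,
m³, m³/day).  Conversions use the exact legal definitions:
1 ft = 0.3048 m, 1 mi = 1.609344 km, 1 US gal = 0.003785411784 m³.
"""

from __future__ import annotations

import math

__all__ = ["convert_units", "round_sig", "UnsupportedUnitError"]

FT_PER_M = 1 / 0.3048
GAL_TO_M3 = 0.003785411784

# Directed conversion factors; reverse pairs are derived below.
_FACTORS: dict[tuple[str, str], float] = {
    ("ft", "m"): 0.3048,
    ("mi", "km"): 1.609344,
    ("gal", "m3"): GAL_TO_M3,
    ("Mgal/day", "m3/day"): 1e6 * GAL_TO_M3,
}
for (a, b), f in list(_FACTORS.items()):
    _FACTORS[(b, a)] = 1.0 / f
for u in {u for pair in _FACTORS for u in pair}:
    _FACTORS[(u, u)] = 1.0

_ALIASES = {"m^3": "m3", "m³": "m3", "m^3/day": "m3/day", "m³/day": "m3/day"}


class UnsupportedUnitError(ValueError):
    """Raised for a unit pair the converter does not know."""


def round_sig(value: float, sig: int) -> float:
    """Round *value* to *sig* significant figures (0 stays 0)."""
    if value == 0 or not math.isfinite(value):
        return value
    digits = sig - 1 - math.floor(math.log10(abs(value)))
    return round(value, digits)


def convert_units(value: float, from_unit: str, to_unit: str, sig_figs: int | None = None) -> float:
    """Convert *value* between supported units.

    Supported pairs: ft↔m, mi↔km, gal↔m³, Mgal/day↔m³/day (and identity).
    ``sig_figs`` optionally rounds the result to that many significant
    figures, matching how report values are printed.
    """
    from_unit = _ALIASES.get(from_unit, from_unit)
    to_unit = _ALIASES.get(to_unit, to_unit)
    try:
        factor = _FACTORS[(from_unit, to_unit)]
    except KeyError:
        raise UnsupportedUnitError(
            f"no conversion from {from_unit!r} to {to_unit!r}; supported pairs: "
            "ft<->m, mi<->km, gal<->m3, Mgal/day<->m3/day"
        ) from None
    out = value * factor
    if sig_figs is not None:
        out = round_sig(out, sig_figs)
    return out
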