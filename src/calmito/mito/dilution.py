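"""Dye-dilution arithmetic.

A topical microinjection (~150 nl of 300 nM TMRE) rapidly diffuses into a
much larger volume — the biopsy (~6 mm^3) or the recording bath (500 ul) —
so the working concentration stays in non-quenching mode. The dilution
factor is simply target volume over injected volume after unit conversion.
"""

from __future__ import annotations

#: conversion to microlitres; 1 mm^3 = 1 ul = 1000 nl
_TO_UL = {"nl": 1e-3, "ul": 1.0, "µl": 1.0, "mm3": 1.0, "ml": 1e3}


def _to_ul(value: float, unit: str) -> float:
    key = unit.lower().replace("^", "").replace("³", "3")
    if key not in _TO_UL:
        raise ValueError(f"unsupported volume unit {unit!r}; use nl, ul, mm3 or ml")
    if value <= 0:
        raise ValueError(f"volume must be positive; got {value} {unit}")
    return value * _TO_UL[key]


def dilution_factor(
    injected_volume: float,
    target_volume: float,
    injected_unit: str = "nl",
    target_unit: str = "mm3",
) -> float:
    """Dimensionless dilution factor: target volume / injected volume."""
    return _to_ul(target_volume, target_unit) / _to_ul(injected_volume, injected_unit)
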