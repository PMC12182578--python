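"""Inhabited-zone mask and per-zone inhabited area.

A cell is an inhabited candidate iff it has any built-up area or any
building height and is not covered by water; only such cells may receive
population, and the mask's cell count per zone is the area denominator
(in hectares, 1 cell = 1 ha at 100 m) for township density.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geodata import Grid, ZoneMap, zonal_aggregate

__all__ = ["compute_mask", "inhabited_area", "uninhabited_zone_report"]

_REQUIRED = ("builtup_frac", "building_height", "water")


def compute_mask(stack: dict[str, Grid]) -> Grid:
    """Boolean inhabited mask: (builtup > 0 or height > 0) and not water.

    The inequalities are strict, with no epsilon: a cell with exactly zero
    built-up fraction and zero building height is uninhabited.
    """
    missing = [n for n in _REQUIRED if n not in stack]
    if missing:
        raise ValueError(f"covariate stack missing layers: {missing}")
    b, h, w = (stack[n] for n in _REQUIRED)
    b.assert_coregistered(h)
    b.assert_coregistered(w)
    mask = ((b.values > 0) | (h.values > 0)) & (w.values == 0)
    return b.like(mask)


def inhabited_area(mask: Grid, zones: ZoneMap, level: str = "township") -> pd.Series:
    """Inhabited area per zone in hectares (cell count x cell area).

    Zones with no inhabited cell get 0 ha (they exist but cannot receive
    population); zones absent from the label grid are not reported.
    """
    counts = zonal_aggregate(mask.like(mask.values.astype(np.float64)),
                             zones, stat="sum", level=level)
    return (counts.fillna(0.0) * mask.cell_area_ha).rename("area_ha")


def uninhabited_zone_report(areas: pd.Series, census: pd.DataFrame,
                            group: str = "total") -> pd.DataFrame:
    """Zones with zero inhabited area, with any stranded census count.

    A positive count in such a zone cannot be allocated anywhere and is a
    conservation violation the caller must surface, never silently drop.
    """
    zero = areas.index[areas == 0]
    rows = []
    for zid in zero:
        count = float(census.at[zid, group]) if zid in census.index else np.nan
        rows.append({"zone_id": zid, "area_ha": 0.0, "stranded_count": count})
    return pd.DataFrame(rows, columns=["zone_id", "area_ha", "stranded_count"])
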