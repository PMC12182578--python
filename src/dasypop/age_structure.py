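"""Per-cell age proportions and total-vs-sum-of-ages consistency checks.

Because total population and each age group are mapped with their own
models, the direct total grid and the cell-wise sum of the age-group grids
need not coincide; their agreement, summarized per city as a Pearson
correlation and RMSE, is a consistency diagnostic. Age proportions are
taken against the summed-ages total, so the four proportions sum to 1 on
every defined cell.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geodata import AGE_GROUPS, Grid, ZoneMap
from .disaggregation import NODATA

__all__ = ["sum_age_groups", "proportions", "age_proportion_grids",
           "consistency_by_region"]


def sum_age_groups(grids: dict[str, Grid]) -> Grid:
    """Cell-wise sum of the four age-group grids; nodata if any input is."""
    gs = [grids[g] for g in AGE_GROUPS]
    for g in gs[1:]:
        gs[0].assert_coregistered(g)
    valid = np.logical_and.reduce([g.valid_mask() for g in gs])
    total = np.where(valid, sum(g.values for g in gs), NODATA)
    return gs[0].like(total, nodata=NODATA)


def proportions(group_grid: Grid, total_sum_grid: Grid) -> Grid:
    """Group share of the summed-ages total; nodata where that total is 0
    or either input is nodata."""
    group_grid.assert_coregistered(total_sum_grid)
    ok = (group_grid.valid_mask() & total_sum_grid.valid_mask()
          & (total_sum_grid.values > 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, group_grid.values / np.where(ok, total_sum_grid.values, 1.0),
                     NODATA)
    return group_grid.like(p, nodata=NODATA)


def age_proportion_grids(pop_grids: dict[str, Grid]) -> dict[str, Grid]:
    """All four proportion grids against the summed-ages denominator."""
    total_sum = sum_age_groups(pop_grids)
    return {g: proportions(pop_grids[g], total_sum) for g in AGE_GROUPS}


def consistency_by_region(total_direct: Grid, total_sum: Grid, zones: ZoneMap,
                          level: str = "city", min_cells: int = 3,
                          ) -> tuple[pd.DataFrame, dict]:
    """Per-region Pearson r and RMSE between the two total-population grids.

    Computed over cells valid in both grids with at least one of the two
    nonzero; regions with fewer than `min_cells` such cells are skipped
    with a warning, and regions where either grid is constant get a null r
    (the correlation is undefined there).

    Returns the per-region table and a summary dict with the mean and the
    25th-75th percentile interquartile range of each metric across regions.
    """
    total_direct.assert_coregistered(total_sum)
    labels = zones.labels_at_level(level).values
    valid = (total_direct.valid_mask() & total_sum.valid_mask()
             & ((total_direct.values != 0) | (total_sum.values != 0)))
    rows = []
    for rid in zones.ids_at_level(level):
        sel = (labels == rid) & valid
        n = int(sel.sum())
        if n < min_cells:
            warnings.warn(f"region {rid}: only {n} valid cells, skipped",
                          stacklevel=2)
            continue
        a = total_direct.values[sel].astype(float)
        b = total_sum.values[sel].astype(float)
        rmse = float(np.sqrt(np.mean((a - b) ** 2)))
        if a.std() == 0 or b.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        rows.append({"region_id": rid, "n_cells": n, "pearson_r": r,
                     "rmse": rmse})
    table = pd.DataFrame(rows, columns=["region_id", "n_cells", "pearson_r", "rmse"])
    summary = {}
    for metric in ("pearson_r", "rmse"):
        vals = table[metric].dropna().to_numpy()
        if len(vals):
            q25, q75 = np.percentile(vals, [25, 75])
            summary[metric] = {"mean": float(vals.mean()),
                               "iqr": [float(q25), float(q75)]}
        else:
            summary[metric] = {"mean": None, "iqr": None}
    return table, summary
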