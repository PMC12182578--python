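"""Weight surfaces and mass-conserving allocation of census counts to cells.

The fitted density model, applied to every cell's covariates, gives a
relative weight surface (zero outside the inhabited mask). Each source
zone's census count is then split across its inhabited cells in proportion
to the weights, with a final exact-sum correction so the pycnophylactic
(mass-preserving) contract holds tightly: cell values in a zone sum to the
zone's count. Cells in zones with no census row become nodata.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geodata import ALL_GROUPS, Grid, ZoneMap
from .density_model import FittedDensityModel
from .synthetic_landscape import COVARIATE_NAMES

__all__ = ["NODATA", "predict_weights", "allocate", "run_group_mappings"]

log = logging.getLogger(__name__)

#: nodata sentinel for population grids (counts are always >= 0)
NODATA = -9999.0


def predict_weights(model: FittedDensityModel, stack: dict[str, Grid],
                    mask: Grid) -> Grid:
    """Per-cell predicted density, clamped at zero, zeroed outside the mask."""
    missing = [n for n in COVARIATE_NAMES if n not in stack]
    if missing:
        raise ValueError(f"covariate stack missing layers: {missing}")
    template = stack["builtup_frac"]
    template.assert_coregistered(mask)
    m = mask.values.astype(bool)
    w = np.zeros(template.shape, dtype=np.float64)
    if m.any():
        X = np.column_stack([stack[n].values[m].astype(np.float64)
                             for n in COVARIATE_NAMES])
        w[m] = np.maximum(model.predict(X), 0.0)
    return template.like(w)


def allocate(census: pd.DataFrame, weights: Grid, zones: ZoneMap,
             mask: Grid, group: str, level: str = "township") -> Grid:
    """Distribute each zone's count over its inhabited cells by weight.

    cell value = count * w / sum(w over the zone's inhabited cells), then a
    final rescale-plus-residual correction pins the zone sum to the count
    exactly (to the last float bit that a single addition can fix). Zones
    with all-zero weight fall back to uniform allocation over inhabited
    cells; zones with population but no inhabited cell are logged as
    unallocatable. Cells of zones missing from the census become nodata.
    """
    weights.assert_coregistered(zones.labels)
    weights.assert_coregistered(mask)
    labels = zones.labels_at_level(level).values
    m = mask.values.astype(bool)
    out = np.zeros(weights.shape, dtype=np.float64)
    townships = zones.ids_at_level(level)
    missing_rows = [z for z in townships if z not in census.index]
    for zid in missing_rows:
        out[labels == zid] = NODATA
    unallocatable = []
    for zid in townships:
        if zid not in census.index:
            continue
        count = float(census.at[zid, group])
        in_zone = (labels == zid) & m
        if not in_zone.any():
            if count > 0:
                unallocatable.append((zid, count))
            continue
        w = weights.values[in_zone]
        wsum = w.sum()
        if wsum <= 0:
            # no model signal anywhere in the zone: spread uniformly
            alloc = np.full(w.shape, count / w.size)
            log.warning("zone %s has zero total weight; uniform fallback", zid)
        else:
            alloc = count * (w / wsum)
            s = alloc.sum()
            if s > 0:
                alloc *= count / s
        # pin the residual rounding error onto the heaviest cell
        resid = count - alloc.sum()
        if resid != 0.0:
            alloc[np.argmax(w)] += resid
        out[in_zone] = alloc
    if unallocatable:
        log.warning("%d zones with population but no inhabited cells; "
                    "counts left unallocated: %s", len(unallocatable),
                    unallocatable[:5])
    return weights.like(out, nodata=NODATA)


def run_group_mappings(census: pd.DataFrame,
                       models: dict[str, FittedDensityModel],
                       stack: dict[str, Grid], mask: Grid,
                       zones: ZoneMap,
                       groups: tuple[str, ...] = ALL_GROUPS,
                       level: str = "township",
                       ) -> dict[str, Grid]:
    """Independent weight-predict + allocate per group.

    The direct total grid and the four age-group grids are produced
    independently (the total is mapped with its own model, not as the sum
    of the groups), each individually mass-conserving.
    """
    missing = [g for g in groups if g not in models]
    if missing:
        raise ValueError(f"no fitted model for groups: {missing}")
    out: dict[str, Grid] = {}
    for g in groups:
        w = predict_weights(models[g], stack, mask)
        out[g] = allocate(census, w, zones, mask, g, level=level)
    return out
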