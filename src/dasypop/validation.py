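"""Coarse-source validation, city-size strata, and spatial-variation metrics.

With no gridded ground truth available in real deployments, the mapping is
validated by rerunning it from the next-coarser admin level (county instead
of township), summing the resulting cells back to townships, and comparing
against the actual township census. By the mass-conservation contract the
township-source mapping is exact at township level, so the coarse-source
agreement is a lower bound on the product's accuracy.

The spatial-variation metric — the within-unit standard deviation of
per-cell age proportions — separates a genuinely age-stratified mapping
from products that multiply a shared regional age share into a total grid
(which are constant within each region).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geodata import AGE_GROUPS, ALL_GROUPS, Grid, ZoneMap, zonal_aggregate
from .habitation import inhabited_area
from .density_model import (
    DEPTH_CANDIDATES,
    TREE_CANDIDATES,
    aggregate_covariates,
    build_training_table,
    evaluate_on_test,
    filter_middle_99,
    split_train_test,
    tune_and_fit,
)
from .disaggregation import NODATA, run_group_mappings

__all__ = [
    "CITY_SIZE_CLASSES",
    "fit_all_groups",
    "agreement_metrics",
    "aggregate_to_zones",
    "coarse_source_validation",
    "stratify_by_city_size",
    "spatial_variation",
    "baseline_county_share_product",
]

#: city classification by total population, left-closed edges (persons)
CITY_SIZE_CLASSES = (
    ("small", 0.0, 0.5e6),
    ("medium", 0.5e6, 1.0e6),
    ("large", 1.0e6, 5.0e6),
    ("very_large", 5.0e6, 10.0e6),
    ("extremely_large", 10.0e6, np.inf),
)


def fit_all_groups(census: pd.DataFrame, stack: dict[str, Grid], mask: Grid,
                   zones: ZoneMap, level: str = "township",
                   groups: tuple[str, ...] = ALL_GROUPS,
                   split_seed: int = 0, model_seed: int = 0,
                   tree_candidates=TREE_CANDIDATES,
                   depth_candidates=DEPTH_CANDIDATES,
                   apply_middle_99: bool = True):
    """Train-table build + per-group filter/split/tune/evaluate at a level.

    One shared train/test township split across groups (same geography for
    every model); the middle-99% filter is per group, re-applied to the
    shared splits. Returns (models, table, train, test).
    """
    agg = aggregate_covariates(stack, zones, mask=mask, level=level)
    areas = inhabited_area(mask, zones, level=level)
    table = build_training_table(census, agg, areas, groups=groups)
    train, test = split_train_test(table, seed=split_seed)
    models = {}
    for g in groups:
        tr = filter_middle_99(train, g) if apply_middle_99 else train
        te = filter_middle_99(test, g) if apply_middle_99 else test
        m = tune_and_fit(tr, g, seed=model_seed,
                         tree_candidates=tree_candidates,
                         depth_candidates=depth_candidates)
        m.split_seed = split_seed
        if len(te):
            evaluate_on_test(m, te)
        models[g] = m
    return models, table, train, test


def agreement_metrics(actual: np.ndarray, estimated: np.ndarray) -> dict:
    """R^2, RMSE, and the OLS fit of estimated (response) on actual.

    With estimated regressed on actual, a slope below 1 reads directly as
    underestimation in the more populous units.
    """
    actual = np.asarray(actual, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    resid = estimated - actual
    ss_res = float(resid @ resid)
    ss_tot = float(((actual - actual.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rmse = float(np.sqrt(np.mean(resid**2)))
    if len(actual) >= 2 and actual.std() > 0:
        slope, intercept = np.polyfit(actual, estimated, 1)
    else:
        slope = intercept = np.nan
    return {"n": len(actual), "r2": r2, "rmse": rmse,
            "slope": float(slope), "intercept": float(intercept)}


def aggregate_to_zones(pop: Grid, zones: ZoneMap,
                       level: str = "township") -> pd.Series:
    """Sum a population grid by zone, excluding nodata cells."""
    return zonal_aggregate(pop, zones, "sum", level=level).fillna(0.0)


def coarse_source_validation(census_fine: pd.DataFrame,
                             census_coarse: pd.DataFrame,
                             stack: dict[str, Grid], mask: Grid,
                             zones: ZoneMap,
                             groups: tuple[str, ...] = ALL_GROUPS,
                             source_level: str = "county",
                             target_level: str = "township",
                             split_seed: int = 0, model_seed: int = 0,
                             tree_candidates=TREE_CANDIDATES,
                             depth_candidates=DEPTH_CANDIDATES,
                             ) -> pd.DataFrame:
    """Rerun the whole mapping from a coarser source level and score it.

    Trains on coarse-level densities, allocates the coarse census, sums the
    grids back to the fine level, and reports per-group R^2, RMSE (persons)
    and the estimated-on-actual OLS fit against the fine census.
    """
    src_i = ("province", "city", "county", "township").index(source_level)
    tgt_i = ("province", "city", "county", "township").index(target_level)
    if src_i >= tgt_i:
        raise ValueError(
            f"source level {source_level!r} must be coarser than target "
            f"{target_level!r}")
    models, *_ = fit_all_groups(
        census_coarse, stack, mask, zones, level=source_level, groups=groups,
        split_seed=split_seed, model_seed=model_seed,
        tree_candidates=tree_candidates, depth_candidates=depth_candidates)
    pop = run_group_mappings(census_coarse, models, stack, mask, zones,
                             groups=groups, level=source_level)
    rows = []
    for g in groups:
        est = aggregate_to_zones(pop[g], zones, level=target_level)
        idx = est.index.intersection(census_fine.index)
        met = agreement_metrics(census_fine.loc[idx, g].to_numpy(),
                                est.loc[idx].to_numpy())
        rows.append({"group": g, **met})
    return pd.DataFrame(rows).set_index("group")


def stratify_by_city_size(estimated: pd.Series, actual: pd.Series,
                          zones: ZoneMap, city_totals: pd.Series,
                          ) -> pd.DataFrame:
    """Agreement metrics recomputed within city-population size classes.

    Every fine-level unit is assigned its city's class; edges are closed on
    the left ([0.5M, 1M) is "medium", 1.0M falls in "large").
    """
    idx = estimated.index.intersection(actual.index)
    city_of = {z: zones.ancestor_at_level(int(z), "city") for z in idx}
    missing = [z for z, c in city_of.items() if c not in city_totals.index]
    if missing:
        raise ValueError(f"city total unknown for zones {missing[:5]}")
    rows = []
    for name, lo, hi in CITY_SIZE_CLASSES:
        members = [z for z in idx if lo <= city_totals[city_of[z]] < hi]
        n_cities = len({city_of[z] for z in members})
        if not members:
            rows.append({"class": name, "n_cities": 0, "n": 0, "r2": np.nan,
                         "rmse": np.nan, "slope": np.nan, "intercept": np.nan})
            continue
        met = agreement_metrics(actual.loc[members].to_numpy(),
                                estimated.loc[members].to_numpy())
        rows.append({"class": name, "n_cities": n_cities, **met})
    return pd.DataFrame(rows).set_index("class")


def spatial_variation(prop: Grid, zones: ZoneMap, level: str = "township",
                      ddof: int = 0) -> tuple[pd.Series, dict]:
    """Within-unit SD of per-cell proportions at an admin level.

    Population (ddof=0) convention by default. Units with fewer than two
    valid cells are excluded. Returns the per-unit SD series and a summary
    with the mean and 25th-75th-percentile IQR across units.
    """
    labels = zones.labels_at_level(level).values
    valid = prop.valid_mask() & (labels > 0)
    lab = labels[valid]
    vals = prop.values[valid].astype(float)
    ids_all = np.asarray(zones.ids_at_level(level))
    nmax = int(max(labels.max(), ids_all.max(initial=0))) + 1
    n = np.bincount(lab, minlength=nmax)
    s = np.bincount(lab, weights=vals, minlength=nmax)
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, s / np.maximum(n, 1), 0.0)
    # two-pass: stable for near-constant proportion fields
    sqdev = np.bincount(lab, weights=(vals - means[lab]) ** 2, minlength=nmax)
    ids = np.asarray(zones.ids_at_level(level))
    keep = ids[n[ids] >= 2]
    var = sqdev[keep] / np.maximum(n[keep] - ddof, 1)
    sd = pd.Series(np.sqrt(np.maximum(var, 0.0)), index=keep, name="sd")
    if len(sd):
        q25, q75 = np.percentile(sd, [25, 75])
        summary = {"mean": float(sd.mean()), "iqr": [float(q25), float(q75)],
                   "n_units": int(len(sd))}
    else:
        summary = {"mean": None, "iqr": None, "n_units": 0}
    return sd, summary


def baseline_county_share_product(total_grid: Grid, census_coarse: pd.DataFrame,
                                  zones: ZoneMap, level: str = "county",
                                  ) -> dict[str, Grid]:
    """Age-group grids built as (regional age share) x (total grid).

    Emulates products whose age structure is a per-region multiplier on a
    gridded total: every cell of a region shares the region's age
    proportions. Used only as the comparison baseline for
    :func:`spatial_variation`.
    """
    labels = zones.labels_at_level(level).values
    denom = sum(census_coarse[g] for g in AGE_GROUPS)
    nmax = int(labels.max()) + 1
    out: dict[str, Grid] = {}
    valid = total_grid.valid_mask()
    for g in AGE_GROUPS:
        share = np.zeros(nmax)
        known = np.zeros(nmax, dtype=bool)
        for zid in census_coarse.index:
            if zid < nmax and denom[zid] > 0:
                share[zid] = census_coarse.at[zid, g] / denom[zid]
                known[zid] = True
        vals = np.where(valid & known[labels],
                        total_grid.values * share[labels], NODATA)
        out[g] = total_grid.like(vals, nodata=NODATA)
    return out
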