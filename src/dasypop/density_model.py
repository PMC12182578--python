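"""Township training tables and tuned random-forest density models.

One model per population group regresses township population density
(persons/ha over the inhabited area, untransformed) on the eight covariate
aggregates. Tuning is an exhaustive grid search over 13 tree counts x
9 depth caps, scored by 5-fold cross-validated RMSE, ties broken toward
the smaller forest; the winner is refit on the full training split and
reported against a held-out 15% test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold

from .geodata import Grid, ZoneMap, zonal_aggregate
from .synthetic_landscape import COVARIATE_NAMES

__all__ = [
    "TREE_CANDIDATES",
    "DEPTH_CANDIDATES",
    "FittedDensityModel",
    "aggregate_covariates",
    "build_training_table",
    "filter_middle_99",
    "split_train_test",
    "tune_and_fit",
    "evaluate_on_test",
    "importance_and_pdp",
]

#: candidate forest sizes for the grid search
TREE_CANDIDATES = (5, 10, 20, 40, 60, 80, 100, 150, 200, 400, 600, 800, 1000)
#: candidate depth caps for the grid search
DEPTH_CANDIDATES = (10, 20, 40, 50, 60, 70, 80, 90, 100)

#: minimum table size for the middle-99% density filter to engage
MIN_ROWS_FOR_FILTER = 200


@dataclass
class FittedDensityModel:
    """A tuned per-group random forest plus its tuning/evaluation record."""

    group: str
    estimator: RandomForestRegressor
    n_trees: int
    max_depth: int
    cv_rmse: float
    model_seed: int
    cv_table: pd.DataFrame = field(repr=False)
    test_r2: float | None = None
    test_rmse: float | None = None
    split_seed: int | None = None

    @property
    def feature_importances(self) -> pd.Series:
        return pd.Series(self.estimator.feature_importances_,
                         index=list(COVARIATE_NAMES), name=self.group)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)

    def report(self) -> dict:
        return {
            "group": self.group,
            "n_trees": self.n_trees,
            "max_depth": self.max_depth,
            "cv_rmse": self.cv_rmse,
            "test_r2": self.test_r2,
            "test_rmse": self.test_rmse,
            "split_seed": self.split_seed,
            "model_seed": self.model_seed,
            "feature_importances": self.feature_importances.to_dict(),
        }


def aggregate_covariates(stack: dict[str, Grid], zones: ZoneMap,
                         mask: Grid | None = None,
                         level: str = "township") -> pd.DataFrame:
    """Per-zone mean of each covariate layer.

    By default the mean is over inhabited cells only (pass ``mask``), which
    matches the inhabited-area denominator of the density target; pass
    ``mask=None`` for an all-cell mean.
    """
    restrict = mask.values.astype(bool) if mask is not None else None
    cols = {name: zonal_aggregate(stack[name], zones, "mean",
                                  restrict_to=restrict, level=level)
            for name in COVARIATE_NAMES}
    return pd.DataFrame(cols)


def build_training_table(census: pd.DataFrame, covariate_aggregates: pd.DataFrame,
                         areas: pd.Series,
                         groups: tuple[str, ...] | None = None) -> pd.DataFrame:
    """One row per zone with positive inhabited area: covariates + densities.

    Density for group g is count / inhabited area, persons per hectare,
    untransformed. Rows with zero area or null covariate aggregates are
    excluded with a warning.
    """
    if groups is None:
        groups = tuple(c for c in ("total", "a0_14", "a15_59", "a60_64", "a65plus")
                       if c in census.columns)
    idx = census.index.intersection(covariate_aggregates.index).intersection(areas.index)
    tab = covariate_aggregates.loc[idx].copy()
    tab["inhabited_area_ha"] = areas.loc[idx]

    zero_area = tab.index[(tab["inhabited_area_ha"] <= 0)
                          & (census.loc[idx, "total"] > 0)]
    if len(zero_area):
        warnings.warn(
            f"{len(zero_area)} zones with population but zero inhabited area "
            f"excluded from training: {list(zero_area[:5])}...", stacklevel=2)
    keep = tab["inhabited_area_ha"] > 0
    null_cov = tab[list(COVARIATE_NAMES)].isna().any(axis=1)
    if null_cov.any():
        warnings.warn(f"{int(null_cov.sum())} zones with null covariate "
                      "aggregates excluded from training", stacklevel=2)
    tab = tab[keep & ~null_cov]
    for g in groups:
        tab[f"density_{g}"] = census.loc[tab.index, g] / tab["inhabited_area_ha"]
    bad = ~np.isfinite(tab.filter(like="density_")).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite densities for zones {list(tab.index[bad])[:5]}")
    return tab


def filter_middle_99(table: pd.DataFrame, group: str) -> pd.DataFrame:
    """Keep rows strictly inside the middle 99% of the group's density.

    Drops 0.5% in each tail of the empirical distribution (linearly
    interpolated percentiles, strict exclusion). Applied per group, on that
    group's own density. Skipped with a warning below 200 rows, where the
    tail percentiles are too noisy to be meaningful.
    """
    col = f"density_{group}"
    if col not in table.columns:
        raise KeyError(f"no density column for group {group!r}")
    if len(table) < MIN_ROWS_FOR_FILTER:
        warnings.warn(
            f"only {len(table)} rows; middle-99% filter skipped", stacklevel=2)
        return table
    d = table[col].to_numpy()
    lo, hi = np.percentile(d, [0.5, 99.5])
    if lo == hi:  # degenerate: all densities equal
        return table
    return table[(d > lo) & (d < hi)]


def split_train_test(table: pd.DataFrame, fraction: float = 0.85,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded shuffle split: floor(fraction*n) train rows, remainder test."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(table))
    n_train = int(np.floor(fraction * len(table)))
    return table.iloc[order[:n_train]], table.iloc[order[n_train:]]


def tune_and_fit(train: pd.DataFrame, group: str, seed: int = 0,
                 tree_candidates: tuple[int, ...] = TREE_CANDIDATES,
                 depth_candidates: tuple[int, ...] = DEPTH_CANDIDATES,
                 n_folds: int = 5) -> FittedDensityModel:
    """Grid-search the forest size and depth by k-fold CV RMSE; refit winner.

    Every (trees, depth) combination — 117 at the default candidate lists —
    is scored by the pooled out-of-fold RMSE of a seeded k-fold split; the
    minimum wins, ties broken by fewer trees then shallower depth. The
    winning configuration is refit on all training rows.
    """
    if train.empty:
        raise ValueError("empty training table")
    col = f"density_{group}"
    X = train[list(COVARIATE_NAMES)].to_numpy(dtype=np.float64)
    y = train[col].to_numpy(dtype=np.float64)
    if not np.isfinite(y).all():
        raise ValueError(f"non-finite density target for group {group!r}")

    trees_sorted = sorted(tree_candidates)
    depths_sorted = sorted(depth_candidates)
    n_max = trees_sorted[-1]
    kf = KFold(n_splits=min(n_folds, len(train)), shuffle=True, random_state=seed)
    folds = list(kf.split(X))

    # Exact shortcut for the exhaustive grid: a seeded forest's first k
    # trees are identical to a fresh k-tree forest with the same seed, so
    # one max-size fit per (depth, fold) scores every tree-count candidate
    # via prefix averages. Likewise, once no tree reaches the depth cap,
    # all deeper caps yield the same forest and are scored from it.
    sq_err = np.zeros((len(depths_sorted), len(trees_sorted)))
    n_seen = 0
    for tr_idx, va_idx in folds:
        n_seen += len(va_idx)
        saturated_preds = None  # per-candidate preds once caps stop binding
        for di, depth in enumerate(depths_sorted):
            if saturated_preds is None:
                rf = RandomForestRegressor(
                    n_estimators=n_max, max_depth=depth, random_state=seed,
                    n_jobs=1)
                rf.fit(X[tr_idx], y[tr_idx])
                tree_preds = np.stack([t.predict(X[va_idx])
                                       for t in rf.estimators_])
                prefix = np.cumsum(tree_preds, axis=0)
                preds = [prefix[k - 1] / k for k in trees_sorted]
                if max(t.get_depth() for t in rf.estimators_) < depth:
                    saturated_preds = preds
            else:
                preds = saturated_preds
            for ti in range(len(trees_sorted)):
                resid = preds[ti] - y[va_idx]
                sq_err[di, ti] += float(resid @ resid)

    records = []
    best = None
    for ti, n_trees in enumerate(trees_sorted):
        for di, depth in enumerate(depths_sorted):
            rmse = float(np.sqrt(sq_err[di, ti] / n_seen))
            records.append({"n_trees": n_trees, "max_depth": depth,
                            "cv_rmse": rmse})
            # strict < keeps the earliest (fewest trees, shallowest) on ties
            if best is None or rmse < best[0]:
                best = (rmse, n_trees, depth)
    cv_rmse, n_trees, depth = best
    final = RandomForestRegressor(n_estimators=n_trees, max_depth=depth,
                                  random_state=seed, n_jobs=1)
    final.fit(X, y)
    return FittedDensityModel(
        group=group, estimator=final, n_trees=n_trees, max_depth=depth,
        cv_rmse=cv_rmse, model_seed=seed, cv_table=pd.DataFrame(records))


def evaluate_on_test(model: FittedDensityModel,
                     test: pd.DataFrame) -> tuple[float, float]:
    """Held-out R^2 and RMSE (persons/ha); recorded on the model."""
    if test.empty:
        raise ValueError("empty test table")
    X = test[list(COVARIATE_NAMES)].to_numpy(dtype=np.float64)
    y = test[f"density_{model.group}"].to_numpy(dtype=np.float64)
    pred = model.predict(X)
    r2 = float(r2_score(y, pred))
    rmse = float(np.sqrt(mean_squared_error(y, pred)))
    model.test_r2, model.test_rmse = r2, rmse
    return r2, rmse


def importance_and_pdp(model: FittedDensityModel, train: pd.DataFrame,
                       n_grid: int = 20) -> tuple[pd.Series, pd.DataFrame]:
    """Impurity importances and one-way partial dependence curves.

    Each covariate is swept over ``n_grid`` evenly spaced values between its
    1st and 99th training percentiles while the other covariates stay at
    their observed rows; the curve is the mean prediction.
    """
    X = train[list(COVARIATE_NAMES)].to_numpy(dtype=np.float64)
    curves = []
    for j, name in enumerate(COVARIATE_NAMES):
        lo, hi = np.percentile(X[:, j], [1, 99])
        grid = np.linspace(lo, hi, n_grid)
        for v in grid:
            Xs = X.copy()
            Xs[:, j] = v
            curves.append({"covariate": name, "value": float(v),
                           "mean_prediction": float(model.predict(Xs).mean())})
    return model.feature_importances, pd.DataFrame(curves)
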