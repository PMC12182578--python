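"""Seeded synthetic worlds for exercising the downscaling pipeline.

Real deployments feed the pipeline national covariate rasters and census
tables; those cannot ship with a test suite, and no gridded ground truth
exists for them anyway. This module builds small worlds where the truth IS
known: hierarchical admin zones tessellating the grid, spatially
autocorrelated covariate fields with correlated urban cores, a water mask,
and per-age-group population surfaces that are explicit nonlinear functions
of the covariates plus noise. Every stage of the pipeline can then be
checked against exact aggregates of that truth.

All randomness flows from a single integer seed; a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geodata import (
    AGE_GROUPS,
    ALL_GROUPS,
    LEVELS,
    Grid,
    ZoneMap,
    derive_a60_64,
)

__all__ = [
    "COVARIATE_NAMES",
    "LandscapeConfig",
    "TruthBundle",
    "generate_landscape",
    "generate_true_population",
    "tabulate_census",
]

#: the eight covariate layers, in canonical order
COVARIATE_NAMES = (
    "builtup_frac",
    "building_height",
    "ntl",
    "dist_road",
    "poi_density",
    "elevation",
    "slope",
    "water",
)


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic world.

    Defaults give a 400x400-cell (40 km x 40 km at 100 m) landscape with
    4 cities x 5 counties x 10 townships = 200 townships, moderate spatial
    autocorrelation, four urban cores, 8% open water, and density noise at
    15% of the signal's standard deviation.
    """

    n_rows: int = 400
    n_cols: int = 400
    cell_size: float = 100.0
    n_cities: int = 4
    counties_per_city: int = 5
    townships_per_county: int = 10
    correlation_length: float = 12.0   # cells; Gaussian-filter sigma
    urban_core_count: int = 4
    urban_decay_scale: float = 40.0    # cells; kernel e-folding radius
    water_fraction: float = 0.08
    density_scale: float = 60.0        # persons/ha at a fully urban cell
    density_noise_sd: float | None = None  # persons/ha; None -> 15% of signal sd
    # per-group logistic spatial trend (x-slope, y-slope, urbanity coefficient)
    age_gradients: dict = field(default_factory=lambda: {
        "a0_14": (0.4, 0.0, -0.5),
        "a15_59": (0.0, 0.0, 1.2),
        "a60_64": (-0.3, 0.3, -0.5),
        "a65plus": (-0.5, -0.4, -1.0),
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cities, self.counties_per_city, self.townships_per_county) < 1:
            raise ValueError("hierarchy counts must be >= 1")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError("water_fraction must lie in [0, 1]")
        if self.n_cols < self.n_cities * self.townships_per_county or \
                self.n_rows < self.counties_per_city:
            raise ValueError("hierarchy counts exceed grid capacity")

    @property
    def n_townships(self) -> int:
        return self.n_cities * self.counties_per_city * self.townships_per_county


@dataclass
class TruthBundle:
    """Known per-group population surfaces (persons per cell).

    ``grids['total']`` equals the cell-wise sum of the four age-group
    surfaces exactly; everything is zero outside the inhabited area.
    """

    grids: dict[str, Grid]
    params: dict

    def __post_init__(self) -> None:
        tot = self.grids["total"].values
        parts = sum(self.grids[g].values for g in AGE_GROUPS)
        if not np.array_equal(tot, parts):
            raise ValueError("group surfaces do not sum to total exactly")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _tessellate(cfg: LandscapeConfig) -> ZoneMap:
    """Rectangular nested tessellation: city column strips, county row
    strips within each city, township column strips within each county."""
    rows, cols = cfg.n_rows, cfg.n_cols
    city_edges = np.linspace(0, cols, cfg.n_cities + 1).astype(int)
    county_edges = np.linspace(0, rows, cfg.counties_per_city + 1).astype(int)

    province_id = 1
    units = [{"zone_id": province_id, "name": "province-1", "level": "province",
              "parent_id": 0}]
    next_id = 2
    labels = np.zeros((rows, cols), dtype=np.int64)
    for ci in range(cfg.n_cities):
        city_id = next_id
        next_id += 1
        units.append({"zone_id": city_id, "name": f"city-{ci + 1}",
                      "level": "city", "parent_id": province_id})
        c0, c1 = city_edges[ci], city_edges[ci + 1]
        for ki in range(cfg.counties_per_city):
            county_id = next_id
            next_id += 1
            units.append({"zone_id": county_id, "name": f"county-{ci + 1}.{ki + 1}",
                          "level": "county", "parent_id": city_id})
            r0, r1 = county_edges[ki], county_edges[ki + 1]
            town_edges = np.linspace(c0, c1, cfg.townships_per_county + 1).astype(int)
            for ti in range(cfg.townships_per_county):
                town_id = next_id
                next_id += 1
                units.append({"zone_id": town_id,
                              "name": f"township-{ci + 1}.{ki + 1}.{ti + 1}",
                              "level": "township", "parent_id": county_id})
                labels[r0:r1, town_edges[ti]:town_edges[ti + 1]] = town_id
    units_df = pd.DataFrame(units).set_index("zone_id")
    template = Grid(labels, (0.0, rows * cfg.cell_size, cfg.cell_size))
    return ZoneMap(template, units_df)


def generate_landscape(config: LandscapeConfig) -> tuple[dict[str, Grid], ZoneMap]:
    """Build the eight co-registered covariate grids and the zone map.

    Urban cores jointly raise built-up fraction, building height, nighttime
    lights and POI density (correlated covariates, as in real cities);
    roads radiate from the cores so distance-to-road is low where urbanity
    is high; elevation is an independent smooth field and slope its
    gradient magnitude; water is carved from a smooth field at the
    configured areal fraction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_rows, cfg.n_cols)
    zones = _tessellate(cfg)
    template = zones.labels

    rr, cc = np.mgrid[0:cfg.n_rows, 0:cfg.n_cols]

    # latent urbanity: smooth background + kernels around random cores
    urban = 0.6 * _smooth_field(rng, shape, cfg.correlation_length)
    cores = rng.uniform([0, 0], [cfg.n_rows, cfg.n_cols],
                        size=(cfg.urban_core_count, 2))
    for cy, cx in cores:
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        urban += 2.5 * np.exp(-d2 / (2 * cfg.urban_decay_scale**2))
    urban = urban - urban.mean()

    # water from its own smooth field, at the requested areal fraction
    wfield = _smooth_field(rng, shape, 1.5 * cfg.correlation_length) - 0.5 * urban
    if cfg.water_fraction > 0:
        thr = np.quantile(wfield, 1.0 - cfg.water_fraction)
        water = (wfield > thr).astype(np.uint8)
    else:
        water = np.zeros(shape, dtype=np.uint8)

    # built-up fraction: squashed urbanity with rural zeros, clipped to [0,1]
    builtup = np.clip(1.0 / (1.0 + np.exp(-(urban - 0.4) * 2.2)) - 0.18, 0.0, 1.0)
    builtup = np.where(water == 1, 0.0, builtup)

    height = np.where(
        builtup > 0,
        np.maximum(0.0, 18.0 * builtup**1.5
                   + 2.0 * _smooth_field(rng, shape, cfg.correlation_length / 2)),
        0.0,
    )
    ntl = np.maximum(
        0.0, 30.0 * builtup + 3.0 * np.maximum(urban, 0)
        + 1.5 * _smooth_field(rng, shape, cfg.correlation_length / 2),
    )
    poi = np.maximum(
        0.0, 25.0 * builtup**2
        + 1.0 * _smooth_field(rng, shape, cfg.correlation_length / 3),
    )

    # roads: spokes from each core plus a sparse lattice; distance transform
    road = np.zeros(shape, dtype=bool)
    spacing = max(cfg.n_rows, cfg.n_cols) // 5
    road[::spacing, :] = True
    road[:, ::spacing] = True
    for cy, cx in cores:
        road[int(np.clip(cy, 0, cfg.n_rows - 1)), :] = True
        road[:, int(np.clip(cx, 0, cfg.n_cols - 1))] = True
    dist_road = ndimage.distance_transform_edt(~road) * cfg.cell_size

    elevation = 300.0 + 120.0 * _smooth_field(rng, shape, 2 * cfg.correlation_length)
    gy, gx = np.gradient(elevation, cfg.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))

    def g(vals, nodata=None):
        return template.like(np.ascontiguousarray(vals, dtype=np.float64)
                             if vals.dtype != np.uint8 else vals, nodata)

    stack = {
        "builtup_frac": g(builtup),
        "building_height": g(height),
        "ntl": g(ntl),
        "dist_road": g(dist_road),
        "poi_density": g(poi),
        "elevation": g(elevation),
        "slope": g(slope),
        "water": template.like(water),
    }
    return stack, zones


def generate_true_population(stack: dict[str, Grid],
                             config: LandscapeConfig) -> TruthBundle:
    """True per-cell densities as a known nonlinear function of covariates.

    Total density rises monotonically with built-up fraction and building
    height, falls with slope and distance to road, and is zero on water and
    on cells with neither built-up area nor buildings. Age-group shares
    follow smooth logistic spatial trends (e.g. the 65+ share is higher
    away from urban cores), renormalized to sum to 1 per cell, so age
    structure varies across townships the way real censuses show.
    """
    cfg = config
    missing = [n for n in COVARIATE_NAMES if n not in stack]
    if missing:
        raise ValueError(f"covariate stack missing layers: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 917]))
    b = stack["builtup_frac"].values
    h = stack["building_height"].values
    s = stack["slope"].values
    d = stack["dist_road"].values
    p = stack["poi_density"].values
    water = stack["water"].values
    shape = b.shape

    inhabited = ((b > 0) | (h > 0)) & (water == 0)

    signal = cfg.density_scale * (
        (0.55 * b**1.3 + 0.35 * (h / (h + 8.0)) + 0.10 * (p / (p + 10.0)))
        * np.exp(-d / 5000.0)
        * np.exp(-s / 25.0)
    )
    noise_sd = cfg.density_noise_sd
    if noise_sd is None:
        sig_sd = signal[inhabited].std() if inhabited.any() else 0.0
        noise_sd = 0.15 * sig_sd
    total = signal + noise_sd * rng.standard_normal(shape)
    total = np.where(inhabited, np.maximum(total, 0.0), 0.0)

    # smooth logistic trends -> per-cell age shares summing to 1
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    xn = (cc - cc.mean()) / max(shape[1], 1)
    yn = (rr - rr.mean()) / max(shape[0], 1)
    urban_proxy = (b - b.mean()) / (b.std() + 1e-12)
    logits = {}
    base = {"a0_14": np.log(0.18), "a15_59": np.log(0.60),
            "a60_64": np.log(0.07), "a65plus": np.log(0.15)}
    for gname in AGE_GROUPS:
        ax, ay, au = cfg.age_gradients[gname]
        logits[gname] = base[gname] + ax * xn + ay * yn + au * 0.3 * urban_proxy
    mx = np.maximum.reduce([logits[gname] for gname in AGE_GROUPS])
    expo = {gname: np.exp(logits[gname] - mx) for gname in AGE_GROUPS}
    denom = sum(expo.values())

    template = stack["builtup_frac"]
    grids: dict[str, Grid] = {}
    for gname in AGE_GROUPS:
        grids[gname] = template.like(total * expo[gname] / denom)
    grids["total"] = template.like(
        sum(grids[gname].values for gname in AGE_GROUPS))
    params = {"noise_sd": float(noise_sd), "density_scale": cfg.density_scale,
              "age_gradients": dict(cfg.age_gradients)}
    return TruthBundle(grids, params)


def tabulate_census(truth: TruthBundle, zones: ZoneMap,
                    level: str = "township") -> pd.DataFrame:
    """Aggregate the true surfaces into a census table at an admin level.

    Output follows the real census schema (total, a0_14, a15_59, a60plus,
    a65plus) with a60plus reconstructed as a60_64 + a65plus, plus the
    derived a60_64 column re-attached; counts are exact cell sums.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown admin level {level!r}; expected one of {LEVELS}")
    labels = zones.labels_at_level(level).values
    ids = np.asarray(zones.ids_at_level(level))
    nmax = int(max(labels.max(), ids.max(initial=0))) + 1
    cols = {}
    for gname in AGE_GROUPS:
        sums = np.bincount(labels.ravel(),
                           weights=truth.grids[gname].values.ravel(),
                           minlength=nmax)
        cols[gname] = sums[ids]
    df = pd.DataFrame(cols, index=pd.Index(ids, name="zone_id"))
    # rebuild the real census schema so its additivity holds exactly
    df["a60plus"] = df["a60_64"] + df["a65plus"]
    df["total"] = df["a0_14"] + df["a15_59"] + df["a60plus"]
    df = df.drop(columns=["a60_64"])
    df.insert(0, "parent_id", [zones.units.at[z, "parent_id"] for z in ids])
    df.insert(0, "level", level)
    df.insert(0, "name", [zones.units.at[z, "name"] for z in ids])
    return derive_a60_64(df)
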