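"""Raster/vector/census I/O and areal bookkeeping.

Grids are plain 2-D numpy arrays with an affine anchor (top-left corner
origin plus square cell size, planar meters). Files are written as GeoTIFF
via :mod:`tifffile`, carrying ModelPixelScale / ModelTiepoint / GDAL_NODATA
tags so they open in standard GIS software. Administrative zones live as an
integer label grid plus a hierarchy table (township -> county -> city ->
province); census counts are per-zone, per-age-group tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import shape as _shapely_shape
from shapely import contains_xy, prepare

__all__ = [
    "Grid",
    "ZoneMap",
    "LEVELS",
    "CENSUS_GROUPS",
    "AGE_GROUPS",
    "ALL_GROUPS",
    "read_grid",
    "write_grid",
    "rasterize_zones",
    "zonal_aggregate",
    "read_census",
    "write_census",
    "derive_a60_64",
]

#: admin hierarchy, coarse to fine
LEVELS = ("province", "city", "county", "township")

#: columns a census table must carry (real census schema)
CENSUS_GROUPS = ("total", "a0_14", "a15_59", "a60plus", "a65plus")

#: the four mapped age groups (a60_64 derived as a60plus - a65plus)
AGE_GROUPS = ("a0_14", "a15_59", "a60_64", "a65plus")

#: all groups a density model is fitted for
ALL_GROUPS = ("total",) + AGE_GROUPS

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class Grid:
    """A georeferenced 2-D cell array.

    Parameters
    ----------
    values : ndarray
        Rectangular (rows x cols) array; row 0 is the northern edge.
    transform : tuple of float
        ``(x_origin, y_origin, cell_size)`` — coordinates of the top-left
        corner of cell (0, 0) and the square cell edge, in meters.
    crs_id : str
        Free-text CRS identifier; synthetic worlds use planar meters.
    nodata : float or None
        Sentinel marking invalid cells; must not collide with valid data.
    """

    values: np.ndarray
    transform: tuple[float, float, float] = (0.0, 0.0, 100.0)
    crs_id: str = "synthetic:planar-meters"
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got {self.values.ndim}-D")
        if self.transform[2] <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> float:
        return float(self.transform[2])

    @property
    def cell_area_ha(self) -> float:
        """Cell area in hectares; exactly 1 for 100-m cells."""
        return self.cell_size**2 / 10_000.0

    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        if np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center (each rows x cols)."""
        x0, y0, cs = self.transform
        rows, cols = self.shape
        xs = x0 + (np.arange(cols) + 0.5) * cs
        ys = y0 - (np.arange(rows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """New grid on the same lattice with different values."""
        if np.asarray(values).shape != self.shape:
            raise ValueError("values shape does not match grid")
        return Grid(np.asarray(values), self.transform, self.crs_id, nodata)

    def assert_coregistered(self, other: "Grid") -> None:
        if self.shape != other.shape or self.transform != other.transform:
            raise ValueError(
                f"grids not co-registered: {self.shape}/{self.transform} vs "
                f"{other.shape}/{other.transform}"
            )


def write_grid(grid: Grid, path) -> str:
    """Write a grid as a single-band GeoTIFF; returns the path written."""
    x0, y0, cs = grid.transform
    desc = json.dumps({"crs_id": grid.crs_id})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
    ]
    if grid.nodata is not None:
        nd = repr(float(grid.nodata)).encode() + b"\x00"
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd), nd))
    tifffile.imwrite(
        str(path), grid.values, description=desc, extratags=extratags,
        photometric="minisblack",
    )
    return str(path)


def read_grid(path) -> Grid:
    """Read a single-band GeoTIFF written by :func:`write_grid` (or alike)."""
    try:
        tf = tifffile.TiffFile(str(path))
    except (FileNotFoundError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read raster {path!r}: {exc}") from exc
    with tf:
        page = tf.pages[0]
        values = page.asarray()
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"raster {path!r} carries no georeferencing tags")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        transform = (float(tie[3]), float(tie[4]), float(scale[0]))
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            if isinstance(raw, bytes):
                raw = raw.decode()
            nodata = float(raw.strip("\x00 "))
        crs_id = "unknown"
        desc = tags.get(270)
        if desc is not None:
            try:
                crs_id = json.loads(desc.value).get("crs_id", "unknown")
            except (json.JSONDecodeError, AttributeError, TypeError):
                pass
        if crs_id == "unknown":
            raise ValueError(f"raster {path!r} has no CRS metadata")
    return Grid(values, transform, crs_id, nodata)


@dataclass
class ZoneMap:
    """Township-level label grid plus the admin hierarchy table.

    ``labels`` holds the finest-level (township) zone id per cell, 0 outside
    the study area. ``units`` is indexed by zone_id with columns
    ``name, level, parent_id`` covering every level of the hierarchy.
    """

    labels: Grid
    units: pd.DataFrame

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels.values))
        present.discard(0)
        missing = present - set(self.units.index)
        if missing:
            raise ValueError(f"labels not in units table: {sorted(missing)[:10]}")
        for level, parent_level in zip(LEVELS[1:], LEVELS[:-1]):
            for zid in self.ids_at_level(level):
                pid = self.units.at[zid, "parent_id"]
                if pid not in self.units.index or self.units.at[pid, "level"] != parent_level:
                    raise ValueError(
                        f"{level} {zid} lacks a {parent_level} parent (parent_id={pid})"
                    )

    def ids_at_level(self, level: str) -> list[int]:
        if level not in LEVELS:
            raise ValueError(f"unknown admin level {level!r}; expected one of {LEVELS}")
        return list(self.units.index[self.units["level"] == level])

    def ancestor_at_level(self, zone_id: int, level: str) -> int:
        """Walk parent links from any unit up to the requested level."""
        zid = zone_id
        while self.units.at[zid, "level"] != level:
            nxt = self.units.at[zid, "parent_id"]
            if nxt == zid or pd.isna(nxt):
                raise ValueError(f"zone {zone_id} has no ancestor at level {level!r}")
            zid = int(nxt)
        return zid

    def labels_at_level(self, level: str) -> Grid:
        """Label grid re-coded so each cell carries its ancestor at `level`."""
        if level not in LEVELS:
            raise ValueError(f"unknown admin level {level!r}; expected one of {LEVELS}")
        lut_max = int(self.labels.values.max())
        lut = np.zeros(lut_max + 1, dtype=np.int64)
        for tid in np.unique(self.labels.values):
            if tid == 0:
                continue
            lut[tid] = self.ancestor_at_level(int(tid), level)
        return self.labels.like(lut[self.labels.values.astype(np.int64)])


def rasterize_zones(polygons, template: Grid) -> ZoneMap:
    """Label each cell of `template` by the polygon containing its center.

    Parameters
    ----------
    polygons : sequence of mappings, or a GeoJSON FeatureCollection dict
        Each entry needs ``zone_id``, ``name``, ``level``, ``parent_id``
        and a ``geometry`` (shapely geometry or GeoJSON geometry mapping).
        Only the finest level present is burned into the label grid; all
        entries populate the hierarchy table.

    Cells outside every polygon get label 0. A cell center contained by two
    polygons of the same level is an overlap error; across levels the
    earliest polygon in input order wins (deterministic tie-break).
    """
    feats = polygons
    if isinstance(polygons, dict) and polygons.get("type") == "FeatureCollection":
        feats = [
            {**f["properties"], "geometry": f["geometry"]}
            for f in polygons["features"]
        ]
    records, geoms = [], []
    for f in feats:
        rec = {k: f[k] for k in ("zone_id", "name", "level", "parent_id")}
        geom = f["geometry"]
        if isinstance(geom, dict):
            geom = _shapely_shape(geom)
        records.append(rec)
        geoms.append(geom)
    units = pd.DataFrame(records).set_index("zone_id")

    present_levels = [lv for lv in LEVELS if (units["level"] == lv).any()]
    finest = present_levels[-1]
    xs, ys = template.cell_centers()
    labels = np.zeros(template.shape, dtype=np.int64)
    owner_order = np.full(template.shape, -1, dtype=np.int64)
    overlaps: list[tuple[int, int]] = []
    for order, (rec, geom) in enumerate(zip(records, geoms)):
        if rec["level"] != finest:
            continue
        prepare(geom)
        inside = contains_xy(geom, xs, ys)
        clash = inside & (labels != 0)
        if clash.any():
            for prev in np.unique(labels[clash]):
                overlaps.append((int(prev), int(rec["zone_id"])))
        burn = inside & (labels == 0)
        labels[burn] = rec["zone_id"]
        owner_order[burn] = order
        if not inside.any():
            warnings.warn(
                f"zone {rec['zone_id']} covers no cell center; it will hold no cells",
                stacklevel=2,
            )
    if overlaps:
        raise ValueError(f"overlapping same-level polygons (ids): {sorted(set(overlaps))}")
    return ZoneMap(template.like(labels), units)


def zonal_aggregate(grid: Grid, zones: ZoneMap, stat: str = "mean",
                    restrict_to: np.ndarray | None = None,
                    level: str = "township") -> pd.Series:
    """Aggregate grid values per zone: mean, sum or count of valid cells.

    Nodata cells never contribute; zones with no contributing cells get NaN
    (an explicit missing marker, never 0). `restrict_to` further limits the
    contributing cells (e.g. to the inhabited mask).
    """
    if stat not in ("mean", "sum", "count"):
        raise ValueError(f"stat must be mean/sum/count, got {stat!r}")
    grid.assert_coregistered(zones.labels)
    labels = zones.labels_at_level(level).values if level != "township" else zones.labels.values
    use = (labels > 0) & grid.valid_mask()
    if restrict_to is not None:
        if restrict_to.shape != grid.shape:
            raise ValueError("restrict_to mask shape mismatch")
        use &= restrict_to.astype(bool)
    ids = np.asarray(zones.ids_at_level(level))
    lab = labels[use]
    nmax = int(max(labels.max(), ids.max(initial=0))) + 1
    counts = np.bincount(lab, minlength=nmax).astype(float)
    if stat == "count":
        out = counts[ids]
        out[counts[ids] == 0] = np.nan
        # a zone genuinely holding zero contributing cells is missing, not 0
        return pd.Series(out, index=ids, name="count")
    sums = np.bincount(lab, weights=grid.values[use].astype(float), minlength=nmax)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = sums[ids] if stat == "sum" else sums[ids] / counts[ids]
    vals = np.where(counts[ids] == 0, np.nan, vals)
    return pd.Series(vals, index=ids, name=stat)


# ---------------------------------------------------------------------------
# census tables

_CENSUS_COLS = ["name", "level", "parent_id", *CENSUS_GROUPS]


def _validate_census(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CENSUS_GROUPS if c not in df.columns]
    if missing:
        raise ValueError(f"census table missing group columns: {missing}")
    counts = df[list(CENSUS_GROUPS)]
    if (counts.to_numpy() < 0).any():
        bad = df.index[(counts < 0).any(axis=1)].tolist()
        raise ValueError(f"negative census counts in zones {bad[:10]}")
    bad = df.index[df["a65plus"] > df["a60plus"]].tolist()
    if bad:
        raise ValueError(f"a65plus exceeds a60plus in zones {bad[:10]}")
    return df


def read_census(path) -> pd.DataFrame:
    """Read a per-zone census CSV (zone_id, name, level, parent_id, counts)."""
    df = pd.read_csv(path)
    if "zone_id" not in df.columns:
        raise ValueError("census CSV must have a zone_id column")
    df = df.set_index("zone_id")
    return _validate_census(df)


def write_census(census: pd.DataFrame, path) -> str:
    cols = [c for c in _CENSUS_COLS if c in census.columns]
    extra = [c for c in census.columns if c not in cols]
    census[cols + extra].to_csv(path, index_label="zone_id")
    return str(path)


def derive_a60_64(census: pd.DataFrame) -> pd.DataFrame:
    """Attach the 60-64 group as a60plus - a65plus (errors if negative)."""
    _validate_census(census)
    out = census.copy()
    out["a60_64"] = out["a60plus"] - out["a65plus"]
    return out
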