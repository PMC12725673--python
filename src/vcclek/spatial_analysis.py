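"""Spatial effort and VCC surfaces from fishing-ground polygons.

The spatial stage has three parts, all on a regular 0.01 degree WGS84 grid:

1. *Effort surface* — every fisher-decade polygon deposits 1 into each grid
   cell whose centre it contains; the summed counts, unit-normalized to
   [0, 1], show what share of fishers operate where.  Cells at or above a
   configurable share (default 0.6) are the core fishing grounds.
2. *Distance accounting* — the planar centroid of each polygon is measured
   geodesically (WGS84) to the fisher's port of origin, and summarised as
   per-village and per-decade means and medians.
3. *VCC surface* — the deposit of 1 is replaced by the polygon's virtual
   catch change value; the additive surface is scaled sign-preservingly so
   the largest magnitude is 4.

Cell membership is strictly centre-in-polygon, which keeps rasterization
additive and admits an exact brute-force oracle.  Grids are cell-centre
registered with row 0 at the northern edge.  Rasters are exchanged as ESRI
ASCII grids (plain text, nodata -9999); polygons as GeoJSON in EPSG:4326.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry

from vcclek.geodesy import geodesic_distance_km
from vcclek.survey_model import DECADES, PortRegistry

NODATA = -9999.0


@dataclass
class FishingGround:
    """One fisher's reported fishing area for one decade."""

    fisher_id: str
    decade: str
    polygon: BaseGeometry
    port_id: str
    vcc_value: float | None = None
    repaired: bool = False

    def __post_init__(self) -> None:
        if self.decade not in DECADES:
            raise ValueError(f"{self.fisher_id}: unknown decade {self.decade!r}")
        if not self.polygon.is_valid:
            # zero-buffer repair of self-intersections; logged via the flag
            self.polygon = self.polygon.buffer(0)
            self.repaired = True
        if self.polygon.is_empty or self.polygon.area == 0.0:
            raise ValueError(f"{self.fisher_id}/{self.decade}: degenerate polygon")
        minx, miny, maxx, maxy = self.polygon.bounds
        if minx < -180 or maxx > 180 or miny < -90 or maxy > 90:
            raise ValueError(f"{self.fisher_id}/{self.decade}: lon/lat out of bounds")


@dataclass(frozen=True)
class GridSpec:
    """Cell-centre registered lon/lat grid; row 0 at the northern edge."""

    origin_lon: float   # west edge
    origin_lat: float   # north edge
    cell_size: float = 0.01
    n_cols: int = 0
    n_rows: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @classmethod
    def from_bounds(cls, minx: float, miny: float, maxx: float, maxy: float,
                    cell_size: float = 0.01, pad_cells: int = 1) -> "GridSpec":
        ox = minx - pad_cells * cell_size
        oy = maxy + pad_cells * cell_size
        n_cols = int(math.ceil((maxx - ox) / cell_size)) + pad_cells
        n_rows = int(math.ceil((oy - miny) / cell_size)) + pad_cells
        return cls(ox, oy, cell_size, n_cols, n_rows)

    @classmethod
    def covering(cls, grounds: Sequence["FishingGround"],
                 cell_size: float = 0.01) -> "GridSpec":
        bounds = np.array([g.polygon.bounds for g in grounds])
        return cls.from_bounds(bounds[:, 0].min(), bounds[:, 1].min(),
                               bounds[:, 2].max(), bounds[:, 3].max(), cell_size)

    def col_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def row_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    @property
    def east(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size

    @property
    def south(self) -> float:
        return self.origin_lat - self.n_rows * self.cell_size

    def contains_bounds(self, minx: float, miny: float,
                        maxx: float, maxy: float) -> bool:
        return (minx >= self.origin_lon and maxx <= self.east
                and miny >= self.south and maxy <= self.origin_lat)


@dataclass
class GridSurface:
    """A raster of effort counts or additive VCC values plus its metadata."""

    spec: GridSpec
    values: np.ndarray
    kind: str = "effort"            # effort | vcc
    normalization: str = "none"     # none | unit | symmetric4
    all_zero: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError("value array does not match the grid spec")


def rasterize_effort(grounds: Sequence[FishingGround],
                     spec: GridSpec) -> GridSurface:
    """Sum, per cell, the polygons containing the cell centre (deposit 1)."""
    return _deposit(grounds, spec, lambda g: 1.0, kind="effort")


def vcc_surface(grounds: Sequence[FishingGround], spec: GridSpec,
                decade: str | None = None, normalized: bool = True
                ) -> GridSurface:
    """Additive VCC raster: each polygon deposits its VCC value.

    Restricted to one decade when ``decade`` is given.  By default the
    result is sign-preservingly scaled to the [-4, 4] display range; pass
    ``normalized=False`` for the raw additive surface.
    """
    sel = [g for g in grounds if decade is None or g.decade == decade]
    for g in sel:
        if g.vcc_value is None:
            raise ValueError(f"{g.fisher_id}/{g.decade}: missing vcc_value")
    surf = _deposit(sel, spec, lambda g: float(g.vcc_value), kind="vcc")
    return normalize_surface(surf, "symmetric4") if normalized else surf


def _deposit(grounds: Sequence[FishingGround], spec: GridSpec,
             weight, kind: str) -> GridSurface:
    values = np.zeros((spec.n_rows, spec.n_cols))
    xs = spec.col_centers()
    ys = spec.row_centers()
    for g in grounds:
        minx, miny, maxx, maxy = g.polygon.bounds
        if not spec.contains_bounds(minx, miny, maxx, maxy):
            raise ValueError(
                f"polygon of fisher {g.fisher_id} ({g.decade}) extends outside the grid"
            )
        c0 = int(np.searchsorted(xs, minx))
        c1 = int(np.searchsorted(xs, maxx))
        # rows are north->south: ys is descending
        r0 = int(np.searchsorted(-ys, -maxy))
        r1 = int(np.searchsorted(-ys, -miny))
        if c0 >= c1 or r0 >= r1:
            continue
        gx, gy = np.meshgrid(xs[c0:c1], ys[r0:r1])
        inside = shapely.contains_xy(g.polygon, gx.ravel(), gy.ravel())
        values[r0:r1, c0:c1] += weight(g) * inside.reshape(gx.shape)
    return GridSurface(spec, values, kind=kind)


def normalize_surface(surface: GridSurface, mode: str) -> GridSurface:
    """Scale a surface to its display range; idempotent, zero-preserving.

    ``unit`` divides by the maximum (range [0, 1], maximum exactly 1);
    ``symmetric4`` multiplies by 4 / max(|values|) so the largest magnitude
    is exactly 4 and signs are preserved.  An all-zero surface is returned
    unchanged with ``all_zero`` set.
    """
    if mode not in ("unit", "symmetric4"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    vmax = float(np.max(np.abs(surface.values)))
    if vmax == 0.0:
        return replace(surface, values=surface.values.copy(),
                       normalization=mode, all_zero=True)
    if mode == "unit":
        scaled = surface.values / float(surface.values.max())
    else:
        scaled = surface.values * (4.0 / vmax)
    return replace(surface, values=scaled, normalization=mode, all_zero=False)


def minmax_affine_symmetric4(surface: GridSurface) -> GridSurface:
    """Alternative [-4, 4] scaling: affine min-max, not sign-preserving."""
    vmin, vmax = float(surface.values.min()), float(surface.values.max())
    if vmax == vmin:
        return replace(surface, values=surface.values.copy(),
                       normalization="symmetric4_affine", all_zero=True)
    scaled = -4.0 + 8.0 * (surface.values - vmin) / (vmax - vmin)
    return replace(surface, values=scaled, normalization="symmetric4_affine",
                   all_zero=False)


def core_fishing_cells(surface: GridSurface, threshold: float = 0.6
                       ) -> np.ndarray:
    """Boolean mask of cells where at least ``threshold`` of fishers operate.

    Expects a unit-normalized effort surface (the share of interviewed
    fishers whose grounds cover each cell).
    """
    if surface.normalization != "unit":
        surface = normalize_surface(surface, "unit")
    return surface.values >= threshold


# ---------------------------------------------------------------------------
# Centroids and distances

def centroid(polygon: BaseGeometry) -> tuple[float, float]:
    """Area-weighted planar centroid in degree space (lon, lat).

    Planar (shoelace) rather than projected: at the near-equatorial
    latitudes of interest the difference from a projected centroid is
    negligible relative to hand-drawn polygon uncertainty.
    """
    if polygon.is_empty or polygon.area == 0.0:
        raise ValueError("degenerate polygon has no area centroid")
    c = polygon.centroid
    return float(c.x), float(c.y)


def distance_to_port(point: tuple[float, float],
                     port: tuple[float, float]) -> float:
    """WGS84 geodesic distance in km between two lon/lat points."""
    return geodesic_distance_km(point[0], point[1], port[0], port[1])


def decadal_distance_summary(grounds: Sequence[FishingGround],
                             ports: PortRegistry) -> "pd.DataFrame":
    """Centroid-to-port distances grouped by village and decade.

    Returns a tidy table (village, decade, n, mean_km, median_km); rows with
    village ``"ALL"`` pool every ground in the decade, and decade ``"all"``
    pools across decades (so the ("ALL", "all") row is the overall mean).
    """
    import pandas as pd

    rows = []
    for g in grounds:
        port = ports[g.port_id]
        d = distance_to_port(centroid(g.polygon), (port.lon, port.lat))
        rows.append({"village": port.name, "decade": g.decade, "km": d})
    df = pd.DataFrame(rows)
    out = []
    for (village, decade), grp in df.groupby(["village", "decade"]):
        out.append({"village": village, "decade": decade, "n": len(grp),
                    "mean_km": grp["km"].mean(), "median_km": grp["km"].median()})
    for decade, grp in df.groupby("decade"):
        out.append({"village": "ALL", "decade": decade, "n": len(grp),
                    "mean_km": grp["km"].mean(), "median_km": grp["km"].median()})
    for village, grp in df.groupby("village"):
        out.append({"village": village, "decade": "all", "n": len(grp),
                    "mean_km": grp["km"].mean(), "median_km": grp["km"].median()})
    out.append({"village": "ALL", "decade": "all", "n": len(df),
                "mean_km": df["km"].mean(), "median_km": df["km"].median()})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# I/O: GeoJSON polygons, ESRI ASCII rasters

def load_fishing_grounds(path: str | Path) -> list[FishingGround]:
    """Read a GeoJSON FeatureCollection of fisher-decade polygons.

    Features must carry ``fisher_id``, ``decade`` and ``port_id`` properties;
    ``vcc_value`` is optional.  Coordinates are taken as EPSG:4326 lon/lat.
    """
    with open(path) as fh:
        fc = json.load(fh)
    crs = fc.get("crs", {}).get("properties", {}).get("name", "")
    if crs and "4326" not in crs and "CRS84" not in crs:
        raise ValueError(f"expected EPSG:4326 polygons, found CRS {crs!r}")
    out = []
    for feat in fc["features"]:
        props = feat["properties"]
        vcc = props.get("vcc_value")
        out.append(FishingGround(
            fisher_id=str(props["fisher_id"]),
            decade=str(props["decade"]),
            polygon=geom_shape(feat["geometry"]),
            port_id=str(props["port_id"]),
            vcc_value=None if vcc is None else float(vcc),
        ))
    return out


def write_fishing_grounds(grounds: Iterable[FishingGround],
                          path: str | Path) -> None:
    feats = []
    for g in grounds:
        props = {"fisher_id": g.fisher_id, "decade": g.decade,
                 "port_id": g.port_id}
        if g.vcc_value is not None:
            props["vcc_value"] = g.vcc_value
        feats.append({"type": "Feature", "properties": props,
                      "geometry": geom_mapping(g.polygon)})
    fc = {"type": "FeatureCollection",
          "crs": {"type": "name",
                  "properties": {"name": "urn:ogc:def:crs:OGC:1.3:CRS84"}},
          "features": feats}
    with open(path, "w") as fh:
        json.dump(fc, fh)


def write_ascii_grid(surface: GridSurface, path: str | Path) -> None:
    """Write an ESRI ASCII grid (row 0 of the array = northern edge)."""
    spec = surface.spec
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {_fmt(spec.origin_lon)}\n")
        fh.write(f"yllcorner {_fmt(spec.south)}\n")
        fh.write(f"cellsize {_fmt(spec.cell_size)}\n")
        fh.write(f"NODATA_value {_fmt(NODATA)}\n")
        for row in surface.values:
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def _fmt(v: float) -> str:
    # shortest round-trippable decimal form
    return format(float(v), ".17g")


def read_ascii_grid(path: str | Path, kind: str = "effort") -> GridSurface:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    spec = GridSpec(origin_lon=header["xllcorner"],
                    origin_lat=header["yllcorner"] + n_rows * cell,
                    cell_size=cell, n_cols=n_cols, n_rows=n_rows)
    return GridSurface(spec, np.array(rows), kind=kind)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
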