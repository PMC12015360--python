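"""Gridded rasters, admin polygons and the utilities shared by every pipeline stage.

The analysis grid is a regular raster of square cells (5 x 5 km by default).
A cell's value refers to its centroid; the affine convention is the raster
standard with the origin at the upper-left corner (row 0 is the northernmost
row).  Rasters are serialized as plain-text ESRI ASCII grids with a JSON
sidecar carrying CRS and band semantics; polygons travel as GeoJSON.

Two coordinate modes exist throughout the package:

``"planar_km"``
    Synthetic desk-scale regions; x/y in kilometres, Euclidean distance.
``"lonlat"``
    WGS84 degrees; distances are great-circle kilometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.prepared import prep

__all__ = [
    "RasterGrid",
    "AdminPolygons",
    "read_ascii_grid",
    "resample_bilinear",
    "align_stack",
    "AlignedBundle",
]

_ASCII_NODATA = -9999.0

#: band semantics accepted in ``RasterGrid.band``
BAND_KINDS = ("population", "covariate", "dn", "mean", "sd", "other")


@dataclass
class RasterGrid:
    """A single-band georeferenced regular grid.

    Parameters
    ----------
    values : ndarray, shape (rows, cols)
        Cell values; ``np.nan`` entries are treated as nodata in memory.
    x0, y0 : float
        Coordinates of the *upper-left corner* of the grid (not a centroid).
    cell_size : float
        Side length of a square cell, in the units of the CRS (km for
        ``planar_km``, degrees for ``lonlat``).
    crs : str
        ``"planar_km"`` or ``"lonlat"``.
    band : str
        Semantic tag, one of :data:`BAND_KINDS`.
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float | None = None
    cell_size: float = 5.0
    crs: str = "planar_km"
    band: str = "other"
    nodata: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.y0 is None:
            # default: lower-left at 0, so the top edge sits at rows*cell
            self.y0 = self.values.shape[0] * self.cell_size
        if self.band == "dn":
            v = self.values[np.isfinite(self.values)]
            if v.size and ((v < 0).any() or (v > 63).any() or (v != np.round(v)).any()):
                raise ValueError("DN band must be integer-valued in [0, 63]")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_centroids(self) -> np.ndarray:
        cols = self.values.shape[1]
        return self.x0 + (np.arange(cols) + 0.5) * self.cell_size

    @property
    def y_centroids(self) -> np.ndarray:
        """Centroid y per row, row 0 first (descending)."""
        rows = self.values.shape[0]
        return self.y0 - (np.arange(rows) + 0.5) * self.cell_size

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) centroid coordinates in row-major order."""
        xx, yy = np.meshgrid(self.x_centroids, self.y_centroids)
        return xx.ravel(), yy.ravel()

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.y0 - y) / self.cell_size).astype(int)
        rows, cols = self.shape
        if ((col < 0) | (col >= cols) | (row < 0) | (row >= rows)).any():
            raise ValueError("point outside raster extent")
        return row, col

    def is_nodata(self) -> np.ndarray:
        mask = ~np.isfinite(self.values)
        if self.nodata is not None:
            mask |= self.values == self.nodata
        return mask

    def grid_spec(self) -> dict:
        return {
            "rows": self.shape[0],
            "cols": self.shape[1],
            "x0": self.x0,
            "y0": self.y0,
            "cell_size": self.cell_size,
            "crs": self.crs,
        }

    # -- i/o ----------------------------------------------------------------
    def write_ascii(self, path: str | Path) -> None:
        """Write an ESRI ASCII grid plus a ``.json`` metadata sidecar."""
        path = Path(path)
        rows, cols = self.shape
        vals = self.values.copy()
        vals[self.is_nodata()] = _ASCII_NODATA
        header = (
            f"ncols {cols}\n"
            f"nrows {rows}\n"
            f"xllcorner {float(self.x0)!r}\n"
            f"yllcorner {float(self.y0 - rows * self.cell_size)!r}\n"
            f"cellsize {float(self.cell_size)!r}\n"
            f"NODATA_value {_ASCII_NODATA}\n"
        )
        body = "\n".join(" ".join(repr(float(v)) for v in r) for r in vals)
        path.write_text(header + body + "\n")
        meta = {"crs": self.crs, "band": self.band, "nodata": self.nodata}
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :meth:`RasterGrid.write_ascii`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        k, v = lines[i].split()
        hdr[k.lower()] = float(v)
        i += 1
    vals = np.array([[float(v) for v in ln.split()] for ln in lines[i:] if ln.strip()])
    vals[vals == hdr.get("nodata_value", _ASCII_NODATA)] = np.nan
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    cell = hdr["cellsize"]
    return RasterGrid(
        vals,
        x0=hdr["xllcorner"],
        y0=hdr["yllcorner"] + hdr["nrows"] * cell,
        cell_size=cell,
        crs=meta.get("crs", "planar_km"),
        band=meta.get("band", "other"),
        nodata=meta.get("nodata"),
    )


# ---------------------------------------------------------------------------
# admin polygons


@dataclass
class AdminPolygons:
    """District polygons with ids, admin level and parent-country tags."""

    district_ids: list
    geometries: list
    level: str = "admin-2"
    country_ids: list | None = None

    def __post_init__(self):
        if len(set(self.district_ids)) != len(self.district_ids):
            raise ValueError("district ids must be unique")
        for g in self.geometries:
            if not g.is_valid:
                raise ValueError("invalid polygon geometry")
        if self.country_ids is None:
            self.country_ids = [0] * len(self.district_ids)

    def __len__(self):
        return len(self.district_ids)

    def geometry(self, district_id):
        return self.geometries[self.district_ids.index(district_id)]

    def to_geojson(self, path: str | Path, properties: pd.DataFrame | None = None) -> None:
        """Write a GeoJSON FeatureCollection; ``properties`` (indexed by
        district id) adds extra attributes such as estimates for mapping."""
        feats = []
        for did, geom, cid in zip(self.district_ids, self.geometries, self.country_ids):
            props = {"district_id": did, "level": self.level, "country_id": cid}
            if properties is not None and did in properties.index:
                props.update({k: _jsonable(v) for k, v in properties.loc[did].items()})
            feats.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "AdminPolygons":
        fc = json.loads(Path(path).read_text())
        ids, geoms, cids, level = [], [], [], "admin-2"
        for f in fc["features"]:
            ids.append(f["properties"]["district_id"])
            level = f["properties"].get("level", level)
            cids.append(f["properties"].get("country_id", 0))
            geoms.append(shape(f["geometry"]))
        return cls(ids, geoms, level=level, country_ids=cids)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# bilinear resampling


def resample_bilinear(src: RasterGrid, target: RasterGrid | dict) -> RasterGrid:
    """Resample ``src`` onto the grid of ``target`` by bilinear interpolation.

    The value at each target cell centroid is interpolated from the four
    surrounding source centroids; beyond the outermost centroids the edge
    value is held (constant extension), so outputs are always bounded by the
    source min/max.  A target cell whose four surrounding source cells include
    nodata becomes nodata — nodata is propagated, never interpolated across.
    """
    spec = target.grid_spec() if isinstance(target, RasterGrid) else dict(target)
    if isinstance(target, RasterGrid) and target.crs != src.crs:
        raise ValueError("CRS mismatch between source and target")
    rows, cols = int(spec["rows"]), int(spec["cols"])
    cell = float(spec["cell_size"])
    xt = spec["x0"] + (np.arange(cols) + 0.5) * cell
    yt = spec["y0"] - (np.arange(rows) + 0.5) * cell

    xs = src.x_centroids
    ys_desc = src.y_centroids
    if xt[-1] + cell / 2 < xs[0] - src.cell_size / 2 or xt[0] - cell / 2 > xs[-1] + src.cell_size / 2 \
            or yt[0] + cell / 2 < ys_desc[-1] - src.cell_size / 2 or yt[-1] - cell / 2 > ys_desc[0] + src.cell_size / 2:
        raise ValueError("source and target extents are disjoint")

    vals = src.values
    bad = src.is_nodata()

    def locate(q, knots):
        j = np.clip(np.searchsorted(knots, q) - 1, 0, len(knots) - 2)
        f = (q - knots[j]) / (knots[j + 1] - knots[j])
        return j, np.clip(f, 0.0, 1.0)

    jx, fx = locate(xt, xs)
    ys_asc = ys_desc[::-1]
    jy_asc, fy = locate(yt, ys_asc)  # per target row, in ascending-y index space
    nrows_src = vals.shape[0]
    r_lo = nrows_src - 1 - jy_asc          # source row of the lower-y knot
    r_hi = r_lo - 1                        # row of the upper-y knot

    JX, FX = np.meshgrid(jx, np.arange(rows), indexing="xy")[0], np.tile(fx, (rows, 1))
    RLO = np.tile(r_lo[:, None], (1, cols))
    RHI = np.tile(r_hi[:, None], (1, cols))
    FY = np.tile(fy[:, None], (1, cols))

    v00 = vals[RLO, JX]
    v01 = vals[RLO, JX + 1]
    v10 = vals[RHI, JX]
    v11 = vals[RHI, JX + 1]
    out = (
        (1 - FY) * ((1 - FX) * v00 + FX * v01)
        + FY * ((1 - FX) * v10 + FX * v11)
    )
    any_bad = bad[RLO, JX] | bad[RLO, JX + 1] | bad[RHI, JX] | bad[RHI, JX + 1]
    out[any_bad] = np.nan
    return RasterGrid(out, x0=spec["x0"], y0=spec["y0"], cell_size=cell,
                      crs=spec.get("crs", src.crs), band=src.band if src.band != "dn" else "other")


# ---------------------------------------------------------------------------
# alignment


@dataclass
class AlignedBundle:
    """Everything on the common analysis grid: rasters, districts, clusters."""

    rasters: dict
    districts: AdminPolygons
    clusters: pd.DataFrame
    district_map: np.ndarray  # per-cell district id, -1 where none
    grid: RasterGrid


def cluster_xy(clusters: pd.DataFrame) -> tuple[np.ndarray, str]:
    """Coordinate array (n, 2) and mode from a cluster table.

    Planar tables carry ``x_km``/``y_km`` columns; spherical tables carry
    ``lon``/``lat`` (the count column ``y`` is never a coordinate).
    """
    if {"x_km", "y_km"}.issubset(clusters.columns):
        return clusters[["x_km", "y_km"]].to_numpy(dtype=float), "planar_km"
    if {"lon", "lat"}.issubset(clusters.columns):
        return clusters[["lon", "lat"]].to_numpy(dtype=float), "lonlat"
    raise ValueError("cluster table needs x_km/y_km or lon/lat columns")


def district_membership(grid: RasterGrid, districts: AdminPolygons) -> np.ndarray:
    """Per-cell district assignment by the centroid-containment rule.

    A cell belongs to the district whose polygon contains its centroid;
    on ties (shared boundaries) the lowest district id wins.  Cells inside
    no district get -1.
    """
    xx, yy = grid.centroids()
    out = np.full(xx.size, -1, dtype=object)
    order = sorted(range(len(districts)), key=lambda i: districts.district_ids[i])
    unassigned = np.ones(xx.size, dtype=bool)
    from shapely.geometry import Point

    for i in order:
        geom = prep(districts.geometries[i])
        for k in np.nonzero(unassigned)[0]:
            if geom.intersects(Point(xx[k], yy[k])):
                out[k] = districts.district_ids[i]
                unassigned[k] = False
    return out.reshape(grid.shape)


def align_stack(
    rasters: dict,
    districts: AdminPolygons,
    clusters: pd.DataFrame,
    grid: RasterGrid | None = None,
) -> AlignedBundle:
    """Bring rasters, polygons and the cluster table onto one analysis grid.

    ``grid`` defaults to the first raster.  Rasters already on the target grid
    pass through untouched; others are resampled bilinearly.  Clusters gain
    ``cell_row``/``cell_col``/``district_id`` columns; a cluster falling in no
    district raises, listing the offending ids.
    """
    if grid is None:
        grid = next(iter(rasters.values()))
    spec = grid.grid_spec()
    aligned = {}
    for name, r in rasters.items():
        if r.crs != grid.crs:
            raise ValueError(f"CRS mismatch for raster {name!r}: {r.crs} vs {grid.crs}")
        if r.grid_spec() == spec:
            aligned[name] = r
        else:
            aligned[name] = resample_bilinear(r, grid)
    dmap = district_membership(grid, districts)
    out = clusters.copy()
    xy, _mode = cluster_xy(out)
    row, col = grid.cell_of(xy[:, 0], xy[:, 1])
    out["cell_row"], out["cell_col"] = row, col
    out["district_id"] = dmap[row, col]
    lost = out.loc[out["district_id"] == -1, "cluster_id"].tolist()
    if lost:
        raise ValueError(f"clusters outside all districts: {lost}")
    return AlignedBundle(aligned, districts, out, dmap, grid)
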