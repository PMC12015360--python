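"""Population-weighted aggregation of posterior surfaces, and pseudo-location
imputation for clusters that lack GPS coordinates.

District estimates are population-weighted averages of the member grid cells,
computed draw-by-draw so the posterior sd of the district value reflects the
full joint uncertainty of the surface.  A cell belongs to the district
containing its centroid (ties to the lowest district id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep
from sklearn.cluster import KMeans

from .geostat import PosteriorSurface
from .io_raster import AdminPolygons, RasterGrid, district_membership

__all__ = ["aggregate_surface", "impute_pseudo_locations", "population_mask"]


def _weighted_mean(draws, w):
    return draws @ w / w.sum()


def aggregate_surface(surface: PosteriorSurface, population: RasterGrid,
                      districts: AdminPolygons | np.ndarray,
                      grid: RasterGrid | None = None):
    """Aggregate a posterior surface to district and national level.

    Parameters
    ----------
    surface : PosteriorSurface
        Draws aligned with the cells of ``population`` (row-major order).
    population : RasterGrid
        Population weights on the same grid.
    districts : AdminPolygons or ndarray
        Either polygons (membership resolved by the centroid rule) or a
        precomputed per-cell district-id array.

    Returns
    -------
    (DataFrame, dict)
        Per-district table with posterior mean and sd in percent, and the
        national summary computed directly over all cells.
    """
    pop = population.values.ravel()
    if surface.draws.shape[1] != pop.size:
        raise ValueError("surface and population are not on a common grid")
    if isinstance(districts, AdminPolygons):
        dmap = district_membership(grid or population, districts).ravel()
    else:
        dmap = np.asarray(districts).ravel()
        if dmap.size != pop.size:
            raise ValueError("district map does not match the grid")

    rows = []
    for did in sorted(pd.unique(dmap[dmap != -1]).tolist()):
        sel = dmap == did
        w = pop[sel]
        if w.sum() <= 0:
            raise ValueError(f"district {did!r} has zero total population")
        dvals = _weighted_mean(surface.draws[:, sel], w)  # one value per draw
        rows.append({
            "district_id": did,
            "mean_pct": 100.0 * dvals.mean(),
            "sd_pct": 100.0 * dvals.std(ddof=1),
            "population": w.sum(),
            "n_cells": int(sel.sum()),
        })
    table = pd.DataFrame(rows)

    inside = dmap != -1
    nat = _weighted_mean(surface.draws[:, inside], pop[inside])
    national = {"mean_pct": 100.0 * nat.mean(), "sd_pct": 100.0 * nat.std(ddof=1),
                "population": float(pop[inside].sum())}
    return table, national


def population_mask(population: RasterGrid, threshold: float = 10.0,
                    per_km2: bool = True) -> np.ndarray:
    """Boolean mask of sparsely populated cells (for map rendering only;
    never applied to the aggregation arithmetic)."""
    dens = population.values / (population.cell_size ** 2 if per_km2 else 1.0)
    return dens < threshold


def impute_pseudo_locations(polygon, population: RasterGrid, n_latent: int,
                            n_candidates: int = 1000, seed: int = 0) -> np.ndarray:
    """Impute plausible coordinates for survey clusters without GPS data.

    For each of the ``n_latent`` latent survey locations, ``n_candidates``
    candidate points are sampled within the admin unit with probability
    proportional to cell population (uniformly within the chosen cell); the
    pooled cloud is clustered by seeded k-means with k = n_latent and the
    centroids are returned.  A centroid that falls outside a non-convex unit
    is snapped to the nearest candidate point.  Each pseudo-location is meant
    to carry the unit-level average indicator value.
    """
    if n_latent < 1:
        raise ValueError("n_latent must be >= 1")
    xx, yy = population.centroids()
    pts = np.column_stack([xx, yy])
    prepared = prep(polygon)
    inside = np.array([prepared.intersects(Point(*p)) for p in pts])
    pop = population.values.ravel().copy()
    pop[~inside] = 0.0
    if pop.sum() <= 0:
        raise ValueError("admin unit contains no positive population")

    rng = np.random.default_rng(seed)
    total = n_latent * n_candidates
    cells = rng.choice(pop.size, size=total, p=pop / pop.sum())
    half = population.cell_size / 2.0
    jitter = rng.uniform(-half, half, size=(total, 2))
    cloud = pts[cells] + jitter
    if np.unique(cloud, axis=0).shape[0] < n_latent:
        raise ValueError("fewer distinct candidate locations than k")

    km = KMeans(n_clusters=n_latent, n_init=4, random_state=seed % (2 ** 31))
    km.fit(cloud)
    centroids = km.cluster_centers_
    for i, c in enumerate(centroids):
        if not prepared.intersects(Point(*c)):
            d2 = ((cloud - c) ** 2).sum(axis=1)
            centroids[i] = cloud[np.argmin(d2)]
    return centroids
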