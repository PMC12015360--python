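"""Synthetic survey regions with the exact statistical structure of the model.

The generator replaces restricted-access survey microdata: it builds a gridded
region (population, covariates, districts), draws a Matérn(nu=1) spatial field
and per-cluster binomial counts whose logit-probability is covariate effect +
spatial field + iid nugget, emits individual records whose aggregation through
the indicators module reproduces the cluster counts, and renders a
nighttime-light raster that induces a distance-to-settlement quality gradient.

Default configuration values are the study conditions used throughout the
test-suite: 300 clusters, beta = (0.5, -0.3) (intercept and one standardized
log-normal covariate), spatial variance 1, range 60 km, nugget variance 0.1,
on a 30 x 30 grid of 5-km cells.  Regions are planar (km) by default —
spherical lon/lat mode uses great-circle distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg
from shapely.geometry import box
from shapely.ops import unary_union
from sklearn.cluster import KMeans

from .geostat import MaternParams, matern_cov, pairwise_distances, cross_distances
from .io_raster import AdminPolygons, RasterGrid

__all__ = [
    "SimulationConfig",
    "RegionGeometry",
    "TrueField",
    "make_region",
    "simulate_latent_field",
    "simulate_clusters_and_counts",
    "simulate_records",
    "simulate_nightlight",
    "simulate_survey",
    "jitter_clusters",
    "HEAPING_BASELINE",
]

#: natural share of terminal digits 0/5 over a 40-age window
HEAPING_BASELINE = 0.2

INDICATORS = ("age_heaping", "incomplete_age", "flagged_haz")


@dataclass
class SimulationConfig:
    """Truth parameters and sizes of one synthetic survey."""

    seed: int = 0
    n_clusters: int = 300
    grid_shape: tuple = (30, 30)
    n_districts: int = 9
    beta: tuple = (0.5, -0.3)
    sigma2_spatial: float = 1.0
    range_km: float = 60.0
    sigma2_nugget: float = 0.1
    mean_cluster_size: float = 25.0
    heaping_link: str = "age_heaping"   # which indicator the record generator targets
    cell_km: float = 5.0
    n_towns: int = 3
    coord_mode: str = "planar_km"

    def __post_init__(self):
        if self.sigma2_spatial < 0 or self.sigma2_nugget < 0:
            raise ValueError("variances must be non-negative")
        if self.range_km <= 0:
            raise ValueError("range_km must be positive")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.heaping_link not in INDICATORS:
            raise ValueError(f"heaping_link must be one of {INDICATORS}")

    @property
    def n_covariates(self) -> int:
        return len(self.beta) - 1

    def write(self, path) -> None:
        """Echo the config as a key=value text file into an output directory."""
        lines = [f"{k}={v!r}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RegionGeometry:
    """Grid, district partition, and population/covariate rasters."""

    population: RasterGrid
    covariates: list
    districts: AdminPolygons
    district_map: np.ndarray  # (rows, cols) int district index
    config: SimulationConfig

    @property
    def grid(self) -> RasterGrid:
        return self.population

    def cell_coords(self) -> np.ndarray:
        xx, yy = self.population.centroids()
        return np.column_stack([xx, yy])


@dataclass
class TrueField:
    """A realization of the latent spatial field and the implied truth."""

    omega: np.ndarray   # (n_cells,)
    p_true: np.ndarray  # (n_cells,), inverse-logit of x'beta + omega

    def __post_init__(self):
        if ((self.p_true <= 0) | (self.p_true >= 1)).any():
            raise ValueError("p_true must lie strictly in (0, 1)")


def _smooth_gaussian_field(coords, sigma2, range_km, rng, mode="planar_km"):
    if sigma2 == 0:
        return np.zeros(coords.shape[0])
    D = pairwise_distances(coords, mode)
    C = matern_cov(D, MaternParams(sigma2, range_km))
    C[np.diag_indices_from(C)] += 1e-9 * sigma2
    try:
        L = linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as e:
        raise ValueError("Matern covariance not positive definite — check "
                         "distances/parameters") from e
    return L @ rng.standard_normal(coords.shape[0])


def make_region(config: SimulationConfig) -> RegionGeometry:
    """Generate the region: smooth log-normal population and covariates plus a
    seeded k-means partition of the cells into districts."""
    rows, cols = config.grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("grid_shape must be positive")
    if config.n_districts > rows * cols:
        raise ValueError("more districts than grid cells requested")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    grid = RasterGrid(np.zeros((rows, cols)), cell_size=config.cell_km,
                      crs=config.coord_mode, band="population")
    coords = np.column_stack(grid.centroids())
    extent = max(rows, cols) * config.cell_km

    # log-normal population: exp of a smooth field, strictly positive
    logpop = _smooth_gaussian_field(coords, 1.0, extent / 4, rng, config.coord_mode)
    pop = np.exp(np.log(500.0) + logpop).reshape(rows, cols)
    population = RasterGrid(pop, cell_size=config.cell_km,
                            crs=config.coord_mode, band="population")

    covariates = []
    for _ in range(config.n_covariates):
        f = _smooth_gaussian_field(coords, 0.8, extent / 5, rng, config.coord_mode)
        covariates.append(RasterGrid(np.exp(f).reshape(rows, cols),
                                     cell_size=config.cell_km,
                                     crs=config.coord_mode, band="covariate"))

    if config.n_districts == 1:
        labels = np.zeros(rows * cols, dtype=int)
    else:
        km = KMeans(n_clusters=config.n_districts, n_init=4,
                    random_state=config.seed % (2 ** 31)).fit(coords)
        labels = km.labels_
    dmap = labels.reshape(rows, cols)
    geoms = []
    cs = config.cell_km
    for d in range(config.n_districts):
        cells = [box(grid.x0 + c * cs, grid.y0 - (r + 1) * cs,
                     grid.x0 + (c + 1) * cs, grid.y0 - r * cs)
                 for r, c in zip(*np.nonzero(dmap == d))]
        geoms.append(unary_union(cells))
    districts = AdminPolygons(list(range(config.n_districts)), geoms)
    return RegionGeometry(population, covariates, districts, dmap, config)


def simulate_latent_field(region: RegionGeometry, sigma2: float, range_km: float,
                          seed: int, beta=None) -> TrueField:
    """Draw the Matérn(nu=1) spatial field over cell centroids and the implied
    per-cell true probability inverse-logit(x'beta + omega)."""
    if sigma2 < 0 or range_km <= 0:
        raise ValueError("need sigma2 >= 0 and range_km > 0")
    rng = np.random.default_rng(seed)
    coords = region.cell_coords()
    omega = _smooth_gaussian_field(coords, sigma2, range_km, rng,
                                   region.config.coord_mode)
    eta = omega.copy()
    if beta is not None:
        eta = eta + region_design_matrix(region) @ np.asarray(beta, dtype=float)
    from scipy.special import expit

    return TrueField(omega, np.clip(expit(eta), 1e-12, 1 - 1e-12))


def region_design_matrix(region: RegionGeometry) -> np.ndarray:
    """Intercept + log-standardized covariates at every cell."""
    n = region.population.values.size
    cols = [np.ones(n)]
    for cov in region.covariates:
        lx = np.log(cov.values.ravel())
        cols.append((lx - lx.mean()) / lx.std())
    return np.column_stack(cols)


_design_matrix = region_design_matrix


def simulate_clusters_and_counts(region: RegionGeometry, field: TrueField,
                                 config: SimulationConfig, seed: int | None = None
                                 ) -> pd.DataFrame:
    """Place clusters proportional to population and draw binomial counts.

    Cluster cells are drawn with probability proportional to cell population;
    cluster sizes are 1 + Poisson(mean_cluster_size - 1) so every cluster has
    at least one record; logit p = x'beta + omega + eps with a fresh iid
    nugget per cluster.  Returns the ClusterCounts table with columns
    cluster_id, x, y, row, col, district_id, y, m, p_true, indicator and the
    standardized covariate columns cov_0..  ``seed`` defaults to a stream
    derived from the config seed.
    """
    cfg = config
    if field.omega.size != region.population.values.size:
        raise ValueError("field not defined on the region grid")
    pop = region.population.values.ravel()
    total = pop.sum()
    if total <= 0:
        raise ValueError("zero total population")
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 2]) if seed is None else seed)
    cells = rng.choice(pop.size, size=cfg.n_clusters, p=pop / total)
    coords = region.cell_coords()[cells]
    m = 1 + rng.poisson(max(cfg.mean_cluster_size - 1.0, 0.0), size=cfg.n_clusters)
    X = region_design_matrix(region)[cells]
    eps = rng.normal(0.0, np.sqrt(cfg.sigma2_nugget), size=cfg.n_clusters)
    from scipy.special import expit

    eta = X @ np.asarray(cfg.beta, dtype=float) + field.omega[cells] + eps
    p = expit(eta)
    yy = rng.binomial(m, p)
    rows, cols = np.unravel_index(cells, region.population.shape)
    cx, cy = ("x_km", "y_km") if cfg.coord_mode == "planar_km" else ("lon", "lat")
    out = pd.DataFrame({
        "cluster_id": np.arange(cfg.n_clusters),
        cx: coords[:, 0], cy: coords[:, 1],
        "row": rows, "col": cols,
        "district_id": region.district_map.ravel()[cells],
        "y": yy, "m": m, "p_true": p,
        "indicator": cfg.heaping_link,
    })
    for j in range(1, X.shape[1]):
        out[f"cov_{j - 1}"] = X[:, j]
    out.attrs["coord_mode"] = cfg.coord_mode
    return out


# ---------------------------------------------------------------------------
# record-level bridge to the indicators


def _heaped_ages(k, rng):
    return rng.choice(np.arange(25, 61, 5), size=k)


def _unheaped_ages(k, rng):
    # ages 23..62 whose terminal digit is not 0 or 5
    pool = np.array([a for a in range(23, 63) if a % 5 != 0])
    return rng.choice(pool, size=k)


def simulate_records(clusters: pd.DataFrame, config: SimulationConfig,
                     seed: int | None = None, exact_counts: bool = True):
    """Emit individual survey rows that aggregate back to the cluster counts.

    In exact-count mode (default) each cluster of size m gets exactly y
    error-bearing rows, so the indicators module recovers (y, m) exactly.
    In stochastic mode each record carries the error independently: for age
    heaping a respondent heaps with probability h = (W - 0.2) / 0.8 — an
    inversion constructed here so the terminal-digit-0/5 share equals the
    target W in expectation on top of the natural 20% baseline (W < 0.2 is
    unreachable and raises) — while for the other two indicators the per-record
    error probability is W itself.

    Returns a :class:`~geoqual.indicators.RecordTable`.
    """
    from .indicators import RecordTable

    cfg = config
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 3]) if seed is None else seed)
    kind = cfg.heaping_link
    rows = []
    for rec in clusters.itertuples(index=False):
        m = int(rec.m)
        if exact_counts:
            n_err = int(rec.y)
        else:
            W = float(rec.p_true)
            if kind == "age_heaping":
                if W < HEAPING_BASELINE - 1e-12:
                    raise ValueError(
                        f"target heaping share {W:.3f} below the natural "
                        f"baseline {HEAPING_BASELINE} is unreachable")
                h = (W - HEAPING_BASELINE) / (1.0 - HEAPING_BASELINE)
                n_err = None  # decided per record below
            else:
                n_err = int(rng.binomial(m, W))
        if kind == "age_heaping":
            if exact_counts:
                err = np.zeros(m, dtype=bool)
                err[:n_err] = True
            else:
                heap = rng.uniform(size=m) < h
                # non-heapers carry a uniform terminal digit
                digit_05 = rng.integers(0, 10, size=m) % 5 == 0
                err = heap | digit_05
            ages = np.where(err, _heaped_ages(m, rng), _unheaped_ages(m, rng))
            for a in ages:
                rows.append({"cluster_id": rec.cluster_id, "reported_age": int(a)})
        elif kind == "incomplete_age":
            err = np.zeros(m, dtype=bool)
            err[:n_err] = True
            ages = rng.integers(15, 50, size=m)
            miss_month = err & (rng.uniform(size=m) < 0.7)
            miss_year = err & ~miss_month
            for i in range(m):
                rows.append({"cluster_id": rec.cluster_id, "age": int(ages[i]),
                             "birth_month_missing": bool(miss_month[i]),
                             "birth_year_missing": bool(miss_year[i])})
        else:  # flagged_haz
            err = np.zeros(m, dtype=bool)
            err[:n_err] = True
            for i in range(m):
                if err[i]:
                    if rng.uniform() < 0.5:
                        haz = np.nan
                    else:
                        haz = rng.choice([-1, 1]) * rng.uniform(6.01, 12.0)
                else:
                    haz = rng.normal(-1.0, 1.3)
                    haz = float(np.clip(haz, -5.9, 5.9))
                rows.append({"cluster_id": rec.cluster_id, "haz": haz,
                             "height_measured": bool(np.isfinite(haz))})
    df = pd.DataFrame(rows)
    if kind == "age_heaping":
        return RecordTable(roster=df)
    if kind == "incomplete_age":
        return RecordTable(women=df)
    return RecordTable(children=df)


# ---------------------------------------------------------------------------
# nightlights


def simulate_nightlight(region: RegionGeometry, config: SimulationConfig,
                        seed: int | None = None) -> RasterGrid:
    """Digital-number raster in [0, 63]: bright town centres (DN >= 15)
    decaying to darkness with distance."""
    cfg = config
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 4]) if seed is None else seed)
    grid = region.population
    coords = region.cell_coords()
    dn = np.zeros(coords.shape[0])
    if cfg.n_towns > 0:
        pop = region.population.values.ravel()
        towns = rng.choice(pop.size, size=cfg.n_towns, replace=False,
                           p=pop / pop.sum())
        peaks = rng.uniform(40, 63, size=cfg.n_towns)
        scale = 2.5 * cfg.cell_km
        d = cross_distances(coords, coords[towns], cfg.coord_mode)
        dn = (peaks[None, :] * np.exp(-d / scale)).max(axis=1)
    dn = np.clip(np.rint(dn), 0, 63)
    return RasterGrid(dn.reshape(grid.shape), x0=grid.x0, y0=grid.y0,
                      cell_size=grid.cell_size, crs=grid.crs, band="dn")


def jitter_clusters(clusters: pd.DataFrame, max_km: float, seed: int) -> pd.DataFrame:
    """Random displacement of cluster coordinates (confidentiality-jitter
    sensitivity utility); uniform direction, uniform radius up to ``max_km``."""
    if "x_km" not in clusters.columns:
        raise ValueError("jitter utility supports planar (km) tables only")
    rng = np.random.default_rng(seed)
    out = clusters.copy()
    theta = rng.uniform(0, 2 * np.pi, size=len(out))
    r = rng.uniform(0, max_km, size=len(out))
    out["x_km"] = out["x_km"] + r * np.cos(theta)
    out["y_km"] = out["y_km"] + r * np.sin(theta)
    return out


# ---------------------------------------------------------------------------
# orchestrator


@dataclass
class SyntheticSurvey:
    region: RegionGeometry
    field: TrueField
    clusters: pd.DataFrame
    records: object
    nightlight: RasterGrid


def simulate_survey(config: SimulationConfig, exact_counts: bool = True) -> SyntheticSurvey:
    """Run the full generator with seed streams derived from ``config.seed``."""
    region = make_region(config)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence([config.seed, 5]).spawn(3)]
    field = simulate_latent_field(region, config.sigma2_spatial, config.range_km,
                                  seeds[0], beta=config.beta)
    clusters = simulate_clusters_and_counts(region, field, config, seed=seeds[1])
    records = simulate_records(clusters, config, seed=seeds[2],
                               exact_counts=exact_counts)
    nightlight = simulate_nightlight(region, config)
    return SyntheticSurvey(region, field, clusters, records, nightlight)
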