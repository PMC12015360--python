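"""Pre-model screening tools.

Empirical-logit transformation of cluster counts, log + z-score covariate
standardization, variance-inflation-factor collinearity checks, empirical
variograms of non-spatial-model residuals, and district-level Moran's I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geostat import pairwise_distances

__all__ = [
    "empirical_logit",
    "LogStandardizeParams",
    "log_standardize",
    "apply_log_standardize",
    "vif",
    "VariogramEstimate",
    "empirical_variogram",
    "morans_i",
    "lattice_adjacency",
    "queen_adjacency",
]

VIF_THRESHOLD = 4.0


def empirical_logit(y, m):
    """Empirical logit ``log((y + 0.5) / (m - y + 0.5))``.

    Finite for every 0 <= y <= m thanks to the half-count offsets, hence
    usable at the boundaries where the plain logit diverges.
    """
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    if (m < 1).any():
        raise ValueError("empirical logit undefined for m == 0")
    if ((y < 0) | (y > m)).any():
        raise ValueError("need 0 <= y <= m")
    return np.log((y + 0.5) / (m - y + 0.5))


# ---------------------------------------------------------------------------
# covariate transformation


@dataclass
class LogStandardizeParams:
    """Frozen parameters of the log + z-score transform, for reuse on the
    prediction grid."""

    columns: list
    offsets: dict
    means: dict
    sds: dict


def log_standardize(covariates: pd.DataFrame, columns=None):
    """Column-wise log transform then standardization to mean 0, variance 1.

    Covariates with zeros (nightlights, malaria incidence) get an offset of
    half the smallest positive value before the log; strictly positive columns
    are logged as-is.  Returns the transformed table and the fitted
    :class:`LogStandardizeParams` for reuse at prediction time.
    """
    cols = list(columns) if columns is not None else list(covariates.columns)
    out = covariates.copy()
    offsets, means, sds = {}, {}, {}
    for c in cols:
        x = covariates[c].to_numpy(dtype=float)
        if (x < 0).any():
            raise ValueError(f"column {c!r} has negative values; log undefined")
        off = 0.0
        if (x == 0).any():
            pos = x[x > 0]
            if pos.size == 0:
                raise ValueError(f"column {c!r} is all zeros")
            off = pos.min() / 2.0
        lx = np.log(x + off)
        mu, sd = lx.mean(), lx.std(ddof=0)
        if sd == 0:
            raise ValueError(f"column {c!r} has zero variance after log")
        out[c] = (lx - mu) / sd
        offsets[c], means[c], sds[c] = off, mu, sd
    return out, LogStandardizeParams(cols, offsets, means, sds)


def apply_log_standardize(covariates: pd.DataFrame, params: LogStandardizeParams):
    """Apply stored transform parameters (e.g. to the prediction grid)."""
    out = covariates.copy()
    for c in params.columns:
        x = covariates[c].to_numpy(dtype=float)
        out[c] = (np.log(x + params.offsets[c]) - params.means[c]) / params.sds[c]
    return out


# ---------------------------------------------------------------------------
# collinearity


def vif(design: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factors VIF_j = 1 / (1 - R^2_j).

    Each covariate is regressed (with intercept) on all the others.  Exact
    linear dependence is reported as ``inf`` with the flag raised rather than
    crashing.  Values at or above 4.0 flag multicollinearity.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least two covariates")
    n = len(design)
    if n <= len(cols):
        raise ValueError("need more observations than covariates")
    rows = []
    for c in cols:
        yv = design[c].to_numpy(dtype=float)
        X = sm.add_constant(design.drop(columns=[c]).to_numpy(dtype=float))
        res = sm.OLS(yv, X).fit()
        r2 = min(res.rsquared, 1.0)
        v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"covariate": c, "vif": v, "flagged": bool(v >= VIF_THRESHOLD)})
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# variogram


@dataclass
class VariogramEstimate:
    """Classical (Matheron) empirical semivariogram."""

    bin_mid: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ok = self.pair_counts > 0
        ax.plot(self.bin_mid[ok], self.semivariance[ok], "o-")
        ax.set_xlabel("distance (km)")
        ax.set_ylabel("semivariance")
        return ax


def empirical_variogram(residuals, locations, n_bins: int = 15,
                        max_dist: float | None = None,
                        mode: str = "planar_km") -> VariogramEstimate:
    """Matheron estimator: half mean squared difference per distance bin.

    Default binning: ``n_bins`` equal-width bins up to half the maximum
    pairwise distance (pairs beyond ``max_dist`` are dropped).
    """
    z = np.asarray(residuals, dtype=float)
    coords = np.asarray(locations, dtype=float).reshape(-1, 2)
    n = z.size
    if n < 2:
        raise ValueError("variogram needs at least 2 locations")
    D = pairwise_distances(coords, mode)
    iu = np.triu_indices(n, 1)
    d = D[iu]
    if d.max() == 0:
        raise ValueError("all locations coincide")
    if max_dist is None:
        max_dist = d.max() / 2.0 if n > 2 else d.max()
    sq = (z[iu[0]] - z[iu[1]]) ** 2
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    keep = d <= max_dist
    gamma = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = keep & (which == b)
        counts[b] = sel.sum()
        if counts[b]:
            gamma[b] = 0.5 * sq[sel].mean()
    mids = 0.5 * (edges[:-1] + edges[1:])
    return VariogramEstimate(mids, gamma, counts)


# ---------------------------------------------------------------------------
# Moran's I


def lattice_adjacency(rows: int, cols: int, rook: bool = True) -> np.ndarray:
    """Binary adjacency of a regular lattice (rook or queen contiguity)."""
    n = rows * cols
    W = np.zeros((n, n))
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
            if not rook:
                steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    W[i, rr * cols + cc] = 1.0
    return W


def queen_adjacency(polygons) -> np.ndarray:
    """Queen contiguity from an :class:`~geoqual.io_raster.AdminPolygons`:
    two districts are neighbours when their polygons share any boundary point."""
    geoms = polygons.geometries
    n = len(geoms)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if geoms[i].intersects(geoms[j]):
                W[i, j] = W[j, i] = 1.0
    return W


def morans_i(values, adjacency, n_permutations: int = 999, seed: int = 0,
             alternative: str = "two-sided") -> dict:
    """Moran's I with row-standardized weights and a permutation p-value.

    Returns a JSON-ready dict with the statistic, its permutation-null
    expectation ``-1/(n-1)``, the p-value, and provenance fields.
    """
    z = np.asarray(values, dtype=float)
    W = np.asarray(adjacency, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 units")
    if np.ptp(z) == 0:
        raise ValueError("Moran's I undefined for constant values")
    if W.shape != (n, n):
        raise ValueError("adjacency shape mismatch")
    rs = W.sum(axis=1)
    if (rs == 0).any():
        raise ValueError("every unit needs at least one neighbour")
    Wr = W / rs[:, None]
    s0 = Wr.sum()

    def stat(v):
        d = v - v.mean()
        return (n / s0) * (d @ Wr @ d) / (d @ d)

    I = stat(z)
    rng = np.random.default_rng(seed)
    perm = np.array([stat(rng.permutation(z)) for _ in range(n_permutations)])
    e_null = -1.0 / (n - 1)
    if alternative == "greater":
        extreme = (perm >= I).sum()
    elif alternative == "less":
        extreme = (perm <= I).sum()
    elif alternative == "two-sided":
        extreme = (np.abs(perm - e_null) >= np.abs(I - e_null)).sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + extreme) / (n_permutations + 1)
    return {"I": float(I), "expectation": e_null, "p_value": float(p),
            "n": int(n), "permutations": int(n_permutations), "seed": int(seed),
            "alternative": alternative, "null_mean": float(perm.mean())}
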