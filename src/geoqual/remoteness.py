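"""Decay of data quality with distance to lit settlements.

Distance from each survey cluster to the nearest nighttime-light pixel at or
above a digital-number threshold (DN 15 by default — bright enough for public
streetlights and basic urban infrastructure; a binary settlement raster with
threshold 1 is accepted too), followed by binomial logistic regressions of the
raw indicator counts on a distance transform with country fixed effects.

These regressions consume indicator counts straight from the records — never
modelled surfaces — so the estimated remoteness penalty cannot be an artifact
of regressing model output on one of its own covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geostat import cross_distances
from .io_raster import RasterGrid, cluster_xy

__all__ = [
    "distance_to_lit",
    "DISTANCE_TRANSFORMS",
    "RemotenessModel",
    "RemotenessResults",
    "fit_remoteness_glm",
    "predict_remoteness_curve",
]

DEFAULT_DN_THRESHOLD = 15

DISTANCE_TRANSFORMS = {
    "identity": lambda d: np.asarray(d, dtype=float),
    "log10p1": lambda d: np.log10(np.asarray(d, dtype=float) + 1.0),
    "logp1": lambda d: np.log(np.asarray(d, dtype=float) + 1.0),
}


def distance_to_lit(clusters: pd.DataFrame, dn_raster: RasterGrid,
                    threshold: int = DEFAULT_DN_THRESHOLD) -> np.ndarray:
    """Distance (km) from each cluster to the nearest lit pixel centroid.

    A pixel is lit when its DN is at or above ``threshold``.  Distances are
    planar or great-circle according to the cluster table's coordinate mode.
    Raises when no pixel anywhere reaches the threshold.
    """
    lit = np.isfinite(dn_raster.values) & (dn_raster.values >= threshold)
    if not lit.any():
        raise ValueError(f"no pixel reaches DN threshold {threshold}; "
                         "distance to lit settlement is undefined")
    xx, yy = dn_raster.centroids()
    lit_pts = np.column_stack([xx, yy])[lit.ravel()]
    coords, mode = cluster_xy(clusters)
    D = cross_distances(coords, lit_pts, mode)
    return D.min(axis=1)


@dataclass
class RemotenessResults:
    """Fitted remoteness regression: slope on the distance term plus one
    fixed-effect intercept per country."""

    glm_results: object
    countries: list
    transform: str
    threshold: int

    @property
    def slope(self) -> float:
        return float(self.glm_results.params[-1])

    @property
    def slope_se(self) -> float:
        return float(np.sqrt(self.glm_results.cov_params()[-1, -1]))

    def slope_ci(self, level: float = 0.95):
        from scipy.stats import norm

        zq = norm.ppf(0.5 + level / 2)
        return self.slope - zq * self.slope_se, self.slope + zq * self.slope_se

    def country_effect(self, country) -> float:
        try:
            i = self.countries.index(country)
        except ValueError:
            raise ValueError(f"country {country!r} absent from fit") from None
        return float(self.glm_results.params[i])

    def predict_curve(self, distances_km, country=None, average: bool = False):
        """Predicted indicator proportion along a distance grid.

        Either hold the fixed effect at a reference ``country`` or average the
        curves over all countries in the fit (``average=True``).
        """
        g = DISTANCE_TRANSFORMS[self.transform](distances_km)
        if average:
            curves = [self._curve(g, c) for c in self.countries]
            return np.mean(curves, axis=0)
        if country is None:
            country = self.countries[0]
        return self._curve(g, country)

    def _curve(self, g, country):
        from scipy.special import expit

        return expit(self.country_effect(country) + self.slope * g)

    def summary(self) -> str:
        lo, hi = self.slope_ci()
        lines = [f"Remoteness binomial GLM (transform={self.transform}, "
                 f"DN threshold={self.threshold})",
                 f"  slope on g(distance): {self.slope:.4f} "
                 f"(se {self.slope_se:.4f}, 95% CI [{lo:.4f}, {hi:.4f}])"]
        for c in self.countries:
            lines.append(f"  country {c!r} intercept: {self.country_effect(c):.4f}")
        return "\n".join(lines)


class RemotenessModel:
    """Binomial logistic regression of (y, m) on g(distance) + country FE."""

    def __init__(self, y, m, distances_km, country_ids=None,
                 transform: str = "log10p1", threshold: int = DEFAULT_DN_THRESHOLD):
        self.y = np.asarray(y, dtype=float)
        self.m = np.asarray(m, dtype=float)
        d = np.asarray(distances_km, dtype=float)
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        if transform not in DISTANCE_TRANSFORMS:
            raise ValueError(f"unknown distance transform {transform!r}")
        self.transform = transform
        self.threshold = threshold
        self.g = DISTANCE_TRANSFORMS[transform](d)
        if country_ids is None:
            country_ids = np.zeros(self.y.size, dtype=int)
        self.country_ids = np.asarray(country_ids)
        self.countries = sorted(pd.unique(self.country_ids).tolist())
        vc = pd.Series(self.country_ids).value_counts()
        if (vc < 2).any():
            raise ValueError("each included country needs at least 2 clusters")

    def fit(self) -> RemotenessResults:
        dummies = np.column_stack([(self.country_ids == c).astype(float)
                                   for c in self.countries])
        X = np.column_stack([dummies, self.g])
        endog = np.column_stack([self.y, self.m - self.y])
        glm = sm.GLM(endog, X, family=sm.families.Binomial())
        res = glm.fit()
        if not np.isfinite(res.params).all() or np.sqrt(np.diag(res.cov_params())).max() > 1e3:
            raise RuntimeError(
                "remoteness GLM did not converge cleanly (possible complete "
                f"separation); params={res.params}, se={np.sqrt(np.diag(res.cov_params()))}")
        return RemotenessResults(res, self.countries, self.transform, self.threshold)


def fit_remoteness_glm(counts: pd.DataFrame, distances_km, country_ids=None,
                       transform: str = "log10p1",
                       threshold: int = DEFAULT_DN_THRESHOLD) -> RemotenessResults:
    """Thin wrapper: fit the remoteness GLM from a ClusterCounts table."""
    mask = (counts["m"] >= 1).to_numpy()
    df = counts.loc[mask]
    d = np.asarray(distances_km, dtype=float)[mask]
    c = None if country_ids is None else np.asarray(country_ids)[mask]
    model = RemotenessModel(df["y"], df["m"], d, c,
                            transform=transform, threshold=threshold)
    return model.fit()


def predict_remoteness_curve(fit: RemotenessResults, distances_km, country=None,
                             average: bool = False) -> np.ndarray:
    return fit.predict_curve(distances_km, country=country, average=average)
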