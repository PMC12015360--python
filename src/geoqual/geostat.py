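"""Bayesian binomial geostatistical model with a Matérn spatial random effect.

The model, for cluster locations :math:`s_1,\\dots,s_n`:

.. math::

    Y(s_i) \\mid m(s_i) &\\sim \\mathrm{Binomial}(m(s_i),\\, p(s_i)) \\\\
    \\mathrm{logit}\\, p(s_i) &= x(s_i)^T\\beta + \\omega(s_i) + \\varepsilon(s_i)

with :math:`\\varepsilon(s_i) \\sim N(0, \\sigma_\\varepsilon^2)` an iid nugget and
:math:`\\omega` a zero-mean Gaussian process with Matérn covariance of smoothness
:math:`\\nu = 1` (fixed for identifiability), marginal variance :math:`\\sigma^2`
and scale :math:`\\kappa`, reported through the range :math:`r = \\sqrt{8\\nu}/\\kappa`
— the distance at which the spatial correlation has decayed to
:math:`\\sqrt8\\,K_1(\\sqrt8) \\approx 0.14`.

Priors: a diffuse :math:`N(0, 10^3 I)` on :math:`\\beta` and penalized-complexity
priors on the standard deviations and the range — exponential on
:math:`\\sigma_\\varepsilon` and :math:`\\sigma` calibrated by a tail statement
:math:`P(\\sigma > U) = \\alpha`, and the 2-D PC range prior calibrated by
:math:`P(r < r_0) = \\alpha` with :math:`r_0` 5% of the region size.

Inference works on the collapsed latent vector :math:`u = \\omega + \\varepsilon`
at the data locations (covariance :math:`\\Sigma_\\omega + \\sigma_\\varepsilon^2 I`),
so no sparse-mesh approximation is involved: the Matérn covariance is evaluated
exactly and densely, which is feasible at the few-hundred-cluster scale this
package targets.  Hyperparameters are sampled by adaptive random-walk MCMC on
the Laplace-approximated marginal posterior; latent draws come from the
Gaussian Laplace approximation at each retained hyperparameter state.  With
all hyperparameters held fixed and a small latent dimension, an exact
adaptive-MH sampler over the latent vector is used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_distance",
    "pairwise_distances",
    "cross_distances",
    "MaternParams",
    "matern_cov",
    "matern_correlation",
    "PriorSpec",
    "pc_prior_calibrate",
    "pc_range_calibrate",
    "sample_pc_sd_prior",
    "sample_pc_range_prior",
    "BinomialGeostatModel",
    "GeostatResults",
    "PosteriorSurface",
    "fit_model",
    "posterior_predict",
    "krige_impute",
]

EARTH_RADIUS_KM = 6371.0

#: Matérn nu=1 correlation at d == range: sqrt(8) * K_1(sqrt(8))
CORRELATION_AT_RANGE = float(np.sqrt(8.0) * special.k1(np.sqrt(8.0)))


# ---------------------------------------------------------------------------
# distances


def great_circle_distance(lonlat_a, lonlat_b) -> np.ndarray:
    """Haversine great-circle distance in km between points in degrees.

    Both arguments are ``(..., 2)`` arrays of (longitude, latitude); the
    result broadcasts.  Latitude must lie in [-90, 90] and longitude in
    [-360, 360].
    """
    a = np.asarray(lonlat_a, dtype=float)
    b = np.asarray(lonlat_b, dtype=float)
    for arr in (a, b):
        if (np.abs(arr[..., 1]) > 90).any() or (np.abs(arr[..., 0]) > 360).any():
            raise ValueError("coordinates out of range (lon, lat degrees expected)")
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def cross_distances(coords_a, coords_b, mode: str = "planar_km") -> np.ndarray:
    """All-pairs distance matrix (km) between two coordinate sets."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if mode == "planar_km":
        return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    if mode == "lonlat":
        return great_circle_distance(a[:, None, :], b[None, :, :])
    raise ValueError(f"unknown coordinate mode {mode!r}")


def pairwise_distances(coords, mode: str = "planar_km") -> np.ndarray:
    return cross_distances(coords, coords, mode)


# ---------------------------------------------------------------------------
# Matérn covariance


@dataclass
class MaternParams:
    """Matérn covariance parameters at fixed smoothness ``nu`` (default 1)."""

    sigma2: float
    range_km: float
    nu: float = 1.0

    def __post_init__(self):
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if self.range_km <= 0:
            raise ValueError("range_km must be positive")

    @property
    def kappa(self) -> float:
        """Scale parameter kappa = sqrt(8 nu) / r."""
        return np.sqrt(8.0 * self.nu) / self.range_km


def matern_correlation(d, range_km: float, nu: float = 1.0):
    """Matérn correlation (kd)^nu K_nu(kd) / (2^(nu-1) Gamma(nu)), k = sqrt(8 nu)/r."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    kd = np.sqrt(8.0 * nu) / range_km * d
    out = np.ones_like(kd)
    pos = kd > 0
    out[pos] = (
        kd[pos] ** nu * special.kv(nu, kd[pos]) / (2 ** (nu - 1) * special.gamma(nu))
    )
    # K_nu underflows to 0 for huge arguments; that limit is correct here
    return np.where(np.isfinite(out), out, 0.0)


def matern_cov(d, params: MaternParams) -> np.ndarray:
    """Matérn covariance sigma^2 * correlation(d); sigma^2 at d = 0."""
    return params.sigma2 * matern_correlation(d, params.range_km, params.nu)


# ---------------------------------------------------------------------------
# penalized-complexity priors


def pc_prior_calibrate(U: float, alpha: float) -> float:
    """Rate of the exponential PC prior on a standard deviation.

    Solves ``P(sigma > U) = alpha`` for an Exponential(lambda) prior,
    giving ``lambda = -ln(alpha) / U``.
    """
    if U <= 0:
        raise ValueError("U must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return -np.log(alpha) / U


def pc_range_calibrate(r0: float, alpha: float, dim: int = 2) -> float:
    """Rate of the PC prior on the Matérn range of a ``dim``-dimensional field.

    The PC range prior has survival ``P(r < r0) = exp(-lam * r0^(-dim/2))``;
    solving the tail statement gives ``lam = -ln(alpha) * r0^(dim/2)``.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return -np.log(alpha) * r0 ** (dim / 2.0)


def sample_pc_sd_prior(lam: float, size: int, rng) -> np.ndarray:
    return rng.exponential(1.0 / lam, size=size)


def sample_pc_range_prior(lam: float, size: int, rng, dim: int = 2) -> np.ndarray:
    # r^{-dim/2} ~ Exponential(lam)
    return rng.exponential(1.0 / lam, size=size) ** (-2.0 / dim)


def _log_pc_sd(sigma: float, lam: float) -> float:
    return np.log(lam) - lam * sigma


def _log_pc_range(r: float, lam: float) -> float:
    # density of r when r^{-1} ~ Exp(lam) (2-D field)
    return np.log(lam) - 2.0 * np.log(r) - lam / r


@dataclass
class PriorSpec:
    """Prior specification for the geostatistical model.

    ``range_r0=None`` defers to the default rule: 5% of the region size,
    measured as the maximum pairwise distance among the data locations.
    """

    beta_variance: float = 1e3
    nugget_u: float = 3.0
    nugget_alpha: float = 0.01
    sigma_u: float = 3.0
    sigma_alpha: float = 0.01
    range_r0: float | None = None
    range_alpha: float = 0.01

    def __post_init__(self):
        for a in (self.nugget_alpha, self.sigma_alpha, self.range_alpha):
            if not 0 < a < 1:
                raise ValueError("prior tail probabilities must lie in (0, 1)")
        if self.range_r0 is not None and self.range_r0 <= 0:
            raise ValueError("range_r0 must be positive")

    def resolve_r0(self, coords, mode) -> float:
        if self.range_r0 is not None:
            return self.range_r0
        dmax = pairwise_distances(coords, mode).max()
        if dmax <= 0:
            raise ValueError("cannot set a range prior on coincident locations")
        return 0.05 * dmax


# ---------------------------------------------------------------------------
# model


def _expit(x):
    return special.expit(x)


def _binom_loglik(eta, y, m):
    # log C(m, y) omitted (constant in parameters)
    return float(np.sum(y * eta - m * np.logaddexp(0.0, eta)))


@dataclass
class _LaplaceState:
    zhat: np.ndarray
    chol_H: np.ndarray  # lower Cholesky of the negative Hessian at the mode
    log_marginal: float


class BinomialGeostatModel:
    """Binomial spatial model for per-cluster counts, statsmodels-style.

    Parameters
    ----------
    y, m : array-like of int, shape (n,)
        Successes (records with the error attribute) and records sampled per
        cluster; clusters with ``m == 0`` must be excluded before fitting.
    X : array-like, shape (n, p)
        Design matrix (already log-standardized covariates; include an
        intercept column explicitly).  ``p = 0`` is allowed when the linear
        predictor is fully specified through ``offset``.
    coords : array-like, shape (n, 2)
        Cluster locations, (x, y) km in planar mode or (lon, lat) degrees.
    coord_mode : {"planar_km", "lonlat"}
    priors : PriorSpec, optional
    offset : array-like or float, optional
        Known additive term on the logit scale.
    """

    def __init__(self, y, m, X=None, coords=None, coord_mode="planar_km",
                 priors: PriorSpec | None = None, offset=0.0, exog_names=None):
        self.y = np.asarray(y, dtype=float)
        self.m = np.asarray(m, dtype=float)
        n = self.y.size
        if n < 1 or self.m.size != n:
            raise ValueError("y and m must be equal-length and non-empty")
        if (self.m < 1).any():
            raise ValueError("all clusters must have m >= 1 (drop m == 0 rows)")
        if ((self.y < 0) | (self.y > self.m)).any():
            raise ValueError("need 0 <= y <= m")
        self.X = np.zeros((n, 0)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != n:
            raise ValueError("X and y are misaligned")
        if coords is None:
            raise ValueError("coords are required")
        self.coords = np.asarray(coords, dtype=float).reshape(n, 2)
        self.coord_mode = coord_mode
        self.priors = priors or PriorSpec()
        self.offset = np.broadcast_to(np.asarray(offset, dtype=float), (n,)).copy()
        self.exog_names = list(exog_names) if exog_names is not None \
            else [f"x{j}" for j in range(self.X.shape[1])]

        D = pairwise_distances(self.coords, coord_mode)
        # duplicate locations make the omega covariance singular only without
        # a nugget; collapse is not needed because inference runs on u = omega+eps,
        # but warn so the user knows the omega decomposition ties those points.
        iu = np.triu_indices(n, 1)
        if n > 1 and (D[iu] == 0).any():
            warnings.warn("duplicate cluster locations detected; their spatial "
                          "effects are perfectly correlated", stacklevel=2)
        self._D = D
        self.n = n
        self.p = self.X.shape[1]

    @classmethod
    def from_cluster_counts(cls, counts: pd.DataFrame, covariate_cols=(),
                            add_intercept=True, **kwargs):
        """Build from a ClusterCounts table (columns cluster_id, x, y, y, m...).

        Rows flagged ``excluded`` (empty clusters) are dropped.
        """
        df = counts
        if "excluded" in df.columns:
            df = df.loc[~df["excluded"].astype(bool)]
        if (df["m"] < 1).any():
            df = df.loc[df["m"] >= 1]
        cols = list(covariate_cols)
        Xc = df[cols].to_numpy(dtype=float) if cols else np.zeros((len(df), 0))
        names = list(cols)
        if add_intercept:
            Xc = np.column_stack([np.ones(len(df)), Xc])
            names = ["const"] + names
        from .io_raster import cluster_xy

        coords, mode = cluster_xy(df)
        kwargs.setdefault("coord_mode", mode)
        return cls(df["y"].to_numpy(), df["m"].to_numpy(), Xc, coords,
                   exog_names=names, **kwargs)

    # -- internal: Laplace machinery ------------------------------------

    def _u_cov(self, sigma2, range_km, sigma2_eps):
        C = matern_cov(self._D, MaternParams(sigma2, range_km))
        C[np.diag_indices_from(C)] += sigma2_eps + 1e-10 * max(sigma2, 1.0)
        return C

    def _log_prior_theta(self, theta, lam_s, lam_r, lam_e, fixed):
        """Log prior of free hyperparameters on the log scale (with Jacobians)."""
        lp = 0.0
        t = dict(theta)
        if "log_sigma" in t:
            s = np.exp(t["log_sigma"])
            lp += _log_pc_sd(s, lam_s) + t["log_sigma"]
        if "log_range" in t:
            r = np.exp(t["log_range"])
            lp += _log_pc_range(r, lam_r) + t["log_range"]
        if "log_sigma_eps" in t:
            e = np.exp(t["log_sigma_eps"])
            lp += _log_pc_sd(e, lam_e) + t["log_sigma_eps"]
        return lp

    def _laplace(self, C_u, z0=None, tol=1e-8, max_iter=100) -> _LaplaceState:
        """Newton optimization of the joint over z = (beta, u) and the Laplace
        evidence approximation at the mode."""
        n, p = self.n, self.p
        y, m, X = self.y, self.m, self.X
        tau_b = 1.0 / self.priors.beta_variance
        cF, low = linalg.cho_factor(C_u, lower=True)
        logdet_C = 2.0 * np.sum(np.log(np.diag(cF)))
        Cinv = linalg.cho_solve((cF, low), np.eye(n))

        def obj(z):
            beta, u = z[:p], z[p:]
            eta = self.offset + X @ beta + u
            return (_binom_loglik(eta, y, m)
                    - 0.5 * tau_b * beta @ beta
                    - 0.5 * u @ Cinv @ u)

        z = np.zeros(n + p) if z0 is None else z0.copy()
        f = obj(z)
        for _ in range(max_iter):
            beta, u = z[:p], z[p:]
            eta = self.offset + X @ beta + u
            pr = _expit(eta)
            g_eta = y - m * pr
            W = m * pr * (1 - pr)
            grad = np.concatenate([X.T @ g_eta - tau_b * beta, g_eta - Cinv @ u])
            H = np.zeros((p + n, p + n))
            H[:p, :p] = X.T @ (W[:, None] * X) + tau_b * np.eye(p)
            H[:p, p:] = X.T * W
            H[p:, :p] = (X.T * W).T
            H[p:, p:] = np.diag(W) + Cinv
            cH = linalg.cho_factor(H, lower=True)
            step = linalg.cho_solve(cH, grad)
            t = 1.0
            for _ls in range(30):
                z_new = z + t * step
                f_new = obj(z_new)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            if not np.isfinite(f_new):
                raise FloatingPointError("Laplace optimization diverged")
            done = f_new - f < tol and np.max(np.abs(t * step)) < 1e-6
            z, f = z_new, f_new
            if done:
                break
        # recompute curvature at the mode
        beta, u = z[:p], z[p:]
        eta = self.offset + X @ beta + u
        pr = _expit(eta)
        W = m * pr * (1 - pr)
        H = np.zeros((p + n, p + n))
        H[:p, :p] = X.T @ (W[:, None] * X) + tau_b * np.eye(p)
        H[:p, p:] = X.T * W
        H[p:, :p] = (X.T * W).T
        H[p:, p:] = np.diag(W) + Cinv
        L = linalg.cholesky(H, lower=True)
        logdet_H = 2.0 * np.sum(np.log(np.diag(L)))
        log_marg = (f
                    - 0.5 * logdet_C - 0.5 * n * np.log(2 * np.pi)
                    - 0.5 * p * np.log(2 * np.pi * self.priors.beta_variance)
                    + 0.5 * (n + p) * np.log(2 * np.pi)
                    - 0.5 * logdet_H)
        return _LaplaceState(z, L, log_marg)

    # -- fitting ---------------------------------------------------------

    def fit(self, seed: int, n_draws: int = 1000, n_mcmc: int = 500,
            n_burn: int = 200, fixed_hypers: dict | None = None,
            start: dict | None = None, method: str = "auto",
            n_mh: int = 40000) -> "GeostatResults":
        """Approximate the posterior and return a :class:`GeostatResults`.

        Parameters
        ----------
        seed : int
            Seed for every random element of the sampler (mandatory).
        n_draws : int
            Posterior draws retained (1000 by default).
        n_mcmc, n_burn : int
            Hyperparameter random-walk chain length and burn-in.
        fixed_hypers : dict, optional
            Any of ``sigma2``, ``range_km``, ``sigma2_eps`` to hold fixed.
        method : {"auto", "laplace", "mh"}
            ``"mh"`` runs an exact adaptive Metropolis sampler over the latent
            vector and requires all hyperparameters fixed; ``"auto"`` selects
            it when that holds and the latent dimension is at most 16.
        """
        if self.n < 1:
            raise ValueError("no data")
        rng = np.random.default_rng(seed)
        fixed = dict(fixed_hypers or {})
        free = [k for k in ("sigma2", "range_km", "sigma2_eps") if k not in fixed]
        if method == "auto":
            method = "mh" if (not free and self.n + self.p <= 16) else "laplace"
        if method == "mh" and free:
            raise ValueError("exact MH sampling requires all hyperparameters fixed")

        r0 = None
        lam_s = pc_prior_calibrate(self.priors.sigma_u, self.priors.sigma_alpha)
        lam_e = pc_prior_calibrate(self.priors.nugget_u, self.priors.nugget_alpha)
        if "range_km" in free:
            r0 = self.priors.resolve_r0(self.coords, self.coord_mode)
            lam_r = pc_range_calibrate(r0, self.priors.range_alpha)
        else:
            lam_r = None

        if method == "mh":
            return self._fit_mh(rng, fixed, n_draws, n_mh)

        # ---- Laplace + hyperparameter MCMC ----
        start = dict(start or {})
        theta = {}
        if "sigma2" in free:
            theta["log_sigma"] = 0.5 * np.log(start.get("sigma2", 0.5))
        if "range_km" in free:
            d = self._D[np.triu_indices(self.n, 1)]
            default_r = np.median(d[d > 0]) if self.n > 1 else 1.0
            theta["log_range"] = np.log(start.get("range_km", default_r))
        if "sigma2_eps" in free:
            theta["log_sigma_eps"] = 0.5 * np.log(start.get("sigma2_eps", 0.1))

        def hypers_of(th):
            h = dict(fixed)
            if "log_sigma" in th:
                h["sigma2"] = np.exp(2 * th["log_sigma"])
            if "log_range" in th:
                h["range_km"] = np.exp(th["log_range"])
            if "log_sigma_eps" in th:
                h["sigma2_eps"] = np.exp(2 * th["log_sigma_eps"])
            h.setdefault("sigma2", 0.0)
            h.setdefault("sigma2_eps", 0.0)
            h.setdefault("range_km", 1.0)
            return h

        def target(th, z0=None):
            h = hypers_of(th)
            C = self._u_cov(h["sigma2"], h["range_km"], h["sigma2_eps"])
            st = self._laplace(C, z0=z0)
            return st.log_marginal + self._log_prior_theta(th, lam_s, lam_r, lam_e, fixed), st, h

        keys = sorted(theta)
        if not keys:
            # all hyperparameters fixed, latent too large for exact MH
            lp, st, h = target(theta)
            states = [(st, h)]
            idx = np.zeros(n_draws, dtype=int)
            theta_trace = {}
        else:
            cur = np.array([theta[k] for k in keys])
            lp, st, h = target(dict(zip(keys, cur)))
            scale = 0.3
            kept_states, kept_theta = [], []
            accepts = 0
            for it in range(n_mcmc):
                prop = cur + scale * rng.standard_normal(cur.size)
                try:
                    lp_p, st_p, h_p = target(dict(zip(keys, prop)), z0=st.zhat)
                except (linalg.LinAlgError, FloatingPointError):
                    lp_p = -np.inf
                if np.log(rng.uniform()) < lp_p - lp:
                    cur, lp, st, h = prop, lp_p, st_p, h_p
                    accepts += 1
                if it < n_burn and (it + 1) % 25 == 0:
                    rate = accepts / (it + 1)
                    scale *= np.exp(0.7 * (rate - 0.3))
                    scale = float(np.clip(scale, 0.02, 2.0))
                if it >= n_burn:
                    kept_states.append((st, h))
                    kept_theta.append(cur.copy())
            states = kept_states
            idx = rng.integers(0, len(states), size=n_draws)
            theta_trace = {k: np.array([t[i] for t in kept_theta])
                           for i, k in enumerate(keys)}

        n, p = self.n, self.p
        z_draws = np.empty((n_draws, p + n))
        hyper_draws = {k: np.empty(n_draws) for k in ("sigma2", "range_km", "sigma2_eps")}
        for j, i in enumerate(idx):
            st_i, h_i = states[i]
            xi = rng.standard_normal(p + n)
            z_draws[j] = st_i.zhat + linalg.solve_triangular(st_i.chol_H, xi, lower=True, trans="T")
            for k in hyper_draws:
                hyper_draws[k][j] = h_i[k]
        return GeostatResults(self, z_draws, hyper_draws, seed=seed,
                              method="laplace", r0=r0,
                              diagnostics={"n_mcmc": n_mcmc, "n_burn": n_burn,
                                           "theta_trace": theta_trace})

    def _fit_mh(self, rng, fixed, n_draws, n_mh):
        """Exact adaptive random-walk Metropolis over z = (beta, u)."""
        h = {"sigma2": fixed.get("sigma2", 0.0),
             "range_km": fixed.get("range_km", 1.0),
             "sigma2_eps": fixed.get("sigma2_eps", 0.0)}
        C = self._u_cov(h["sigma2"], h["range_km"], h["sigma2_eps"])
        st = self._laplace(C)
        n, p = self.n, self.p
        tau_b = 1.0 / self.priors.beta_variance
        Cinv = linalg.cho_solve(linalg.cho_factor(C, lower=True), np.eye(n))

        def logpost(z):
            beta, u = z[:p], z[p:]
            eta = self.offset + self.X @ beta + u
            return (_binom_loglik(eta, self.y, self.m)
                    - 0.5 * tau_b * beta @ beta - 0.5 * u @ Cinv @ u)

        # proposal shaped by the Laplace curvature
        z = st.zhat.copy()
        lp = logpost(z)
        scale = 2.4 / np.sqrt(p + n)
        burn = n_mh // 4
        kept = []
        accepts = 0
        for it in range(n_mh):
            xi = rng.standard_normal(p + n)
            prop = z + scale * linalg.solve_triangular(st.chol_H, xi, lower=True, trans="T")
            lp_p = logpost(prop)
            if np.log(rng.uniform()) < lp_p - lp:
                z, lp = prop, lp_p
                accepts += 1
            if it < burn and (it + 1) % 200 == 0:
                rate = accepts / (it + 1)
                scale *= np.exp(0.5 * (rate - 0.3))
            if it >= burn:
                kept.append(z.copy())
        kept = np.asarray(kept)
        take = rng.integers(0, len(kept), size=n_draws) if len(kept) > n_draws else \
            np.resize(np.arange(len(kept)), n_draws)
        z_draws = kept[take]
        hyper_draws = {k: np.full(n_draws, v) for k, v in h.items()}
        return GeostatResults(self, z_draws, hyper_draws, seed=None, method="mh",
                              r0=None, diagnostics={"n_mh": n_mh,
                                                    "accept_rate": accepts / n_mh})


@dataclass
class PosteriorSurface:
    """Per-cell posterior draws of the indicator probability on a grid."""

    draws: np.ndarray  # (n_samples, n_cells)
    coords: np.ndarray  # (n_cells, 2)
    grid_spec: dict | None = None

    def __post_init__(self):
        if ((self.draws <= 0) | (self.draws >= 1)).any():
            self.draws = np.clip(self.draws, 1e-12, 1 - 1e-12)

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)


class GeostatResults:
    """Posterior of a fitted :class:`BinomialGeostatModel`.

    Carries joint draws of the regression coefficients, the combined latent
    effect ``u = omega + eps`` at the data locations, and the hyperparameters;
    exposes summaries, credible intervals and posterior prediction.
    """

    def __init__(self, model, z_draws, hyper_draws, seed, method, r0, diagnostics):
        self.model = model
        self.z_draws = z_draws
        self.beta_draws = z_draws[:, : model.p]
        self.u_draws = z_draws[:, model.p:]
        self.hyper_draws = hyper_draws
        self.seed = seed
        self.method = method
        self.r0 = r0
        self.diagnostics = diagnostics

    @property
    def n_draws(self) -> int:
        return self.z_draws.shape[0]

    @property
    def eta_draws(self) -> np.ndarray:
        return self.model.offset + self.beta_draws @ self.model.X.T + self.u_draws

    @property
    def fitted_p_draws(self) -> np.ndarray:
        return _expit(self.eta_draws)

    @property
    def fitted_p(self) -> np.ndarray:
        """Posterior mean of p at the data locations."""
        return self.fitted_p_draws.mean(axis=0)

    def beta_interval(self, level: float = 0.95) -> np.ndarray:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        return np.quantile(self.beta_draws, [lo, hi], axis=0).T

    def hyper_summary(self) -> pd.DataFrame:
        rows = {}
        for k, v in self.hyper_draws.items():
            rows[k] = {"mean": v.mean(), "sd": v.std(ddof=1) if v.std() > 0 else 0.0,
                       "q2.5": np.quantile(v, 0.025), "q97.5": np.quantile(v, 0.975)}
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        lines = ["Binomial geostatistical model (Matern nu=1)",
                 f"n clusters: {self.model.n}   draws: {self.n_draws}   "
                 f"inference: {self.method}"]
        if self.model.p:
            ci = self.beta_interval()
            lines.append(f"{'coef':>12} {'mean':>10} {'sd':>10} {'[2.5%':>10} {'97.5%]':>10}")
            for j, name in enumerate(self.model.exog_names):
                b = self.beta_draws[:, j]
                lines.append(f"{name:>12} {b.mean():>10.4f} {b.std(ddof=1):>10.4f} "
                             f"{ci[j, 0]:>10.4f} {ci[j, 1]:>10.4f}")
        lines.append("hyperparameters (posterior mean [2.5%, 97.5%]):")
        for k, v in self.hyper_draws.items():
            lines.append(f"  {k:>10}: {v.mean():.4f} [{np.quantile(v, .025):.4f}, "
                         f"{np.quantile(v, .975):.4f}]")
        if self.r0 is not None:
            lines.append(f"  range prior r0 = {self.r0:.2f} km")
        return "\n".join(lines)

    # -- prediction ------------------------------------------------------

    def predict(self, coords, X=None, offset=0.0, n_samples: int = 1000,
                include_nugget: bool = False, seed: int = 0,
                grid_spec: dict | None = None) -> PosteriorSurface:
        """Posterior predictive draws of p at new locations.

        For each retained posterior draw the spatial effect omega at the
        prediction points is simulated conditionally on the latent values at
        the data locations (standard Gaussian conditioning against
        ``u = omega + eps``).  The iid nugget is excluded by default: it is
        read as survey-team noise, not a property of place.
        """
        model = self.model
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        g = coords.shape[0]
        if X is None:
            X = np.zeros((g, 0))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != model.p:
            raise ValueError("prediction covariates not aligned with the fit "
                             "(transform them with the training parameters)")
        if not np.isfinite(X).all():
            raise ValueError("missing grid covariates: impute before predicting")
        offset = np.broadcast_to(np.asarray(offset, dtype=float), (g,))
        rng = np.random.default_rng(seed)
        idx = (np.arange(n_samples) % self.n_draws if n_samples != self.n_draws
               else np.arange(n_samples))
        D_gd = cross_distances(coords, model.coords, model.coord_mode)
        D_gg = pairwise_distances(coords, model.coord_mode)

        thetas = np.column_stack([self.hyper_draws[k] for k in
                                  ("sigma2", "range_km", "sigma2_eps")])
        out = np.empty((n_samples, g))
        uniq, inv = np.unique(thetas[idx], axis=0, return_inverse=True)
        for t, (s2, r, s2e) in enumerate(uniq):
            sel = np.nonzero(inv == t)[0]
            if s2 <= 1e-14:
                for j in sel:
                    eta = offset + X @ self.beta_draws[idx[j]]
                    if include_nugget and s2e > 0:
                        eta = eta + rng.normal(0, np.sqrt(s2e), size=g)
                    out[j] = _expit(eta)
                continue
            mp = MaternParams(s2, r)
            C_dd = matern_cov(model._D, mp)
            S = C_dd + (s2e + 1e-10 * max(s2, 1.0)) * np.eye(model.n)
            cS = linalg.cho_factor(S, lower=True)
            C_gd = matern_cov(D_gd, mp)
            B = linalg.cho_solve(cS, C_gd.T).T          # C_gd S^-1
            cond_cov = matern_cov(D_gg, mp) - B @ C_gd.T
            cond_cov[np.diag_indices_from(cond_cov)] += 1e-10 * s2
            L = linalg.cholesky((cond_cov + cond_cov.T) / 2, lower=True)
            for j in sel:
                u = self.u_draws[idx[j]]
                omega = B @ u + L @ rng.standard_normal(g)
                eta = offset + X @ self.beta_draws[idx[j]] + omega
                if include_nugget and s2e > 0:
                    eta = eta + rng.normal(0, np.sqrt(s2e), size=g)
                out[j] = _expit(eta)
        return PosteriorSurface(out, coords, grid_spec)

    def predict_surface(self, grid, X_grid, n_samples: int = 1000,
                        include_nugget: bool = False, seed: int = 0) -> PosteriorSurface:
        """Predict on every cell of a :class:`~geoqual.io_raster.RasterGrid`."""
        xx, yy = grid.centroids()
        coords = np.column_stack([xx, yy])
        return self.predict(coords, X_grid, n_samples=n_samples,
                            include_nugget=include_nugget, seed=seed,
                            grid_spec=grid.grid_spec())


# ---------------------------------------------------------------------------
# spec-surface wrappers


def fit_model(counts: pd.DataFrame, covariate_cols=(), priors: PriorSpec | None = None,
              seed: int = 0, **fit_kwargs) -> GeostatResults:
    """Fit the geostatistical model from a ClusterCounts table (thin wrapper
    around :class:`BinomialGeostatModel`)."""
    model = BinomialGeostatModel.from_cluster_counts(
        counts, covariate_cols, priors=priors)
    if model.n < 10 and "fixed_hypers" not in fit_kwargs:
        raise ValueError("need at least 10 clusters to estimate hyperparameters")
    return model.fit(seed=seed, **fit_kwargs)


def posterior_predict(fit: GeostatResults, grid, X_grid, n_samples: int = 1000,
                      include_nugget: bool = False, seed: int = 0) -> PosteriorSurface:
    return fit.predict_surface(grid, X_grid, n_samples=n_samples,
                               include_nugget=include_nugget, seed=seed)


# ---------------------------------------------------------------------------
# ordinary kriging (covariate imputation)


def _fit_exponential_variogram(d, gamma):
    """Least-squares fit of gamma(h) = c0 + c1 (1 - exp(-h / a))."""
    gmax = gamma.max()
    dmax = d.max()
    if gmax <= 0:
        return 0.0, 0.0, max(dmax, 1.0)

    def f(h, c0, c1, a):
        return c0 + c1 * (1 - np.exp(-h / a))

    try:
        popt, _ = optimize.curve_fit(
            f, d, gamma, p0=[0.0, gmax, max(dmax / 3, 1e-6)],
            bounds=([0, 0, 1e-9], [gmax + 1e-12, 10 * gmax + 1e-9, 100 * dmax]),
            maxfev=5000)
        return tuple(popt)
    except RuntimeError:
        return 0.0, gmax, max(dmax / 3, 1e-6)


def krige_impute(known_coords, values, query_coords, mode: str = "planar_km"):
    """Ordinary kriging of covariate values from nearby known locations.

    An exponential variogram is fitted to the empirical (Matheron) variogram of
    the known values; the kriging system uses gamma(0) = 0 on the diagonal, so
    predictions honour the data exactly at known locations.
    """
    known_coords = np.asarray(known_coords, dtype=float).reshape(-1, 2)
    values = np.asarray(values, dtype=float)
    query_coords = np.asarray(query_coords, dtype=float).reshape(-1, 2)
    n = known_coords.shape[0]
    if n < 3:
        raise ValueError("kriging needs at least 3 known points")
    D = pairwise_distances(known_coords, mode)
    iu = np.triu_indices(n, 1)
    if (D[iu] == 0).any():
        raise ValueError("coincident known points make the kriging system singular")
    if np.ptp(values) == 0:
        return np.full(query_coords.shape[0], values[0])

    from .exploratory import empirical_variogram
    vg = empirical_variogram(values, known_coords, mode=mode)
    ok = vg.pair_counts > 0
    c0, c1, a = _fit_exponential_variogram(vg.bin_mid[ok], vg.semivariance[ok])

    def gamma(h):
        out = c0 + c1 * (1 - np.exp(-h / a))
        return np.where(h == 0, 0.0, out)

    A = np.ones((n + 1, n + 1))
    A[:n, :n] = gamma(D)
    A[n, n] = 0.0
    Dq = cross_distances(query_coords, known_coords, mode)
    b = np.ones((n + 1, Dq.shape[0]))
    b[:n] = gamma(Dq).T
    try:
        w = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular kriging system") from e
    return w[:n].T @ values
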