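"""Independent brute-force oracles used by the test-suite.

These deliberately avoid the package's inference code paths: the posterior
oracle integrates the binomial-Gaussian posterior by dense Gauss-Hermite
quadrature over the (tiny) latent space, and the Moran oracle evaluates the
statistic from its definition with explicit loops.
"""

from itertools import product

import numpy as np
from scipy import linalg, special

from geoqual.geostat import MaternParams, matern_cov, pairwise_distances


def quadrature_posterior_p(y, m, coords, sigma2, range_km, sigma2_eps,
                           offset=0.0, n_nodes=40, mode="planar_km"):
    """Posterior mean and sd of p at each cluster by tensor Gauss-Hermite
    quadrature over the latent field u = omega + eps (dimension <= 4)."""
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    n = y.size
    assert n <= 4, "oracle is exponential in n"
    D = pairwise_distances(np.asarray(coords, dtype=float), mode)
    C = matern_cov(D, MaternParams(sigma2, range_km)) + sigma2_eps * np.eye(n)
    L = linalg.cholesky(C, lower=True)
    nodes, wts = np.polynomial.hermite_e.hermegauss(n_nodes)
    off = np.broadcast_to(np.asarray(offset, dtype=float), (n,))
    # full tensor grid, vectorized: Z is (n_nodes^n, n)
    grids = np.meshgrid(*([nodes] * n), indexing="ij")
    Z = np.column_stack([g.ravel() for g in grids])
    wgrids = np.meshgrid(*([wts] * n), indexing="ij")
    w = np.prod(np.stack([g.ravel() for g in wgrids]), axis=0)
    eta = off[None, :] + Z @ L.T
    ll = np.sum(y * eta - m * np.logaddexp(0.0, eta), axis=1)
    f = w * np.exp(ll - ll.max())
    p = special.expit(eta)
    den = f.sum()
    mean = f @ p / den
    mean2 = f @ (p * p) / den
    sd = np.sqrt(np.maximum(mean2 - mean ** 2, 0.0))
    return mean, sd


def morans_i_bruteforce(values, W_rowstd):
    """Moran's I from its definition, with explicit loops."""
    z = np.asarray(values, dtype=float)
    n = z.size
    zbar = z.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W_rowstd[i, j] * (z[i] - zbar) * (z[j] - zbar)
            s0 += W_rowstd[i, j]
    den = ((z - zbar) ** 2).sum()
    return (n / s0) * num / den


def bilinear_point(x, y, x00, y00, step, grid_vals):
    """Hand evaluation of bilinear interpolation on a 2x2 patch of centroids.

    ``grid_vals`` is [[v_at(x00,y00), v_at(x00+step,y00)],
                      [v_at(x00,y00-step), ...]] with y decreasing downward.
    """
    fx = (x - x00) / step
    fy = (y00 - y) / step
    v = ((1 - fy) * ((1 - fx) * grid_vals[0][0] + fx * grid_vals[0][1])
         + fy * ((1 - fx) * grid_vals[1][0] + fx * grid_vals[1][1]))
    return v
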