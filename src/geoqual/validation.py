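"""k-fold cross-validation of the geostatistical model.

Validation runs on the probability scale: observed fold values are the raw
per-cluster proportions y/m, predictions are posterior means of p at the
held-out locations.  Four metrics are computed per fold and then averaged
across the k folds (never pooled):

* percentage bias  = 100 * sum(phat - p) / sum(p)
* RMSE             = sqrt(mean((phat - p)^2))
* MAE              = mean(|phat - p|)
* Pearson correlation of phat with p

Perfect predictions give (0, 0, 0); the correlation is then reported as 1
when both vectors have positive variance and as undefined (NaN) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geostat import BinomialGeostatModel, PriorSpec

__all__ = ["CvMetrics", "cv_metrics", "kfold_indices", "cross_validate"]


@dataclass
class CvMetrics:
    pct_bias: float
    rmse: float
    mae: float
    pearson_r: float
    n: int
    k: int = 1
    per_fold: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"pct_bias": self.pct_bias, "rmse": self.rmse, "mae": self.mae,
                "pearson_r": self.pearson_r, "n": self.n, "k": self.k}


def cv_metrics(observed, predicted) -> CvMetrics:
    """Evaluation metrics between observed and predicted proportions."""
    p = np.asarray(observed, dtype=float)
    ph = np.asarray(predicted, dtype=float)
    if p.size == 0 or p.shape != ph.shape:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    if p.sum() == 0:
        raise ValueError("percent bias undefined when observed sum is zero")
    diff = ph - p
    pct_bias = 100.0 * diff.sum() / p.sum()
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    mae = float(np.mean(np.abs(diff)))
    if np.ptp(p) > 0 and np.ptp(ph) > 0:
        r = float(np.corrcoef(p, ph)[0, 1])
    elif np.allclose(p, ph):
        # perfect but degenerate prediction: correlation of a constant is
        # undefined; report 1 only when variance exists on both sides
        r = float("nan") if np.ptp(p) == 0 else 1.0
    else:
        r = float("nan")
    return CvMetrics(float(pct_bias), rmse, mae, r, n=p.size)


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition of n locations into k disjoint folds."""
    if not 2 <= k <= n:
        raise ValueError("need n >= k >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(order, k)]


def cross_validate(counts: pd.DataFrame, covariate_cols=(), priors: PriorSpec | None = None,
                   k: int = 10, seed: int = 0, include_nugget: bool = False,
                   **fit_kwargs) -> CvMetrics:
    """k-fold CV of the geostatistical model (default k = 10).

    Folds are seeded random splits of the data locations.  Each fold is held
    out in turn; the model is refitted on the remainder and the held-out
    clusters' raw proportions y/m are compared with the posterior-mean
    predictions.  Metrics are averaged over folds; a fold whose observed sum
    is zero has undefined %Bias and is flagged NaN for that metric.
    """
    from .io_raster import cluster_xy

    df = counts.loc[counts["m"] >= 1].reset_index(drop=True)
    n = len(df)
    folds = kfold_indices(n, k, seed)
    coords, mode = cluster_xy(df)
    fit_kwargs.setdefault("n_draws", 200)
    rows = []
    for fi, hold in enumerate(folds):
        train = df.drop(index=hold)
        test = df.loc[hold]
        model = BinomialGeostatModel.from_cluster_counts(
            train, covariate_cols, priors=priors)
        res = model.fit(seed=seed + 1000 + fi, **fit_kwargs)
        Xt = np.column_stack([np.ones(len(test))]
                             + [test[c].to_numpy(dtype=float) for c in covariate_cols])
        surf = res.predict(coords[hold], Xt, n_samples=res.n_draws,
                           include_nugget=include_nugget, seed=seed + 2000 + fi)
        obs = (test["y"] / test["m"]).to_numpy()
        pred = surf.mean
        if obs.sum() == 0:
            rows.append({"fold": fi, "pct_bias": np.nan, "rmse": np.nan,
                         "mae": np.nan, "pearson_r": np.nan, "n": len(test),
                         "flag": "zero observed sum"})
            continue
        mm = cv_metrics(obs, pred)
        rows.append({"fold": fi, **mm.to_dict(), "flag": ""})
    per_fold = pd.DataFrame(rows)
    mean_of = lambda c: float(per_fold[c].mean())
    return CvMetrics(mean_of("pct_bias"), mean_of("rmse"), mean_of("mae"),
                     mean_of("pearson_r"), n=n, k=k, per_fold=per_fold)
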