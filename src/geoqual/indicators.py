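"""Survey data-quality indicators computed from individual-level records.

Three indicators, each yielding per-cluster counts (y, m):

age heaping
    Share of reported ages ending in 5 or 0 among adults aged 23-62
    (inclusive).  This is the Whipple-index window: 8 of the 40 ages in it
    end in 0/5, so the natural baseline absent any digit preference is
    exactly 20%, and values above it indicate heaping.
incomplete age
    Share of interviewed women aged 15-49 (inclusive) with the birth month
    or the birth year missing.
flagged HAZ
    Share of anthropometry-eligible children whose height-for-age z-score is
    missing or biologically implausible — strictly outside the WHO
    plausibility window [-6, +6]; boundary values count as plausible.  The
    denominator is all listed eligible children, so missing heights appear
    in both y and m.

Clusters where no record is eligible are carried with ``m = 0`` and an
``excluded`` flag rather than silently dropped; model fitting skips them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RecordTable",
    "compute_age_heaping",
    "compute_incomplete_age",
    "compute_flagged_haz",
    "compute_indicator",
    "attach_locations",
    "HAZ_WINDOW",
    "AGE_HEAPING_BOUNDS",
    "WOMEN_AGE_BOUNDS",
]

HAZ_WINDOW = (-6.0, 6.0)
AGE_HEAPING_BOUNDS = (23, 62)
WOMEN_AGE_BOUNDS = (15, 49)

ROSTER_COLUMNS = ("cluster_id", "reported_age")
WOMEN_COLUMNS = ("cluster_id", "age", "birth_month_missing", "birth_year_missing")
CHILD_COLUMNS = ("cluster_id", "haz", "height_measured")


@dataclass
class RecordTable:
    """Individual-level survey rows: household roster, women, children.

    Any subset of the three tables may be present; CSV round trips use the
    documented column names (``ROSTER_COLUMNS`` etc.).
    """

    roster: pd.DataFrame | None = None
    women: pd.DataFrame | None = None
    children: pd.DataFrame | None = None

    def __post_init__(self):
        if self.roster is not None:
            ages = self.roster["reported_age"]
            if (ages < 0).any() or (ages != ages.astype(int)).any():
                raise ValueError("roster ages must be non-negative integers")

    def write_csv(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in (("roster", self.roster), ("women", self.women),
                         ("children", self.children)):
            if df is not None:
                df.to_csv(out_dir / f"records_{name}.csv", index=False)

    @classmethod
    def read_csv(cls, in_dir) -> "RecordTable":
        in_dir = Path(in_dir)
        kw = {}
        for name in ("roster", "women", "children"):
            p = in_dir / f"records_{name}.csv"
            if p.exists():
                kw[name] = pd.read_csv(p)
        return cls(**kw)


def _to_counts(df: pd.DataFrame, eligible: np.ndarray, error: np.ndarray,
               indicator: str) -> pd.DataFrame:
    """Aggregate record-level eligibility/error flags to per-cluster (y, m)."""
    tmp = pd.DataFrame({
        "cluster_id": df["cluster_id"].to_numpy(),
        "m": eligible.astype(int),
        "y": (eligible & error).astype(int),
    })
    out = (tmp.groupby("cluster_id", sort=True)[["y", "m"]].sum().reset_index())
    out["indicator"] = indicator
    out["excluded"] = out["m"] == 0
    return out


def compute_age_heaping(records: RecordTable) -> pd.DataFrame:
    """Per-cluster counts for the age-heaping indicator (terminal digit 0/5
    among roster ages 23-62 inclusive)."""
    if records.roster is None:
        raise ValueError("roster rows are required for age heaping")
    df = records.roster
    age = df["reported_age"].to_numpy(dtype=int)
    lo, hi = AGE_HEAPING_BOUNDS
    eligible = (age >= lo) & (age <= hi)
    error = age % 5 == 0
    return _to_counts(df, eligible, error, "age_heaping")


def compute_incomplete_age(records: RecordTable) -> pd.DataFrame:
    """Per-cluster counts of women 15-49 with birth month or year missing."""
    if records.women is None:
        raise ValueError("women rows are required for incomplete age")
    df = records.women
    age = df["age"].to_numpy(dtype=int)
    lo, hi = WOMEN_AGE_BOUNDS
    eligible = (age >= lo) & (age <= hi)
    error = (df["birth_month_missing"].to_numpy(dtype=bool)
             | df["birth_year_missing"].to_numpy(dtype=bool))
    return _to_counts(df, eligible, error, "incomplete_age")


def compute_flagged_haz(records: RecordTable) -> pd.DataFrame:
    """Per-cluster counts of children with missing or implausible HAZ.

    A child is flagged when HAZ is missing or lies strictly outside
    [-6, +6]; z-scores of exactly +-6 are plausible.
    """
    if records.children is None:
        raise ValueError("child rows are required for flagged HAZ")
    df = records.children
    haz = df["haz"].to_numpy(dtype=float)
    eligible = np.ones(len(df), dtype=bool)
    missing = ~np.isfinite(haz)
    lo, hi = HAZ_WINDOW
    implausible = np.where(missing, True, (haz < lo) | (haz > hi))
    return _to_counts(df, eligible, implausible, "flagged_haz")


_DISPATCH = {
    "age_heaping": compute_age_heaping,
    "incomplete_age": compute_incomplete_age,
    "flagged_haz": compute_flagged_haz,
}


def compute_indicator(records: RecordTable, indicator: str) -> pd.DataFrame:
    try:
        return _DISPATCH[indicator](records)
    except KeyError:
        raise ValueError(f"unknown indicator {indicator!r}") from None


def attach_locations(counts: pd.DataFrame, clusters: pd.DataFrame) -> pd.DataFrame:
    """Merge cluster coordinates (and any covariate columns) onto counts."""
    keep = [c for c in clusters.columns if c not in ("y", "m", "indicator")]
    out = counts.merge(clusters[keep], on="cluster_id", how="left",
                       validate="one_to_one")
    coord_cols = [c for c in ("x_km", "y_km", "lon", "lat") if c in out.columns]
    if not coord_cols or out[coord_cols].isna().any().any():
        raise ValueError("clusters missing coordinates")
    return out
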