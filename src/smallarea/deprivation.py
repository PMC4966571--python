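"""Pooled-city socioeconomic deprivation index.

Five census indicators (unemployment, manual work, temporary work, low
education overall and among the young, all percentages) are standardized
over the tracts of *all* cities pooled — pooling is what makes index values
comparable between cities — and combined into a single score using the
first principal component's loadings as weights.  Higher values mean
greater deprivation (the sign is fixed so the index correlates positively
with unemployment).  Tertiles of the pooled index drive the rate
comparison tables; septiles drive the map tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

INDICATOR_COLUMNS = [
    "unemployment_pct",
    "manual_workers_pct",
    "temporary_workers_pct",
    "low_education_pct",
    "low_education_young_pct",
]

__all__ = [
    "INDICATOR_COLUMNS",
    "DeprivationIndex",
    "normalize_indicators",
    "build_index",
    "assign_quantile_groups",
]


@dataclass
class DeprivationIndex:
    """Per-tract deprivation score with pooled tertile labels and PCA metadata."""

    table: pd.DataFrame  # columns: city, tract, x, tertile
    loadings: np.ndarray  # unit-norm first-axis weights, one per indicator
    variance_explained: float  # fraction of indicator variance on the first axis
    correlations: pd.Series  # Pearson r between the index and each raw indicator


def _check_indicator_frame(ind: pd.DataFrame) -> None:
    missing = [c for c in ("city", "tract", *INDICATOR_COLUMNS) if c not in ind.columns]
    if missing:
        raise ValueError(f"indicator table missing columns: {missing}")
    vals = ind[INDICATOR_COLUMNS]
    if vals.isna().any().any():
        raise ValueError("indicator table contains missing values")
    if ((vals < 0) | (vals > 100)).any().any():
        raise ValueError("indicators must be percentages in [0, 100]")


def normalize_indicators(ind: pd.DataFrame) -> pd.DataFrame:
    """Standardize each indicator to mean 0, SD 1 over all tracts pooled.

    Uses the population SD (denominator ``n``).  Raises if any indicator is
    constant, naming the offending column.
    """
    _check_indicator_frame(ind)
    if len(ind) < 2:
        raise ValueError("need at least 2 tracts to standardize")
    out = ind.copy()
    for col in INDICATOR_COLUMNS:
        v = ind[col].to_numpy(float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(f"indicator {col!r} has zero variance")
        out[col] = (v - v.mean()) / sd
    return out


def build_index(standardized: pd.DataFrame) -> DeprivationIndex:
    """First-principal-component deprivation index from standardized indicators.

    The index is the standardized indicator matrix projected on the
    unit-norm first eigenvector of its correlation matrix (equivalently a
    PCA on the pre-standardized columns).  Also reports the fraction of
    variance the first axis explains and the correlation of the index with
    each indicator.
    """
    missing = [c for c in ("city", "tract", *INDICATOR_COLUMNS) if c not in standardized.columns]
    if missing:
        raise ValueError(f"indicator table missing columns: {missing}")
    z = standardized[INDICATOR_COLUMNS].to_numpy(float)
    n, p = z.shape
    if n < p:
        raise ValueError(f"need at least {p} tracts for a {p}-indicator PCA, got {n}")
    pca = PCA(n_components=p).fit(z)
    loadings = pca.components_[0].copy()
    x = z @ loadings
    # sign convention: greater deprivation (unemployment) => larger index
    unemp = z[:, INDICATOR_COLUMNS.index("unemployment_pct")]
    if np.corrcoef(x, unemp)[0, 1] < 0:
        loadings = -loadings
        x = -x
    tert = assign_quantile_groups(x, 3)
    table = standardized[["city", "tract"]].copy()
    table["x"] = x
    table["tertile"] = [f"T{g}" for g in tert]
    corr = pd.Series(
        {col: float(np.corrcoef(x, standardized[col].to_numpy(float))[0, 1])
         for col in INDICATOR_COLUMNS}
    )
    return DeprivationIndex(
        table=table,
        loadings=loadings,
        variance_explained=float(pca.explained_variance_ratio_[0]),
        correlations=corr,
    )


def assign_quantile_groups(values, k: int) -> np.ndarray:
    """Quantile-group labels ``1..k`` (1 = lowest values).

    Cut points are the ``i/k`` empirical quantiles (linear, "type 7"
    interpolation); intervals are left-closed, so a value exactly equal to
    a cut point goes to the *lower* group.  Deterministic in the input
    (labels depend only on each value, not on input order).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > v.size:
        raise ValueError(f"cannot split {v.size} values into {k} quantile groups")
    cuts = np.quantile(v, [i / k for i in range(1, k)], method="linear")
    return 1 + (v[:, None] > cuts[None, :]).sum(axis=1)
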