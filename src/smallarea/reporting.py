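"""Output surfaces: septile map tables, tertile comparison tables, forest data.

Display rounding follows the printed-table convention — rates and
differences to whole numbers, ratios to two decimals, percentages to whole
numbers, ties rounded half-up (away from zero) — and is applied only at
write time; everything upstream stays at full precision.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .deprivation import assign_quantile_groups
from .models import RRSummary

__all__ = [
    "round_half_up",
    "make_septile_table",
    "format_comparison",
    "emit_tables",
    "forest_table",
    "TABLE_DISPLAY_COLUMNS",
]

TABLE_DISPLAY_COLUMNS = [
    "city", "sex",
    "asmr_t1_p1", "asmr_t3_p1", "ratio_p1", "diff_p1",
    "asmr_t1_p2", "asmr_t3_p2", "ratio_p2", "diff_p2",
    "diff_t1", "diff_t3", "pct_reduction_t1", "pct_reduction_t3",
]
_RATIO_COLS = ("ratio_p1", "ratio_p2")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal rounding with ties going away from zero (printed-table style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def make_septile_table(ssmr_table: pd.DataFrame, index) -> pd.DataFrame:
    """Septile labels for smoothed SMRs and the deprivation index, per city.

    Smoothed-SMR septiles are assigned within (city, period) — each
    period's geography is mapped on its own scale — while deprivation
    septiles are within city only (one index for both periods).  Emits a
    long-format table joinable to any tract geometry.
    """
    required = {"city", "tract", "period", "ssmr"}
    missing = required - set(ssmr_table.columns)
    if missing:
        raise ValueError(f"ssmr table missing columns: {sorted(missing)}")
    table = index.table if hasattr(index, "table") else index
    out = ssmr_table.copy()
    out["ssmr_septile"] = 0
    for (city, period), sub in out.groupby(["city", "period"]):
        if len(sub) < 7:
            raise ValueError(
                f"city {city!r} period {period} has {len(sub)} tracts < 7; "
                "use a smaller number of quantile groups"
            )
        if np.ptp(sub["ssmr"].to_numpy()) == 0:
            warnings.warn(
                f"city {city!r} period {period}: all smoothed SMRs identical; "
                "septiles collapse to a single group",
                stacklevel=2,
            )
        out.loc[sub.index, "ssmr_septile"] = assign_quantile_groups(
            sub["ssmr"].to_numpy(), 7
        )
    dep = table[["city", "tract", "x"]].copy()
    dep["deprivation_septile"] = 0
    for city, sub in dep.groupby("city"):
        dep.loc[sub.index, "deprivation_septile"] = assign_quantile_groups(
            sub["x"].to_numpy(), 7
        )
    out = out.merge(
        dep[["city", "tract", "deprivation_septile"]], on=["city", "tract"], how="left"
    )
    if out["deprivation_septile"].isna().any():
        raise ValueError("deprivation index missing tracts present in the sSMR table")
    return out


def format_comparison(comparison: pd.DataFrame) -> pd.DataFrame:
    """Apply display rounding to a full-precision tertile comparison table."""
    out = comparison[TABLE_DISPLAY_COLUMNS].copy()
    for col in TABLE_DISPLAY_COLUMNS[2:]:
        nd = 2 if col in _RATIO_COLS else 0
        out[col] = comparison[col].map(lambda v, nd=nd: round_half_up(v, nd))
        if nd == 0:
            out[col] = out[col].astype(int)
    return out


def emit_tables(comparison: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Write the display-rounded comparison table as CSV; returns what was written."""
    path = Path(path)
    if len(comparison) == 0:
        header = pd.DataFrame(columns=TABLE_DISPLAY_COLUMNS)
        header.to_csv(path, index=False)
        return header
    disp = format_comparison(comparison)
    disp.to_csv(path, index=False)
    return disp


def forest_table(summary: RRSummary) -> pd.DataFrame:
    """Forest-plot data: per-city RRs with intervals plus a global row (Model 3)."""
    rows = summary.per_city.copy()
    if summary.global_summary is not None:
        g = summary.global_summary.iloc[0]
        global_row = pd.DataFrame(
            [{"city": "GLOBAL", "sex": g["sex"],
              "rr_p1": g["rrg_p1"], "rr_p1_lo": g["rrg_p1_lo"], "rr_p1_hi": g["rrg_p1_hi"],
              "rr_p2": g["rrg_p2"], "rr_p2_lo": g["rrg_p2_lo"], "rr_p2_hi": g["rrg_p2_hi"],
              "pr_delta": g["pr_delta_global"], "category": g["category"]}]
        )
        rows = pd.concat([rows, global_row], ignore_index=True)
    return rows
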