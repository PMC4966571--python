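"""Direct and indirect age standardization of small-area mortality.

Direct standardization weights local age-specific rates by a fixed
reference population's age structure, yielding comparable age-standardized
mortality rates (ASMR, per 100 000).  Indirect standardization applies
reference age-specific rates to local age-specific populations, yielding
expected death counts ``E`` — the offsets of the Poisson spatial models.

Two reference-rate modes are supported for the expected counts:

``city_period1``
    rates derived from each city's own first-period aggregate, so a tract's
    ``E`` answers "how many deaths if this tract died at the city's
    period-1 rates"; by construction the city's period-1 expected total
    equals its observed total (the smoothed-SMR convention).
``national``
    a supplied national schedule, making relative risks comparable across
    cities and periods (the ecological-regression convention).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .reference import reference_rate_lookup, reference_weights, validate_reference

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["city", "tract", "sex", "age_group", "period", "deaths", "population"]

__all__ = [
    "COUNT_COLUMNS",
    "validate_counts",
    "direct_asmr",
    "tertile_table",
    "comparison_from_asmr",
    "expected_counts",
]


def validate_counts(counts: pd.DataFrame) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    if (counts["deaths"] < 0).any() or (counts["population"] < 0).any():
        raise ValueError("deaths and population must be non-negative")
    bad = (counts["population"] == 0) & (counts["deaths"] > 0)
    if bad.any():
        raise ValueError(f"{bad.sum()} strata have deaths > 0 with population 0")


def direct_asmr(selection: pd.DataFrame, reference: pd.DataFrame, sex: str | None = None) -> float:
    """Directly age-standardized mortality rate (per 100 000) of a selection.

    ``selection`` holds the stratified counts of the pooled tracts of one
    (city, sex, period) — or any other pooling the caller intends.  Age
    groups with zero pooled population contribute zero to the weighted sum
    and are logged.
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    validate_reference(reference)
    if sex is None:
        sexes = selection["sex"].unique()
        if len(sexes) != 1:
            raise ValueError("selection spans several sexes; pass sex= explicitly")
        sex = sexes[0]
    w = reference_weights(reference, sex)
    agg = selection.groupby("age_group")[["deaths", "population"]].sum()
    present = agg.index
    uncovered = present.difference(w.index)
    if len(uncovered):
        raise ValueError(f"reference weights missing age groups: {sorted(uncovered)}")
    pop = agg["population"].to_numpy(float)
    deaths = agg["deaths"].to_numpy(float)
    rate = np.zeros_like(pop)
    nz = pop > 0
    rate[nz] = deaths[nz] / pop[nz]
    if (~nz).any():
        logger.warning(
            "direct_asmr: %d age group(s) with zero population contribute 0", (~nz).sum()
        )
    return float((w.loc[present].to_numpy(float) * rate).sum() * 1e5)


def comparison_from_asmr(asmr: pd.DataFrame) -> pd.DataFrame:
    """Derive the comparison columns from tertile ASMRs (full precision).

    ``asmr`` needs columns ``asmr_t1_p1, asmr_t3_p1, asmr_t1_p2,
    asmr_t3_p2`` (rates per 100 000 for the lowest/highest deprivation
    tertiles in each period); identifier columns are carried through.
    Adds, per period, the T3/T1 ratio and T3-T1 difference, and across
    periods the per-tertile reduction and percentage reduction (relative
    to that tertile's first-period rate).
    """
    out = asmr.copy()
    for p in (1, 2):
        out[f"ratio_p{p}"] = out[f"asmr_t3_p{p}"] / out[f"asmr_t1_p{p}"]
        out[f"diff_p{p}"] = out[f"asmr_t3_p{p}"] - out[f"asmr_t1_p{p}"]
    for g in (1, 3):
        out[f"diff_t{g}"] = out[f"asmr_t{g}_p1"] - out[f"asmr_t{g}_p2"]
        out[f"pct_reduction_t{g}"] = 100.0 * out[f"diff_t{g}"] / out[f"asmr_t{g}_p1"]
    return out


def tertile_table(
    counts: pd.DataFrame, index, reference: pd.DataFrame
) -> pd.DataFrame:
    """ASMR comparison of extreme deprivation tertiles, per (city, sex).

    Pools the T1 (least deprived) and T3 (most deprived) tracts of each
    city, computes their direct ASMRs per period, and derives ratios,
    differences and cross-period reductions.  All values are kept at full
    precision; display rounding happens only in the reporting layer.
    """
    validate_counts(counts)
    table = index.table if hasattr(index, "table") else index
    if "tertile" not in table.columns:
        raise ValueError("deprivation index has no tertile assignment")
    periods = sorted(counts["period"].unique())
    if periods != [1, 2]:
        raise ValueError(f"both periods 1 and 2 required, got {periods}")
    merged = counts.merge(table[["city", "tract", "tertile"]], on=["city", "tract"], how="left")
    if merged["tertile"].isna().any():
        missing = merged.loc[merged["tertile"].isna(), ["city", "tract"]].drop_duplicates()
        raise ValueError(f"{len(missing)} tracts lack a tertile assignment")
    rows = []
    for (city, sex), sub in merged.groupby(["city", "sex"], sort=True):
        row = {"city": city, "sex": sex}
        for g in (1, 3):
            for p in (1, 2):
                sel = sub[(sub["tertile"] == f"T{g}") & (sub["period"] == p)]
                if len(sel) == 0:
                    raise ValueError(f"city {city!r} has no T{g} tracts in period {p}")
                row[f"asmr_t{g}_p{p}"] = direct_asmr(sel, reference, sex=sex)
        rows.append(row)
    return comparison_from_asmr(pd.DataFrame(rows))


def expected_counts(
    counts: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    mode: str = "national",
) -> pd.DataFrame:
    """Indirectly standardized expected deaths per (city, tract, sex, period).

    ``E = sum_a rate_ref(a) * population(a)``.  With ``mode='city_period1'``
    the reference rates are each city's own period-1 aggregate rates (and
    ``reference`` is ignored); with ``mode='national'`` a reference table
    covering every locally present age group is required.
    """
    validate_counts(counts)
    if mode not in ("national", "city_period1"):
        raise ValueError(f"unknown mode {mode!r}")
    df = counts.copy()
    if mode == "national":
        if reference is None:
            raise ValueError("mode='national' requires a reference rate table")
        validate_reference(reference)
        parts = []
        for sex, sub in df.groupby("sex", sort=True):
            rates = reference_rate_lookup(reference, sex)
            uncovered = set(sub["age_group"].unique()) - set(rates.index)
            if uncovered:
                raise ValueError(
                    f"reference rates missing age groups for sex={sex!r}: {sorted(uncovered)}"
                )
            part = sub.copy()
            part["_rate"] = part["age_group"].map(rates)
            parts.append(part)
        df = pd.concat(parts)
    else:
        p1 = df[df["period"] == 1]
        if len(p1) == 0:
            raise ValueError("mode='city_period1' requires period-1 data")
        agg = p1.groupby(["city", "sex", "age_group"])[["deaths", "population"]].sum()
        zero_pop = agg["population"] == 0
        if zero_pop.any():
            logger.warning(
                "expected_counts: %d city/sex/age cells with zero period-1 population; "
                "their rate is taken as 0",
                int(zero_pop.sum()),
            )
        rate = np.zeros(len(agg))
        nz = ~zero_pop.to_numpy()
        rate[nz] = (agg["deaths"].to_numpy(float)[nz] / agg["population"].to_numpy(float)[nz])
        rate_s = pd.Series(rate, index=agg.index, name="_rate")
        df = df.join(rate_s, on=["city", "sex", "age_group"])
    df["_e"] = df["_rate"] * df["population"]
    out = (
        df.groupby(["city", "tract", "sex", "period"], sort=True)["_e"]
        .sum()
        .rename("expected")
        .reset_index()
    )
    return out
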