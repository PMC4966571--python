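"""Reference population and mortality-rate schedules.

Direct standardization needs reference-population age weights; indirect
standardization needs reference age-specific rates.  Both are carried in a
single tidy table with columns ``sex, age_group, rate, ref_population``.
The synthetic study ships a fixed schedule built here: population declining
geometrically across 5-year age groups and all-cause rates rising
Gompertz-like with age, calibrated so crude rates land in the range typical
of adult urban populations (roughly 1 100 per 100 000 person-years for men,
650 for women).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "age_group_labels",
    "default_reference",
    "reference_weights",
    "reference_rate_lookup",
    "validate_reference",
]

#: annual baseline rate at age group 0, by sex
_BASE_RATE = {"men": 1.2e-4, "women": 0.7e-4}
#: multiplicative increase in rate per 5-year age group
_RATE_GROWTH = 1.5
#: multiplicative decline in population per 5-year age group
_POP_DECLINE = 0.93


def age_group_labels(n_age_groups: int = 18) -> list[str]:
    """Five-year age-group labels ``0-4 ... 85+`` (open-ended last group)."""
    if n_age_groups < 1:
        raise ValueError("need at least one age group")
    labels = [f"{5 * a}-{5 * a + 4}" for a in range(n_age_groups - 1)]
    labels.append(f"{5 * (n_age_groups - 1)}+")
    return labels


def default_reference(
    n_age_groups: int = 18, sexes: tuple[str, ...] = ("men", "women")
) -> pd.DataFrame:
    """Reference schedule: rates and population weights per (sex, age group)."""
    labels = age_group_labels(n_age_groups)
    a = np.arange(n_age_groups, dtype=float)
    pop = _POP_DECLINE**a
    pop = pop / pop.sum()
    rows = []
    for sex in sexes:
        rate = _BASE_RATE[sex] * _RATE_GROWTH**a
        for lab, r, w in zip(labels, rate, pop):
            rows.append({"sex": sex, "age_group": lab, "rate": r, "ref_population": w})
    return pd.DataFrame(rows)


def reference_weights(reference: pd.DataFrame, sex: str) -> pd.Series:
    """Normalized reference-population age weights for one sex."""
    sub = reference[reference["sex"] == sex]
    if sub.empty:
        raise ValueError(f"reference has no rows for sex={sex!r}")
    w = sub.set_index("age_group")["ref_population"].astype(float)
    total = w.sum()
    if total <= 0:
        raise ValueError("reference population weights must sum to > 0")
    return w / total


def reference_rate_lookup(reference: pd.DataFrame, sex: str) -> pd.Series:
    """Age-specific reference rates (deaths per person-year) for one sex."""
    sub = reference[reference["sex"] == sex]
    if sub.empty:
        raise ValueError(f"reference has no rows for sex={sex!r}")
    return sub.set_index("age_group")["rate"].astype(float)


def validate_reference(reference: pd.DataFrame) -> None:
    required = {"sex", "age_group", "rate"}
    missing = required - set(reference.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    if (reference["rate"] < 0).any():
        raise ValueError("reference rates must be non-negative")
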