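"""Stratification and crude fertility rates.

Fertility is measured as live births per 1,000 women of reproductive age
(15-49) over a study period.  Analyses are stratified by period, mother's age
group and nationality group: Spanish nationals together with nationals of
high-income countries (World Bank threshold, GNI per capita >= $12,056) form
one group; mothers from low- and middle-income countries form the other
("LIC").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PERIODS",
    "PERIOD_YEARS",
    "AGE_GROUPS",
    "AGE_ALL",
    "NATIONALITIES",
    "GNI_HIGH_INCOME_THRESHOLD",
    "classify_nationality",
    "assign_age_group",
    "crude_rate",
    "validate_counts",
    "aggregate_age_all",
]

#: Canonical period labels and the calendar years they span.
PERIOD_YEARS: dict[str, tuple[int, int]] = {
    "P1": (1999, 2003),  # first pre-crisis period
    "P2": (2004, 2008),  # second pre-crisis period
    "P3": (2009, 2013),  # economic-crisis period
}
PERIODS: tuple[str, ...] = tuple(PERIOD_YEARS)

#: Narrow maternal age groups (completed years at delivery) ...
AGE_GROUPS: tuple[str, ...] = ("15-19", "20-24", "25-34", "35-49")
#: ... and the all-ages reproductive-span group, the sum of the four above.
AGE_ALL: str = "15-49"

NATIONALITIES: tuple[str, ...] = ("Spanish", "LIC")

#: World Bank high-income cutoff (GNI per capita, US dollars).
GNI_HIGH_INCOME_THRESHOLD: float = 12_056.0

_AGE_EDGES = {"15-19": (15, 19), "20-24": (20, 24), "25-34": (25, 34), "35-49": (35, 49)}

COUNT_COLUMNS = ["tract_id", "period", "age_group", "nationality", "births", "women"]


def classify_nationality(gni_per_capita: float | None = None, is_spanish: bool = False) -> str:
    """Assign a mother to the ``Spanish`` or ``LIC`` nationality group.

    Spanish nationals, and nationals of countries whose GNI per capita is at
    or above the high-income threshold, are grouped together as ``Spanish``;
    everyone else is ``LIC``.
    """
    if is_spanish:
        return "Spanish"
    if gni_per_capita is None:
        raise ValueError("need either is_spanish or the country's GNI per capita")
    if gni_per_capita < 0:
        raise ValueError("GNI per capita cannot be negative")
    return "Spanish" if gni_per_capita >= GNI_HIGH_INCOME_THRESHOLD else "LIC"


def assign_age_group(age: float) -> tuple[str, str]:
    """Map a maternal age (completed years at delivery) to its age groups.

    Returns the narrow group plus the global ``15-49`` group the mother also
    belongs to.  Ages outside the reproductive span are an error, not a
    silent drop.
    """
    if not 15 <= age <= 49:
        raise ValueError(f"age {age} outside the reproductive span 15-49")
    for label, (lo, hi) in _AGE_EDGES.items():
        if lo <= age <= hi:
            return label, AGE_ALL
    raise AssertionError("unreachable")  # pragma: no cover


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a stratified-counts table and return it with canonical columns.

    Expected long format: one row per (tract_id, period, age_group,
    nationality) cell with integer ``births`` and ``women``.
    """
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    out = counts[COUNT_COLUMNS].copy()
    for col in ("births", "women"):
        vals = out[col].to_numpy()
        if np.any(vals < 0):
            raise ValueError(f"negative values in {col!r}")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(f"{col!r} must be integer counts")
        out[col] = np.round(vals).astype(np.int64)
    bad_p = set(out["period"]) - set(PERIODS)
    if bad_p:
        raise ValueError(f"unknown period labels: {sorted(bad_p)}")
    bad_a = set(out["age_group"]) - set(AGE_GROUPS) - {AGE_ALL}
    if bad_a:
        raise ValueError(f"unknown age groups: {sorted(bad_a)}")
    bad_n = set(out["nationality"]) - set(NATIONALITIES)
    if bad_n:
        raise ValueError(f"unknown nationality groups: {sorted(bad_n)}")
    return out


def crude_rate(counts: pd.DataFrame) -> pd.DataFrame:
    """Crude fertility rate per 1,000 women for every cell of a counts table.

    Returns the table with two added columns: ``rate`` (1000 * births /
    women; NaN where undefined) and ``undefined`` (True where women == 0 —
    an empty denominator is flagged, never coerced to a zero rate).
    """
    out = validate_counts(counts)
    women = out["women"].to_numpy(dtype=float)
    births = out["births"].to_numpy(dtype=float)
    undefined = women == 0
    rate = np.full(len(out), np.nan)
    np.divide(1000.0 * births, women, out=rate, where=~undefined)
    out["rate"] = rate
    out["undefined"] = undefined
    return out


def aggregate_age_all(counts: pd.DataFrame) -> pd.DataFrame:
    """Append 15-49 cells as the sum of the four narrow age groups.

    Rows already labelled 15-49 are passed through untouched; otherwise the
    aggregate is computed per (tract, period, nationality).
    """
    out = validate_counts(counts)
    if (out["age_group"] == AGE_ALL).any():
        return out
    agg = (
        out.groupby(["tract_id", "period", "nationality"], as_index=False, sort=False)[
            ["births", "women"]
        ]
        .sum()
        .assign(age_group=AGE_ALL)
    )
    return pd.concat([out, agg[COUNT_COLUMNS]], ignore_index=True)
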