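"""MEDEA-style small-area deprivation index.

The index condenses five census socioeconomic indicators per tract — manual
work, unemployment, temporary work, low education, and low education among
the young — into a single score via the first principal component of the
standardized indicators.  The score is normalized to mean 0 / sd 1, oriented
so that higher values mean greater deprivation, and summarized by septiles
(seven equal-count groups) and by its 5th/95th percentile span, the exposure
contrast used for relative risks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "INDICATOR_COLUMNS",
    "DeprivationIndex",
    "compute_index",
    "assign_septiles",
    "percentile_span",
]

#: The five tract-level indicators, as percentages 0-100.
INDICATOR_COLUMNS: tuple[str, ...] = (
    "manual_workers_pct",
    "unemployment_pct",
    "temporary_workers_pct",
    "low_education_pct",
    "low_education_young_pct",
)

_ORIENT_COLUMN = "unemployment_pct"  # sign anchor: more unemployment = more deprived


@dataclass(frozen=True)
class DeprivationIndex:
    """Per-tract deprivation score and its derived summaries.

    Attributes
    ----------
    tract_id
        Tract identifiers in canonical order.
    x
        Standardized score (mean 0, sd 1); higher = more deprived.
    septile
        Label 1..7 per tract; 7 = most deprived seventh.
    q5, q95
        Empirical 5th and 95th percentiles of ``x``.
    variance_explained
        Fraction of total indicator variance carried by the first principal
        component, in [0, 1].
    """

    tract_id: tuple[str, ...]
    x: np.ndarray
    septile: np.ndarray | None  # None when fewer than 7 tracts
    q5: float
    q95: float
    variance_explained: float

    @property
    def span(self) -> float:
        """The 95th-minus-5th percentile contrast used in relative risks."""
        return self.q95 - self.q5

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"tract_id": list(self.tract_id), "x": self.x})
        if self.septile is not None:
            df["septile"] = self.septile
        return df


def _standardize(values: np.ndarray, name: str) -> np.ndarray:
    sd = values.std()  # population sd; the convention used throughout
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"indicator column {name!r} has zero variance")
    return (values - values.mean()) / sd


def compute_index(indicators: pd.DataFrame) -> DeprivationIndex:
    """Build the deprivation index from a five-indicator tract table.

    Each column is standardized to mean 0 / sd 1; the first principal
    component of the standardized matrix gives the raw scores, whose sign is
    chosen so the score correlates positively with unemployment; scores are
    rescaled to mean 0 / sd 1.  ``variance_explained`` is the leading
    eigenvalue of the indicator correlation matrix divided by 5.

    Parameters
    ----------
    indicators
        DataFrame with the five :data:`INDICATOR_COLUMNS` and either a
        ``tract_id`` column or tract ids as index.
    """
    missing = [c for c in INDICATOR_COLUMNS if c not in indicators.columns]
    if missing:
        raise ValueError(f"indicator table missing columns: {missing}")
    if "tract_id" in indicators.columns:
        ids = tuple(str(t) for t in indicators["tract_id"])
    else:
        ids = tuple(str(t) for t in indicators.index)
    n = len(indicators)
    if n < 3:
        raise ValueError(f"need at least 3 tracts to compute an index, got {n}")

    mat = indicators.loc[:, list(INDICATOR_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("indicator table contains missing or non-finite values")
    Z = np.column_stack(
        [_standardize(mat[:, k], INDICATOR_COLUMNS[k]) for k in range(mat.shape[1])]
    )

    corr = Z.T @ Z / n  # correlation matrix of the indicators
    eigvals, eigvecs = np.linalg.eigh(corr)
    lead = eigvecs[:, -1]
    scores = Z @ lead
    # orient: more unemployment must mean a higher index
    unemp = Z[:, INDICATOR_COLUMNS.index(_ORIENT_COLUMN)]
    if scores @ unemp < 0:
        scores = -scores
    scores = (scores - scores.mean()) / scores.std()

    q5, q95 = percentile_span(scores)
    return DeprivationIndex(
        tract_id=ids,
        x=scores,
        septile=assign_septiles(scores) if n >= 7 else None,
        q5=q5,
        q95=q95,
        variance_explained=float(eigvals[-1] / corr.shape[0]),
    )


def assign_septiles(x: np.ndarray, n_groups: int = 7) -> np.ndarray:
    """Rank-based split of scores into 7 ordered equal-count groups.

    Label ``n_groups`` (7) marks the most deprived group.  Group sizes differ
    by at most one; ties are broken by stable input order, so the labels are
    a deterministic function of the ranks alone.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} tracts for {n_groups} groups, got {n}")
    order = np.argsort(x, kind="stable")
    labels = np.empty(n, dtype=int)
    # np.array_split puts the larger chunks first (lowest scores)
    for g, chunk in enumerate(np.array_split(order, n_groups), start=1):
        labels[chunk] = g
    return labels


def percentile_span(x: np.ndarray, lo: float = 5.0, hi: float = 95.0) -> tuple[float, float]:
    """Empirical (lo, hi) percentiles by linear interpolation of order statistics.

    Raises if the scores are constant: a zero exposure span would make the
    relative risk comparing the two percentiles undefined.
    """
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("scores are constant; percentile span is zero and RR undefined")
    qlo, qhi = np.percentile(x, [lo, hi], method="linear")
    return float(qlo), float(qhi)
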