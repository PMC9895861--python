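"""Descriptive scoring: exclusion, prevalence, severity, composites, alpha.

A response matrix is a pandas DataFrame with one column per item and integer
scores in {0, 1, 2, 3}; raw (pre-exclusion) matrices may contain NaN for
missing answers.  A symptom is counted as present when its score is >= 1, the
only threshold consistent with the published prevalence table under 0-3
scoring.  Cluster composites are sums of member-item scores (cluster means in
the published table exceed the per-item maximum of 3, ruling out a per-item
mean).  Percentages are rounded half-away-from-zero to one decimal, the mode
that reproduces every verifiable published percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyDatasetError,
    InsufficientDataError,
    MissingItemError,
    UndefinedAlphaError,
)
from .instrument import InstrumentConfig

__all__ = [
    "SeverityStat",
    "round_half_away",
    "exclude_incomplete",
    "item_prevalence",
    "item_severity",
    "cluster_score",
    "cluster_prevalence",
    "cronbach_alpha",
    "summary_table",
]


@dataclass(frozen=True)
class SeverityStat:
    """Mean and sample (N-1) standard deviation of a score column or composite."""

    mean: float
    sd: float


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Python's builtin round() is banker's rounding; reported percentages use
    the half-away-from-zero convention instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(count: int, n: int) -> float:
    return round_half_away(100.0 * count / n)


def _require_item(matrix: pd.DataFrame, item: str) -> pd.Series:
    if item not in matrix.columns:
        raise MissingItemError(f"unknown item {item!r}")
    return matrix[item]


def exclude_incomplete(
    raw_records: pd.DataFrame,
) -> tuple[pd.DataFrame, int, float]:
    """Listwise deletion of records with any missing item.

    Returns the complete-case matrix (integer dtype), the number of excluded
    records, and the exclusion percentage rounded to one decimal.
    """
    n_raw = len(raw_records)
    complete = raw_records.dropna()
    n_excluded = n_raw - len(complete)
    if len(complete) == 0:
        raise EmptyDatasetError("no complete records remain after listwise deletion")
    pct_excluded = _pct(n_excluded, n_raw) if n_raw else 0.0
    return complete.astype(np.int64), n_excluded, pct_excluded


def item_prevalence(matrix: pd.DataFrame, item: str) -> tuple[int, float]:
    """(count, %) of participants scoring >= 1 on ``item``."""
    col = _require_item(matrix, item)
    count = int((col >= 1).sum())
    return count, _pct(count, len(matrix))


def item_severity(matrix: pd.DataFrame, item: str) -> SeverityStat:
    """Mean +- sample SD of one item's 0-3 score."""
    col = _require_item(matrix, item)
    if len(col) < 2:
        raise InsufficientDataError("severity needs at least 2 participants")
    return SeverityStat(mean=float(col.mean()), sd=float(col.std(ddof=1)))


def cluster_score(
    matrix: pd.DataFrame, instrument: InstrumentConfig, cluster: str
) -> pd.Series:
    """Per-participant sum composite over the cluster's items (range [0, 3k])."""
    items = instrument.cluster_items(cluster)
    missing = [i for i in items if i not in matrix.columns]
    if missing:
        raise MissingItemError(f"items {missing} absent from the response matrix")
    return matrix[list(items)].sum(axis=1).rename(cluster)


def cluster_prevalence(
    matrix: pd.DataFrame, instrument: InstrumentConfig, cluster: str
) -> tuple[int, float]:
    """(count, %) of participants with at least one cluster item scored >= 1."""
    items = list(instrument.cluster_items(cluster))
    count = int((matrix[items] >= 1).any(axis=1).sum())
    return count, _pct(count, len(matrix))


def cronbach_alpha(matrix: pd.DataFrame, items: Sequence[str]) -> float:
    """Cronbach's alpha, k/(k-1) * (1 - sum item variances / variance of sum).

    Variances are sample-based (N-1).  Alpha is at most 1 and may be negative;
    a composite with zero total variance leaves it undefined.
    """
    items = list(items)
    if len(items) < 2:
        raise InsufficientDataError("alpha needs at least 2 items")
    if len(matrix) < 3:
        raise InsufficientDataError("alpha needs at least 3 participants")
    missing = [i for i in items if i not in matrix.columns]
    if missing:
        raise MissingItemError(f"items {missing} absent from the response matrix")
    sub = matrix[items].astype(float)
    total_var = sub.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise UndefinedAlphaError("zero variance of the item sum")
    k = len(items)
    return float(k / (k - 1) * (1.0 - sub.var(ddof=1).sum() / total_var))


def summary_table(matrix: pd.DataFrame, instrument: InstrumentConfig) -> pd.DataFrame:
    """Prevalence/severity summary shaped like the published symptom table.

    One row per cluster (count, %, mean +- SD of the sum composite, alpha)
    followed by its items, then the standalone items.  Columns: ``row_type``
    (cluster/item), ``name``, ``label``, ``count``, ``pct``, ``mean``, ``sd``,
    ``alpha`` (clusters only).
    """
    rows: list[dict] = []

    def _item_row(item: str) -> dict:
        count, pct = item_prevalence(matrix, item)
        sev = item_severity(matrix, item)
        return {
            "row_type": "item",
            "name": item,
            "label": instrument.labels[item],
            "count": count,
            "pct": pct,
            "mean": sev.mean,
            "sd": sev.sd,
            "alpha": np.nan,
        }

    for cluster in instrument.cluster_names:
        count, pct = cluster_prevalence(matrix, instrument, cluster)
        comp = cluster_score(matrix, instrument, cluster)
        try:
            alpha = cronbach_alpha(matrix, instrument.cluster_items(cluster))
        except UndefinedAlphaError:
            alpha = np.nan
        rows.append(
            {
                "row_type": "cluster",
                "name": cluster,
                "label": cluster.replace("_", " "),
                "count": count,
                "pct": pct,
                "mean": float(comp.mean()),
                "sd": float(comp.std(ddof=1)),
                "alpha": alpha,
            }
        )
        rows.extend(_item_row(i) for i in instrument.cluster_items(cluster))
    rows.extend(_item_row(i) for i in instrument.standalone_items)
    return pd.DataFrame(rows)
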