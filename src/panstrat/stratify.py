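"""Quartile-based high/low stratification and nonparametric group tests.

High/low groups are defined by the 75th/25th linear-interpolation empirical
percentiles of a per-sample value (typically focal-gene expression) with
inclusive membership (value >= upper threshold, <= lower threshold); the
``strict`` flag switches to the exclusive (>/<) reading.  Samples strictly
between the two thresholds belong to neither group and are excluded from all
two-group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateStratificationError,
    UndefinedRangeError,
    ValidationError,
)


@dataclass
class StratifiedGroups:
    high_ids: frozenset
    low_ids: frozenset
    q_high: float
    q_low: float
    focal_values: dict

    @property
    def mid_ids(self) -> frozenset:
        return frozenset(self.focal_values) - self.high_ids - self.low_ids

    def as_frame(self) -> pd.DataFrame:
        """sample_id / focal_value / group table (CLI output layout)."""
        rows = [
            {
                "sample_id": sample,
                "focal_value": value,
                "group": "high"
                if sample in self.high_ids
                else "low"
                if sample in self.low_ids
                else "mid",
            }
            for sample, value in sorted(self.focal_values.items())
        ]
        return pd.DataFrame(rows, columns=["sample_id", "focal_value", "group"])


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_high: int
    n_low: int


def quartile_groups(
    values: Mapping,
    high_q: float = 0.75,
    low_q: float = 0.25,
    strict: bool = False,
) -> StratifiedGroups:
    """Split samples at the ``high_q``/``low_q`` empirical quantiles.

    Thresholds use linear interpolation between order statistics; membership
    is inclusive unless ``strict``.  Missing values are excluded.  Raises
    :class:`DegenerateStratificationError` when the thresholds coincide.
    """
    series = pd.Series(dict(values), dtype=float).dropna()
    if len(series) < 8:
        raise ValidationError(f"need >=8 non-missing values, got {len(series)}")
    if not 0 < low_q < high_q < 1:
        raise ValidationError(f"require 0 < low_q < high_q < 1, got {low_q}, {high_q}")
    q_low, q_high = np.quantile(series.to_numpy(), [low_q, high_q])
    if q_low == q_high:
        raise DegenerateStratificationError(
            f"quantile thresholds coincide at {q_high}; values too tied/constant"
        )
    if strict:
        high = series.index[series > q_high]
        low = series.index[series < q_low]
    else:
        high = series.index[series >= q_high]
        low = series.index[series <= q_low]
    return StratifiedGroups(
        high_ids=frozenset(high),
        low_ids=frozenset(low),
        q_high=float(q_high),
        q_low=float(q_low),
        focal_values=series.to_dict(),
    )


def expression_range(values: Sequence) -> float:
    """Within-cohort max/min abundance ratio; requires all values > 0."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValidationError("expression_range needs >=2 values")
    if (arr <= 0).any():
        raise UndefinedRangeError("max/min ratio undefined for non-positive values")
    return float(arr.max() / arr.min())


def compare_continuous(
    high_values: Sequence,
    low_values: Sequence,
    test: str = "mann_whitney",
) -> TestResult:
    """Two-sided two-sample rank-sum comparison of high vs low groups.

    ``mann_whitney`` and ``wilcoxon_ranksum`` are aliases for the same
    unpaired rank-sum computation (the groups are independent).  Exact
    enumeration for small untied samples, tie-corrected normal approximation
    otherwise (scipy's ``method="auto"`` policy).
    """
    if test not in ("mann_whitney", "wilcoxon_ranksum"):
        raise ValidationError(f"unknown test {test!r}")
    high = np.asarray(high_values, dtype=float)
    low = np.asarray(low_values, dtype=float)
    high = high[~np.isnan(high)]
    low = low[~np.isnan(low)]
    if high.size == 0 or low.size == 0:
        raise ValidationError("both groups must be non-empty")
    res = stats.mannwhitneyu(high, low, alternative="two-sided", method="auto")
    return TestResult(
        test_name=test,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_high=int(high.size),
        n_low=int(low.size),
    )


def compare_categorical(contingency) -> TestResult:
    """Pearson chi-square (no continuity correction) on an r x c count table.

    Zero-marginal rows/columns are dropped with a warning; a table collapsing
    below 2 x 2 raises :class:`ValidationError`.  ``n_high``/``n_low`` report
    the first two row totals (rows are groups by convention).
    """
    table = pd.DataFrame(contingency).astype(float)
    if (table.to_numpy() < 0).any():
        raise ValidationError("counts must be non-negative")
    zero_rows = table.index[table.sum(axis=1) == 0]
    zero_cols = table.columns[table.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping zero-marginal rows {list(zero_rows)} / columns {list(zero_cols)}"
        )
        table = table.drop(index=zero_rows, columns=zero_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError(
            f"contingency table collapsed to {table.shape}; need >=2 rows and columns"
        )
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    totals = table.sum(axis=1)
    return TestResult(
        test_name="chi_square",
        statistic=float(chi2),
        p_value=float(p),
        n_high=int(round(totals.iloc[0])),
        n_low=int(round(totals.iloc[1])),
    )


def compare_metrics(
    cohort_metrics: pd.DataFrame,
    groups: StratifiedGroups,
    metric_names: Sequence | None = None,
) -> pd.DataFrame:
    """Rank-sum comparisons of each requested per-sample metric between the
    high and low groups; one TestResult row per available metric."""
    if metric_names is None:
        metric_names = [c for c in cohort_metrics.columns]
    rows = []
    for name in metric_names:
        if name not in cohort_metrics.columns:
            continue
        col = cohort_metrics[name]
        high = col.reindex(sorted(groups.high_ids)).dropna()
        low = col.reindex(sorted(groups.low_ids)).dropna()
        if high.empty or low.empty:
            warnings.warn(f"metric {name!r}: one group has no data; skipped")
            continue
        result = compare_continuous(high.to_numpy(), low.to_numpy())
        rows.append(
            {
                "metric": name,
                "test": result.test_name,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "n_high": result.n_high,
                "n_low": result.n_low,
                "median_high": float(high.median()),
                "median_low": float(low.median()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "metric",
            "test",
            "statistic",
            "p_value",
            "n_high",
            "n_low",
            "median_high",
            "median_low",
        ],
    )
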