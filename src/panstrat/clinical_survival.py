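"""Kaplan–Meier estimation, log-rank tests, and stage/grade contingency
analyses between high and low focal-expression groups.

The survival machinery is deliberately self-contained (product-limit
estimator plus the standard two-group log-rank chi-square with
hypergeometric variance) so its arithmetic can be checked against
independent life-table oracles; ties between events and censorings at the
same time are resolved events-first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_cohort import GRADE_LEVELS, T_STAGE_LEVELS
from .stratify import StratifiedGroups, TestResult, compare_categorical


@dataclass
class KMCurve:
    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival_prob,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
            }
        )


@dataclass
class SurvivalTestResult:
    chi_square: float
    p_value: float
    n_high: int
    n_low: int
    events_high: int
    events_low: int
    defined: bool = True


def _clean(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")
    mask = ~(np.isnan(t) | np.isnan(e))
    t, e = t[mask], e[mask]
    if (t < 0).any():
        raise ValidationError("negative survival time")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValidationError("event flags must be 0/1")
    return t, e.astype(int)


def km_estimate(times: Sequence, events: Sequence) -> KMCurve:
    """Product-limit survival estimate at each distinct event time."""
    t, e = _clean(times, events)
    event_times = np.unique(t[e == 1])
    n_at_risk = np.array([(t >= u).sum() for u in event_times], dtype=int)
    n_events = np.array([((t == u) & (e == 1)).sum() for u in event_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - n_events / n_at_risk)
    return KMCurve(event_times, surv, n_at_risk, n_events)


def _logrank_components(high, low):
    """(O - E, V) of the high group accumulated over distinct event times."""
    t1, e1 = _clean(*high)
    t2, e2 = _clean(*low)
    if t1.size == 0 or t2.size == 0:
        raise ValidationError("both groups must be non-empty")
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.ones_like(t1), np.zeros_like(t2)])
    o_minus_e = 0.0
    variance = 0.0
    for u in np.unique(t[e == 1]):
        at_risk = t >= u
        n = at_risk.sum()
        n1 = (at_risk & (g == 1)).sum()
        dying = (t == u) & (e == 1)
        d = dying.sum()
        d1 = (dying & (g == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (
        float(o_minus_e),
        float(variance),
        (t1.size, t2.size, int(e1.sum()), int(e2.sum())),
    )


def logrank_test(high: tuple, low: tuple) -> SurvivalTestResult:
    """Standard two-group log-rank test (1 df).

    ``high`` and ``low`` are ``(times, events)`` pairs.  With zero total
    events (or zero variance) the test is undefined and returned flagged
    rather than raised.
    """
    o_minus_e, variance, (n1, n2, d1, d2) = _logrank_components(high, low)
    if d1 + d2 == 0 or variance == 0:
        return SurvivalTestResult(
            float("nan"), float("nan"), n1, n2, d1, d2, defined=False
        )
    chi2 = o_minus_e**2 / variance
    return SurvivalTestResult(
        float(chi2), float(stats.chi2.sf(chi2, df=1)), n1, n2, d1, d2
    )


def stratified_logrank_test(groups_by_stratum: Mapping) -> SurvivalTestResult:
    """Stratified log-rank: O-E and V summed across strata (each stratum
    maps to a ``(high, low)`` pair of ``(times, events)`` tuples)."""
    if not groups_by_stratum:
        raise ValidationError("need >=1 stratum")
    total_oe = total_var = 0.0
    n1 = n2 = d1 = d2 = 0
    for high, low in groups_by_stratum.values():
        oe, var, (a, b, c, d) = _logrank_components(high, low)
        total_oe += oe
        total_var += var
        n1, n2, d1, d2 = n1 + a, n2 + b, d1 + c, d2 + d
    if d1 + d2 == 0 or total_var == 0:
        return SurvivalTestResult(
            float("nan"), float("nan"), n1, n2, d1, d2, defined=False
        )
    chi2 = total_oe**2 / total_var
    return SurvivalTestResult(
        float(chi2), float(stats.chi2.sf(chi2, df=1)), n1, n2, d1, d2
    )


def survival_comparison(
    clinical: pd.DataFrame,
    groups: StratifiedGroups,
    endpoint: str = "os",
    by_cohort: pd.Series | None = None,
):
    """KM curves plus log-rank for one endpoint ('os' or 'pfs') given a
    pooled clinical table indexed by sample; ``by_cohort`` (sample -> cohort
    label) switches to the stratified log-rank."""
    time_col, event_col = f"{endpoint}_time", f"{endpoint}_event"
    if time_col not in clinical or event_col not in clinical:
        raise ValidationError(f"clinical table lacks {time_col}/{event_col}")
    usable = clinical[[time_col, event_col]].dropna()

    def _arm(ids):
        sub = usable.loc[usable.index.intersection(sorted(ids))]
        return sub[time_col].to_numpy(), sub[event_col].to_numpy()

    high, low = _arm(groups.high_ids), _arm(groups.low_ids)
    if by_cohort is None:
        test = logrank_test(high, low)
    else:
        strata = {}
        for label in by_cohort.dropna().unique():
            members = set(by_cohort.index[by_cohort == label])
            strata[label] = (
                _arm(groups.high_ids & members),
                _arm(groups.low_ids & members),
            )
        test = stratified_logrank_test(strata)
    return {
        "high_curve": km_estimate(*high),
        "low_curve": km_estimate(*low),
        "test": test,
    }


def stage_grade_tables(clinical: pd.DataFrame, groups: StratifiedGroups) -> dict:
    """Group x category contingency tables, chi-square tests, and per-group
    percentage distributions for AJCC T stage and histologic grade.

    Returns ``{variable: {"counts", "percent", "test"}}``; variables with no
    usable data in a group are skipped with a warning.
    """
    out = {}
    for variable, levels in (("t_stage", T_STAGE_LEVELS), ("grade", GRADE_LEVELS)):
        if variable not in clinical.columns:
            continue
        col = clinical[variable].dropna()
        rows = {}
        for name, ids in (("high", groups.high_ids), ("low", groups.low_ids)):
            values = col.loc[col.index.intersection(sorted(ids))]
            rows[name] = values.value_counts().reindex(levels, fill_value=0)
        counts = pd.DataFrame(rows).T[list(levels)]
        if (counts.sum(axis=1) == 0).any():
            warnings.warn(f"{variable}: a group has no annotated samples; skipped")
            continue
        try:
            test = compare_categorical(counts)
        except ValidationError as exc:
            warnings.warn(f"{variable}: {exc}")
            continue
        percent = counts.div(counts.sum(axis=1), axis=0) * 100.0
        out[variable] = {"counts": counts, "percent": percent, "test": test}
    return out


def results_table(named_results: Mapping) -> pd.DataFrame:
    """Flatten a name -> TestResult/SurvivalTestResult mapping for export."""
    rows = []
    for name, res in named_results.items():
        if isinstance(res, SurvivalTestResult):
            rows.append(
                {
                    "comparison": name,
                    "test": "logrank",
                    "statistic": res.chi_square,
                    "p_value": res.p_value,
                    "n_high": res.n_high,
                    "n_low": res.n_low,
                }
            )
        elif isinstance(res, TestResult):
            rows.append(
                {
                    "comparison": name,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n_high": res.n_high,
                    "n_low": res.n_low,
                }
            )
    return pd.DataFrame(
        rows, columns=["comparison", "test", "statistic", "p_value", "n_high", "n_low"]
    )
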