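"""Focal-gene co-expression screening and cross-cohort consistency voting.

Within each cohort every gene is Spearman-correlated against the focal gene
(mid-rank, tie-corrected) with Benjamini–Hochberg q-values computed across
the cohort's gene list.  A gene is then voted "consistent" when it passes the
per-cohort direction criterion (|rho| >= rho_thresh with q <= sig_thresh by
default) in at least ``floor(min_frac * n_datasets)`` of the datasets —
with the default 0.8 fraction, 53 datasets give a vote threshold of 42.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import GeneLookupError, ValidationError
from .io_cohort import CohortDataset


@dataclass
class CorrelationRecord:
    gene: str
    cohort_id: str
    rho: float
    p_value: float
    q_value: float
    n_pairs: int


@dataclass
class ConsistencyResult:
    gene: str
    n_datasets: int
    n_pos_sig: int
    n_neg_sig: int
    mean_rho: float
    label: str  # consistent_positive | consistent_negative | none


def _spearman_exact_p(rho: float, n: int) -> float:
    """Two-sided exact permutation p for untied samples, n < 10."""
    ranks = np.array(list(permutations(range(n))), dtype=float)
    ref = np.arange(n, dtype=float)
    d2 = ((ranks - ref) ** 2).sum(axis=1)
    rhos = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def _spearman_p(rho: float, n: int, exact_ok: bool) -> float:
    if n < 3:
        return 1.0
    if exact_ok and n < 10:
        return _spearman_exact_p(rho, n)
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman(x: Sequence, y: Sequence) -> tuple:
    """Mid-rank Spearman rho with two-sided p (t-approximation; exact
    enumeration for n < 10 when neither vector has ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValidationError("spearman needs >=3 complete pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(rx, ry)[0, 1]
    if np.isnan(rho):
        return float("nan"), float("nan")
    untied = len(np.unique(x)) == n and len(np.unique(y)) == n
    return float(rho), _spearman_p(float(rho), n, exact_ok=untied)


def correlate_focal(
    cohort: CohortDataset, focal_gene: str, min_pairs: int = 3
) -> list:
    """One :class:`CorrelationRecord` per non-focal gene in the cohort.

    q-values are BH-adjusted across all genes retained within this cohort.
    Genes with fewer than ``min_pairs`` complete pairs are omitted with a
    warning.
    """
    if focal_gene not in cohort.expression.index:
        raise GeneLookupError(f"focal gene {focal_gene!r} absent from {cohort.cohort_id}")
    expr = cohort.expression
    focal = expr.loc[focal_gene].to_numpy(dtype=float)
    others = expr.drop(index=focal_gene)
    values = others.to_numpy(dtype=float)

    if not np.isnan(values).any() and not np.isnan(focal).any():
        records = _correlate_dense(others.index, values, focal, cohort.cohort_id)
    else:
        records = []
        for gene, row in zip(others.index, values):
            mask = ~(np.isnan(row) | np.isnan(focal))
            if mask.sum() < min_pairs:
                warnings.warn(
                    f"{cohort.cohort_id}: gene {gene!r} has "
                    f"{int(mask.sum())} complete pairs; record omitted"
                )
                continue
            rho, p = spearman(row[mask], focal[mask])
            records.append(
                CorrelationRecord(gene, cohort.cohort_id, rho, p, np.nan, int(mask.sum()))
            )
    if records:
        _, qvals, _, _ = multipletests(
            [r.p_value for r in records], method="fdr_bh"
        )
        for record, q in zip(records, qvals):
            record.q_value = float(q)
    return records


def _correlate_dense(genes, values, focal, cohort_id) -> list:
    """Vectorised mid-rank Spearman of every row of ``values`` against
    ``focal`` (no missing data path)."""
    n = focal.size
    ranks = stats.rankdata(values, axis=1)
    focal_ranks = stats.rankdata(focal)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    fc = focal_ranks - focal_ranks.mean()
    denom = np.sqrt((rc ** 2).sum(axis=1) * (fc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rc @ fc) / denom
    rho = np.clip(rho, -1.0, 1.0)
    records = []
    untied_focal = len(np.unique(focal)) == n
    for gene, row, r in zip(genes, values, rho):
        if np.isnan(r):  # constant gene: correlation undefined, skip
            warnings.warn(f"{cohort_id}: gene {gene!r} constant; record omitted")
            continue
        untied = untied_focal and len(np.unique(row)) == n
        records.append(
            CorrelationRecord(
                gene, cohort_id, float(r), _spearman_p(float(r), n, untied), np.nan, n
            )
        )
    return records


def classify_direction(
    record: CorrelationRecord,
    rho_thresh: float = 0.3,
    sig_thresh: float = 0.05,
    sig_field: str = "q",
) -> str:
    """positive / negative / neither per the inclusive per-cohort criterion."""
    if sig_field not in ("q", "p"):
        raise ValidationError(f"sig_field must be 'q' or 'p', got {sig_field!r}")
    sig = record.q_value if sig_field == "q" else record.p_value
    if np.isnan(record.rho) or np.isnan(sig) or sig > sig_thresh:
        return "neither"
    if record.rho >= rho_thresh:
        return "positive"
    if record.rho <= -rho_thresh:
        return "negative"
    return "neither"


def consistency_vote(
    records_by_cohort: Mapping,
    min_frac: float = 0.8,
    rho_thresh: float = 0.3,
    sig_thresh: float = 0.05,
    sig_field: str = "q",
) -> list:
    """Cross-cohort vote over genes present in every cohort.

    Vote threshold is ``floor(min_frac * n_datasets)`` (0.8 of 53 datasets
    gives 42).  ``mean_rho`` averages over all cohorts, including those where
    the gene fails the per-cohort criterion.
    """
    if len(records_by_cohort) < 2:
        raise ValidationError("consistency vote needs >=2 cohorts")
    by_cohort = {
        cid: {r.gene: r for r in recs} for cid, recs in records_by_cohort.items()
    }
    shared = set.intersection(*(set(m) for m in by_cohort.values()))
    if not shared:
        raise ValidationError("no genes shared across all cohorts")
    n_datasets = len(by_cohort)
    threshold = math.floor(min_frac * n_datasets)
    results = []
    for gene in sorted(shared):
        votes = [
            classify_direction(by_cohort[cid][gene], rho_thresh, sig_thresh, sig_field)
            for cid in by_cohort
        ]
        n_pos = votes.count("positive")
        n_neg = votes.count("negative")
        if n_pos >= threshold:
            label = "consistent_positive"
        elif n_neg >= threshold:
            label = "consistent_negative"
        else:
            label = "none"
        mean_rho = float(np.mean([by_cohort[cid][gene].rho for cid in by_cohort]))
        results.append(
            ConsistencyResult(gene, n_datasets, n_pos, n_neg, mean_rho, label)
        )
    return results


def build_ordered_matrix(
    results: Sequence, records_by_cohort: Mapping
) -> tuple:
    """Gene x cohort rho matrix of consistent genes, split/ordered for display.

    Group 1 holds genes whose rho is positive in every cohort, group 2 genes
    negative in at least one cohort; within each group rows are sorted by
    descending mean rho.  Cells carry raw rho including non-significant
    values.  Returns ``(matrix, groups)`` where ``groups`` maps gene -> 1/2.
    """
    consistent = [r for r in results if r.label != "none"]
    cohort_ids = list(records_by_cohort)
    if not consistent:
        warnings.warn("no consistently labelled genes; empty matrix")
        return pd.DataFrame(columns=cohort_ids), pd.Series(dtype=int)
    by_cohort = {
        cid: {r.gene: r.rho for r in recs} for cid, recs in records_by_cohort.items()
    }
    rows, groups = {}, {}
    for res in consistent:
        rhos = [by_cohort[cid][res.gene] for cid in cohort_ids]
        rows[res.gene] = rhos
        groups[res.gene] = 1 if all(r > 0 for r in rhos) else 2
    order = sorted(
        rows,
        key=lambda g: (groups[g], -next(r.mean_rho for r in consistent if r.gene == g), g),
    )
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=cohort_ids).loc[order]
    return matrix, pd.Series({g: groups[g] for g in order}, dtype=int)


def recurrence_count(label_sets: Mapping) -> dict:
    """Count, for each label, the number of cohorts whose set contains it;
    returned in descending-count (then lexicographic) order."""
    if not label_sets:
        raise ValidationError("need >=1 cohort")
    counts = {}
    for labels in label_sets.values():
        for label in set(labels):
            counts[label] = counts.get(label, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Flatten CorrelationRecords for TSV export."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "cohort_id": r.cohort_id,
                "rho": r.rho,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "n_pairs": r.n_pairs,
            }
            for r in records
        ],
        columns=["gene", "cohort_id", "rho", "p_value", "q_value", "n_pairs"],
    )


def consistency_to_frame(results: Sequence) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "n_datasets": r.n_datasets,
                "n_pos_sig": r.n_pos_sig,
                "n_neg_sig": r.n_neg_sig,
                "mean_rho": r.mean_rho,
                "label": r.label,
            }
            for r in results
        ],
        columns=["gene", "n_datasets", "n_pos_sig", "n_neg_sig", "mean_rho", "label"],
    )
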