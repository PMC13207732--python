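"""Mutation-rate enrichment between high and low focal-expression groups.

Within each tumour type (cohort), each gene's mutation rate is computed in
the high and low quartile groups and summarised as a delta (high - low).
Sign comparisons use exact integer cross-multiplication, never floats.
Across tumour types a gene's positive/negative counts form the pos/neg
ratio: > 2 classifies the gene as enriched in high-expression tumours,
<= 0.8 as depleted, anything in between as neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GeneLookupError, ValidationError
from .io_cohort import CohortDataset
from .stratify import quartile_groups

STATUS_CODES = {"positive": 1, "negative": 2, "unchanged": 3, "unknown": 4}
CODE_STATUS = {v: k for k, v in STATUS_CODES.items()}


@dataclass
class DeltaRecord:
    gene: str
    cohort_id: str
    rate_high: float | None
    rate_low: float | None
    delta: float | None
    status: str  # positive | negative | unchanged | unknown


@dataclass
class RatioSummary:
    gene: str
    n_pos: int
    n_neg: int
    n_unchanged: int
    n_unknown: int
    pos_neg_ratio: float
    classification: str  # enriched | depleted | neither


def mutation_rate(cohort: CohortDataset, sample_ids, gene: str):
    """Fraction of ``sample_ids`` carrying a mutation in ``gene``; ``None``
    when the gene is absent from the cohort's mutation universe."""
    ids = sorted(sample_ids)
    if not ids:
        raise ValidationError("empty sample set")
    missing = set(ids) - set(cohort.samples)
    if missing:
        raise ValidationError(f"samples not in cohort: {sorted(missing)[:5]}")
    if gene not in cohort.mutated.index:
        return None
    return float(cohort.mutated.loc[gene, ids].sum()) / len(ids)


def _counts(cohort: CohortDataset, sample_ids, gene: str):
    if gene not in cohort.mutated.index:
        return None
    ids = sorted(sample_ids)
    return int(cohort.mutated.loc[gene, ids].sum()), len(ids)


def delta_enrichment(
    cohort: CohortDataset,
    focal_gene: str,
    gene_list: Sequence,
    high_q: float = 0.75,
    low_q: float = 0.25,
    strict: bool = False,
) -> list:
    """One :class:`DeltaRecord` per requested gene in one cohort.

    Status is decided on integer counts (a/b vs c/d compared as a*d vs c*b),
    so delta == 0 is exact.  Genes absent from the mutation universe get
    status ``unknown`` (kept for heatmap encoding, excluded from ratios).
    """
    if focal_gene not in cohort.expression.index:
        raise GeneLookupError(f"focal gene {focal_gene!r} absent from {cohort.cohort_id}")
    groups = quartile_groups(
        cohort.expression.loc[focal_gene].to_dict(), high_q, low_q, strict
    )
    records = []
    for gene in gene_list:
        high = _counts(cohort, groups.high_ids, gene)
        low = _counts(cohort, groups.low_ids, gene)
        if high is None or low is None:
            records.append(DeltaRecord(gene, cohort.cohort_id, None, None, None, "unknown"))
            continue
        (a, b), (c, d) = high, low
        cross = a * d - c * b  # sign of rate_high - rate_low, exactly
        status = "positive" if cross > 0 else "negative" if cross < 0 else "unchanged"
        records.append(
            DeltaRecord(
                gene, cohort.cohort_id, a / b, c / d, a / b - c / d, status
            )
        )
    return records


def pos_neg_ratio(records: Sequence) -> RatioSummary:
    """Cross-tumour-type ratio classification for one gene's DeltaRecords."""
    if not records:
        raise ValidationError("need >=1 record")
    genes = {r.gene for r in records}
    if len(genes) != 1:
        raise ValidationError(f"records span multiple genes: {sorted(genes)}")
    n_pos = sum(r.status == "positive" for r in records)
    n_neg = sum(r.status == "negative" for r in records)
    n_unch = sum(r.status == "unchanged" for r in records)
    n_unk = sum(r.status == "unknown" for r in records)
    if n_neg > 0:
        ratio = n_pos / n_neg
    elif n_pos > 0:
        ratio = float("inf")
    else:
        ratio = float("nan")  # no informative tumour types
    if n_pos == 0 and n_neg == 0:
        classification = "neither"
    elif ratio > 2:
        classification = "enriched"
    elif ratio <= 0.8:
        classification = "depleted"
    else:
        classification = "neither"
    return RatioSummary(records[0].gene, n_pos, n_neg, n_unch, n_unk, ratio, classification)


def summarise_ratios(records: Sequence) -> list:
    """pos_neg_ratio over every gene appearing in ``records``."""
    by_gene = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    return [pos_neg_ratio(by_gene[g]) for g in sorted(by_gene)]


def encode_status_matrix(records: Sequence) -> pd.DataFrame:
    """Gene x tumour-type integer matrix (positive=1, negative=2,
    unchanged=3, unknown=4), rows ordered by positive-count descending."""
    genes = sorted({r.gene for r in records})
    cohorts = list(dict.fromkeys(r.cohort_id for r in records))
    matrix = pd.DataFrame(
        STATUS_CODES["unknown"], index=genes, columns=cohorts, dtype=int
    )
    for r in records:
        matrix.loc[r.gene, r.cohort_id] = STATUS_CODES[r.status]
    n_pos = (matrix == STATUS_CODES["positive"]).sum(axis=1)
    order = sorted(genes, key=lambda g: (-int(n_pos[g]), g))
    return matrix.loc[order]


def decode_status_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Inverse of the numeric encoding (status labels as strings)."""
    return matrix.map(lambda v: CODE_STATUS[int(v)])


def alteration_frequency(
    cohort: CohortDataset, gene: str, alteration_class: str = "mutation"
) -> float:
    """Fraction of profiled samples carrying >=1 alteration of the given
    class in ``gene``.  ``mutation`` uses the mutation layer; other classes
    (amplification, deletion, structural) must be present as extra layers."""
    if alteration_class == "mutation":
        layer = cohort.mutated
    elif alteration_class in cohort.alterations:
        layer = cohort.alterations[alteration_class]
    else:
        raise GeneLookupError(
            f"alteration layer {alteration_class!r} absent from {cohort.cohort_id}"
        )
    if gene not in layer.index:
        raise GeneLookupError(f"gene {gene!r} absent from {alteration_class} layer")
    row = layer.loc[gene]
    return float(np.asarray(row, dtype=float).mean())


def delta_records_to_frame(records: Sequence) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "cohort_id": r.cohort_id,
                "rate_high": r.rate_high,
                "rate_low": r.rate_low,
                "delta": r.delta,
                "status": r.status,
            }
            for r in records
        ],
        columns=["gene", "cohort_id", "rate_high", "rate_low", "delta", "status"],
    )


def ratio_summaries_to_frame(summaries: Sequence) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene,
                "n_pos": s.n_pos,
                "n_neg": s.n_neg,
                "n_unchanged": s.n_unchanged,
                "n_unknown": s.n_unknown,
                "pos_neg_ratio": s.pos_neg_ratio,
                "classification": s.classification,
            }
            for s in summaries
        ],
        columns=[
            "gene",
            "n_pos",
            "n_neg",
            "n_unchanged",
            "n_unknown",
            "pos_neg_ratio",
            "classification",
        ],
    )
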