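"""Proliferation scoring and proliferation-adjusted instability regressions.

The proliferation score is the per-sample mean of gene-wise z-scores of
log2-transformed expression over a cell-cycle gene set (MKI67 excluded by
default so it can serve as an independent single-gene covariate).  Genomic
instability outcomes (FGA, log1p mutation count) are regressed on focal-gene
log2 expression unadjusted and with each proliferation covariate in turn;
attenuation summarises how much the focal coefficient shrinks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import GeneLookupError, SingularDesignError, ValidationError
from .io_cohort import CohortDataset, GeneSet
from .coexpression import spearman

OUTCOMES = ("fga", "log1p_mutation_count")
MODELS = ("unadjusted", "mki67_adjusted", "g2m_adjusted")
PAN_CANCER = "pan-cancer"


@dataclass
class ProliferationScore:
    scores: pd.Series  # per-sample
    gene_set_name: str
    n_genes_used: int
    excluded_genes: frozenset


@dataclass
class Term:
    name: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class RegressionResult:
    outcome: str
    stratum: str
    model: str
    terms: list
    n: int
    fitted: np.ndarray = field(default=None, repr=False)
    residuals: np.ndarray = field(default=None, repr=False)

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def g2m_score(
    cohort: CohortDataset,
    gene_set: GeneSet,
    exclude: Iterable = frozenset({"MKI67"}),
    pseudocount: float = 1.0,
) -> ProliferationScore:
    """Mean of per-gene z-scores of log2(expression + pseudocount).

    z uses the sample standard deviation (n-1 denominator); zero-variance
    genes are dropped with a warning and counted as excluded.
    """
    exclude = frozenset(exclude)
    wanted = sorted((gene_set.genes - exclude) & set(cohort.expression.index))
    if not wanted:
        raise ValidationError(
            f"{cohort.cohort_id}: no usable genes from set {gene_set.name!r}"
        )
    logged = np.log2(cohort.expression.loc[wanted].astype(float) + pseudocount)
    sd = logged.std(axis=1, ddof=1)
    degenerate = sd.index[(sd == 0) | sd.isna()]
    if len(degenerate):
        warnings.warn(
            f"{cohort.cohort_id}: dropping zero-variance set genes {list(degenerate)[:5]}"
        )
        logged = logged.drop(index=degenerate)
        sd = sd.drop(index=degenerate)
    if logged.empty:
        raise ValidationError(f"{cohort.cohort_id}: all set genes have zero variance")
    z = logged.sub(logged.mean(axis=1), axis=0).div(sd, axis=0)
    return ProliferationScore(
        scores=z.mean(axis=0),
        gene_set_name=gene_set.name,
        n_genes_used=int(z.shape[0]),
        excluded_genes=exclude | frozenset(degenerate),
    )


def transform_covariates(
    cohort: CohortDataset, focal_gene: str, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-sample model inputs: focal_log2, mki67_log2 (if present),
    log1p_mutation_count, fga."""
    if focal_gene not in cohort.expression.index:
        raise GeneLookupError(f"focal gene {focal_gene!r} absent from {cohort.cohort_id}")
    focal = cohort.expression.loc[focal_gene].astype(float)
    if (focal.dropna() < 0).any():
        raise ValidationError("negative expression values")
    out = pd.DataFrame(index=cohort.samples)
    out["focal_log2"] = np.log2(focal + pseudocount)
    if "MKI67" in cohort.expression.index:
        out["mki67_log2"] = np.log2(
            cohort.expression.loc["MKI67"].astype(float) + pseudocount
        )
    if "mutation_count" in cohort.metrics:
        out["log1p_mutation_count"] = np.log1p(
            cohort.metrics["mutation_count"].reindex(out.index).astype(float)
        )
    if "fga" in cohort.metrics:
        out["fga"] = cohort.metrics["fga"].reindex(out.index).astype(float)
    return out


def fit_instability_model(
    outcome: pd.Series,
    focal: pd.Series,
    covariate: pd.Series | None = None,
    stratum: str = PAN_CANCER,
    outcome_name: str = "outcome",
    model_name: str = "unadjusted",
    covariate_name: str = "covariate",
) -> RegressionResult:
    """OLS of ``outcome`` on focal expression (plus one optional covariate)
    with intercept; per-term beta, SE, two-sided t p-value, and 95% CI."""
    frame = pd.DataFrame({"outcome": outcome, "focal": focal})
    names = ["focal"]
    if covariate is not None:
        frame[covariate_name] = covariate
        names.append(covariate_name)
    frame = frame.dropna()
    k = len(names)
    if len(frame) < k + 2:
        raise ValidationError(
            f"{stratum}/{outcome_name}: {len(frame)} complete cases, need >= {k + 2}"
        )
    X = sm.add_constant(frame[names].to_numpy(float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"{stratum}/{outcome_name}/{model_name}: perfectly collinear predictors"
        )
    fit = sm.OLS(frame["outcome"].to_numpy(float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    labels = ["intercept"] + names
    terms = [
        Term(
            name=labels[i],
            beta=float(fit.params[i]),
            se=float(fit.bse[i]),
            ci_low=float(ci[i, 0]),
            ci_high=float(ci[i, 1]),
            p_value=float(fit.pvalues[i]),
        )
        for i in range(len(labels))
    ]
    return RegressionResult(
        outcome=outcome_name,
        stratum=stratum,
        model=model_name,
        terms=terms,
        n=int(fit.nobs),
        fitted=np.asarray(fit.fittedvalues),
        residuals=np.asarray(fit.resid),
    )


def attenuation(unadjusted: RegressionResult, adjusted: RegressionResult) -> float:
    """1 - beta_adj / beta_unadj for the focal term; NaN when the unadjusted
    coefficient is exactly zero (undefined, flagged rather than raised)."""
    if (unadjusted.outcome, unadjusted.stratum) != (adjusted.outcome, adjusted.stratum):
        raise ValidationError("attenuation requires matching outcome and stratum")
    b0 = unadjusted.term("focal").beta
    b1 = adjusted.term("focal").beta
    if b0 == 0:
        return float("nan")
    return 1.0 - b1 / b0


def _cohort_table(
    cohort: CohortDataset, focal_gene: str, gene_set: GeneSet, pseudocount: float
) -> pd.DataFrame:
    table = transform_covariates(cohort, focal_gene, pseudocount)
    score = g2m_score(cohort, gene_set, pseudocount=pseudocount)
    table["g2m_score"] = score.scores.reindex(table.index)
    table["cohort_id"] = cohort.cohort_id
    return table


def run_model_grid(
    cohorts: Sequence,
    focal_gene: str,
    gene_set: GeneSet,
    pseudocount: float = 1.0,
    pool_raw: bool = False,
) -> list:
    """Fit 2 outcomes x 3 models per cohort and on the pooled pan-cancer
    table.  By default proliferation scores are standardised within cohort
    before pooling; ``pool_raw`` recomputes them on the concatenated table.
    """
    if not cohorts:
        raise ValidationError("need >=1 cohort")
    tables = {
        c.cohort_id: _cohort_table(c, focal_gene, gene_set, pseudocount)
        for c in cohorts
    }
    pooled = pd.concat(tables.values(), axis=0, ignore_index=True)
    if pool_raw:
        pooled = _pool_raw_table(cohorts, focal_gene, gene_set, pseudocount)
    strata = [(PAN_CANCER, pooled)] + [(cid, tables[cid]) for cid in tables]
    covariates = {
        "unadjusted": None,
        "mki67_adjusted": "mki67_log2",
        "g2m_adjusted": "g2m_score",
    }
    results = []
    for stratum, table in strata:
        for outcome_name in OUTCOMES:
            if outcome_name not in table.columns:
                continue
            for model_name, cov in covariates.items():
                if cov is not None and cov not in table.columns:
                    continue
                try:
                    results.append(
                        fit_instability_model(
                            table[outcome_name],
                            table["focal_log2"],
                            table[cov] if cov else None,
                            stratum=stratum,
                            outcome_name=outcome_name,
                            model_name=model_name,
                            covariate_name=cov or "covariate",
                        )
                    )
                except (ValidationError, SingularDesignError) as exc:
                    warnings.warn(f"skipping {stratum}/{outcome_name}/{model_name}: {exc}")
    return results


def _pool_raw_table(cohorts, focal_gene, gene_set, pseudocount) -> pd.DataFrame:
    """Global-standardisation reading: concatenate raw expression, then score."""
    merged_expr = pd.concat(
        [c.expression for c in cohorts], axis=1, join="inner"
    )
    merged_metrics = pd.concat([c.metrics for c in cohorts], axis=0)
    merged = CohortDataset(
        cohort_id=PAN_CANCER,
        expression=merged_expr,
        mutated=pd.DataFrame(columns=merged_expr.columns),
        metrics=merged_metrics.reindex(merged_expr.columns),
        clinical=pd.DataFrame(index=merged_expr.columns),
    )
    return _cohort_table(merged, focal_gene, gene_set, pseudocount)


def focal_proliferation_correlation(
    cohorts: Sequence,
    focal_gene: str,
    scores: Mapping,
    pseudocount: float = 1.0,
) -> tuple:
    """Spearman rho/p between pooled focal log2 expression and pooled
    proliferation scores (``scores`` maps cohort_id -> per-sample Series)."""
    xs, ys = [], []
    for cohort in cohorts:
        focal = np.log2(
            cohort.expression.loc[focal_gene].astype(float) + pseudocount
        )
        score = pd.Series(scores[cohort.cohort_id]).reindex(focal.index)
        xs.append(focal.to_numpy())
        ys.append(score.to_numpy(dtype=float))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 10:
        raise ValidationError("need >=10 pooled samples")
    return spearman(x, y)


def attenuation_summary(results: Sequence) -> pd.DataFrame:
    """Per stratum/outcome: unadjusted beta plus attenuation for each
    adjusted model (forest-plot companion table)."""
    index = {(r.stratum, r.outcome, r.model): r for r in results}
    rows = []
    for (stratum, outcome, model), res in index.items():
        if model == "unadjusted":
            continue
        unadj = index.get((stratum, outcome, "unadjusted"))
        if unadj is None:
            continue
        rows.append(
            {
                "stratum": stratum,
                "outcome": outcome,
                "model": model,
                "beta_unadjusted": unadj.term("focal").beta,
                "beta_adjusted": res.term("focal").beta,
                "attenuation": attenuation(unadj, res),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "stratum",
            "outcome",
            "model",
            "beta_unadjusted",
            "beta_adjusted",
            "attenuation",
        ],
    )


def results_to_frame(results: Sequence) -> pd.DataFrame:
    """Forest-plot-ready flat table (one row per term)."""
    rows = []
    for r in results:
        for t in r.terms:
            rows.append(
                {
                    "stratum": r.stratum,
                    "outcome": r.outcome,
                    "model": r.model,
                    "term": t.name,
                    "beta": t.beta,
                    "se": t.se,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p_value": t.p_value,
                    "n": r.n,
                    "significant": int(t.p_value < 0.05),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "stratum",
            "outcome",
            "model",
            "term",
            "beta",
            "se",
            "ci_low",
            "ci_high",
            "p_value",
            "n",
            "significant",
        ],
    )
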