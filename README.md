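# panstrat

Gene-centric pan-cancer cohort stratification analysis. Given multi-cohort
tumour expression, mutation, genomic-metric, and clinical tables
(cBioPortal-style TSV exports), `panstrat` stratifies tumours by a focal
gene's expression and computes:

- **co-expression** — per-cohort Spearman correlation of every gene against
  the focal gene (BH q-values within cohort), cross-cohort consistency
  voting (default: |ρ| ≥ 0.3 with q ≤ 0.05 in ≥ floor(0.8 × n) datasets),
  and a display-ordered correlation matrix split into exclusively-positive
  and sometimes-negative gene groups;
- **mutation enrichment** — per-tumour-type mutation-rate deltas
  (Δ = rate_high − rate_low, decided on exact integer counts) for a
  user-supplied driver list, cross-type pos/neg ratios (> 2 enriched,
  ≤ 0.8 depleted), and the numeric status matrix
  (positive = 1, negative = 2, unchanged = 3, unknown = 4);
- **metric comparisons** — rank-sum (Mann–Whitney / Wilcoxon) tests of
  mutation count, FGA, HRD, and hypoxia scores between the upper- and
  lower-quartile expression groups;
- **proliferation-adjusted regressions** — a multi-gene cell-cycle score
  (mean of per-gene z-scores of log2 expression, MKI67 excluded), OLS
  models of FGA and log1p mutation count on focal expression (unadjusted /
  MKI67-adjusted / score-adjusted), per cohort and pooled, with attenuation
  summaries (1 − β_adj/β_unadj);
- **clinical associations** — stage/grade chi-square contingency analyses
  and Kaplan–Meier / log-rank survival comparisons (optionally stratified
  by cohort).

A synthetic multi-cohort generator (latent proliferation factor, planted
co-expressed gene blocks, expression-dependent driver mutation rates,
mediated FGA/mutation-count structure, exponential survival with censoring)
makes the whole pipeline testable offline; presets `null`, `mediation`, and
`direct-effect` cover the calibration, fully-mediated, and persistent-
association regimes.

## CLI

```bash
# write a synthetic study directory (per-cohort TSVs + GMT + driver list)
panstrat simulate --out study/ --preset mediation --seed 1 \
    --n-cohorts 4 --n-samples 300 --n-genes 120

# individual stages
panstrat stratify  --data study/ --out strat.tsv
panstrat compare   --data study/ --out metric_tests.tsv
panstrat coexpress --data study/ --out coexpr/       # --rho-thresh --sig-field --min-frac
panstrat mutenrich --data study/ --out mutenrich/    # --driver-list
panstrat adjust    --data study/ --out adjust/       # --pseudocount --pool-raw
panstrat clinical  --data study/ --out clinical/     # --stratify-by-cohort

# everything at once (simulate + all stages; byte-deterministic per seed)
panstrat pipeline --out run/ --preset mediation --seed 42
```

Real data can be analysed by arranging per-cohort directories
(`expression.tsv`, `mutations.tsv`, `metrics.tsv`, `clinical.tsv`,
optionally `mutation_genes.txt` and extra binary alteration layers) and a
`config.yaml` naming them; see `panstrat.io_cohort` for the exact formats.

## Conventions and defaults

- Quartile membership is inclusive (≥ 75th / ≤ 25th percentile thresholds,
  linear-interpolation quantiles); `--strict-quartiles` switches to the
  exclusive reading. Samples between the thresholds are excluded from all
  two-group analyses.
- Expression inputs are any non-negative linear-scale abundances; log2
  transforms use a +1 pseudocount (`--pseudocount`).
- `mann_whitney` and `wilcoxon_ranksum` are aliases for the same unpaired
  two-sample rank-sum test.
- Gene identifiers are opaque, case-sensitive strings; no symbol aliasing.
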