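# prognosig

Multi-cohort prognostic gene-signature discovery and validation for survival
transcriptomics, built around a per-gene univariate Cox screen and a
rank-aggregation prioritization:

1. **Screen** — every gene is fit in a single-covariate Cox proportional-hazards
   model (Efron tie handling) against overall survival, per cohort.
2. **Rank** — genes are ranked ascending by Wald p-value and descending by
   folded hazard ratio `max(HR, 1/HR)`; the sum of the two ranks ("ranksum")
   prioritizes candidates.
3. **Assemble** — the top-K genes of each discovery cohort are intersected
   (present in ≥ 2 cohorts), retested in a tuning cohort, and kept with sign
   +1 (HR > 1, adverse) or −1 (HR < 1, favorable).
4. **Score & validate** — a sample's signature score is the signed sum of log
   expression over signature genes; cohorts are split at the median score and
   evaluated by Kaplan–Meier / log-rank, group Cox models, and backward-Wald
   multivariate elimination.
5. **Drug screen** — per-cell-line scores are correlated (Pearson) with
   per-drug cytotoxicity AUC to flag compounds preferentially effective on
   high- or low-score lines.

The canonical 20-gene pancreatic signature (PPS20: 11 adverse + 9 favorable
genes) ships with the package (`prognosig.pps20()`), along with adapters for
re-applying published comparator signatures (coefficient-weighted scores and
median-ratio cut-off transfer with a binary 0/1 risk score).

A fully seeded synthetic-data module generates negative-binomial count
cohorts with planted prognostic genes (hazard
`h0 · exp(Σ β_g z_g)` on standardized log-CPM, uniform censoring tuned to a
target rate) and cell-line/AUC panels with planted drug effects, so the whole
pipeline is testable offline.

## Test

```sh
python -m pytest tests/
```

## CLI

All stages are exposed through one entry point:

```sh
prognosig simulate   --config sim.yaml --out data/         # synthetic cohorts
prognosig discover   --config pipeline.yaml --out disc/    # screen→rank→top-K→intersect→retest
prognosig score      --expr X.tsv --signature pps20 --out scores.tsv
prognosig evaluate   --config pipeline.yaml --signature disc/signature.tsv --out eval/
prognosig compare    --expr X.tsv --spec chen.tsv --survival S.tsv --out cmp/
prognosig drugscreen --expr lines.tsv --auc auc.tsv --out screen.tsv
```

`pipeline.yaml` lists cohorts (path, role: discovery / tuning / validation,
unit: counts / cpm / rsem / log_*) and thresholds. All defaults follow the
reference analysis: top-K = 500, min cohorts = 2, retest α = 0.05, zero-count
filter 0.85, pseudocount 0.001, log base 2, backward-Wald removal α = 0.10,
drug screen ≥ 10 lines, binary risk threshold 1.709. Counts matrices are
preprocessed as CPM = count/total × 10⁶ then log₂(CPM + 0.001), with genes
zero in more than 85% of samples removed; samples with survival time 0 are
excluded and day-scale times are converted to months (÷30) for KM display.

Exit codes: 2 = configuration error, 3 = data/format error, 4 = numerical /
degeneracy error.

## Formats

Delimited text throughout: gene × sample matrices (first column gene/probe
id), survival tables (`sample_id`, `time`, `event`, covariates…), two-column
probe maps, signature files (`gene`, `weight` with `# key = value`
provenance headers), and line × drug AUC matrices.

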