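# scprog

Single-cell expression analysis pipeline: per-cell sequencing QC, CDS-length
TPM normalization, coefficient-of-variation variable-gene selection,
unsupervised Ward.D2 clustering of cells into ordered risk groups, derivation
of a monotone progression gene signature by group-wise ANOVA and fold-change
screening, hypergeometric gene-set over-representation, and survival
stratification of an external expression cohort by the signature
(K-means dichotomization, Kaplan–Meier, Mantel–Cox log-rank, hazard ratios).

A first-class synthetic-data module generates count matrices with a planted
monotone gene program, QC-metric tables with exact planted violations, and
survival cohorts with a planted hazard ratio, so every stage is testable
without external data.

## Layout

| module | role |
|---|---|
| `scprog.synthetic` | generators with planted ground truth (`SimConfig`, `simulate_expression`, `simulate_qc_metrics`, `simulate_survival_cohort`) |
| `scprog.qc` | three-criterion cell filtering with per-criterion failure reasons |
| `scprog.expression` | counts → TPM (CDS-length normalized) → log2(TPM+1) |
| `scprog.features` | per-gene stats, CV selection, Seurat-style prefilter, housekeeping accounting |
| `scprog.clustering` | 1−Pearson distance, Ward.D2 linkage, tree cut, expression-ordered L1..Lk labels |
| `scprog.signature` | per-gene ANOVA, pairwise fold changes, common-up / adjacent-monotone sets, GMT over-representation |
| `scprog.survival` | probe collapse, standardization, K-means high/low split, KM / log-rank / hazard ratio |
| `scprog.pipeline` | `run_all` orchestration, packaged per-patient cell-accounting fixture (`summarize_table1`) |
| `scprog.cli` | `scprog` command-line interface |

## CLI

```bash
scprog simulate --seed 1 --out out/sim           # synthetic dataset + truth labels
scprog qc --metrics metrics.csv --out out/qc     # --min-reads --min-mapped --min-tin
scprog normalize --counts counts.tsv --annotation ann.tsv --out out/norm
scprog select --log-matrix out/norm/log2_tpm1.tsv --housekeeping hk.txt --out out/sel
scprog cluster --log-matrix out/norm/log2_tpm1.tsv --genes out/sel/selected_genes.txt --k 4 --out out/clust
scprog signature --log-matrix out/norm/log2_tpm1.tsv --groups out/clust/group_assignment.csv --gmt sets.gmt --out out/sig
scprog survive --expression gep.csv --probe-map probes.tsv --survival surv.csv --genes out/sig/signature_genes.txt --out out/surv
scprog run-all --config config.yaml --out out/run   # full pipeline; simulates inputs when none configured
scprog table1                                       # packaged fixture totals
```

Matrices travel as TSV (genes × cells) or MatrixMarket directories
(`matrix.mtx` + `genes.tsv` + `cells.tsv`); gene lists are one symbol per
line; gene sets are GMT; survival tables are CSV with
`sample_id,time_days,event,arm`.

## Notes

- Thresholds follow the published procedure: QC failure only when strictly
  below 1,000,000 reads / 55% mapped / TIN 45 (boundary values pass);
  CV selection is inclusive (CV ≥ 0.5, mean log2(TPM+1) ≥ 3); the prefilter
  is strict (> 2 cells, mean log > 1, SD > 1); signature gating uses
  FC ≥ 2 and p < 0.05 per comparison (BH optional, off by default).
- Ward.D2 is the Murtagh–Legendre formulation (Lance–Williams on squared
  dissimilarities, square-root heights) with a deterministic tie rule.
- Hazard ratios report a Cox fit (Efron ties) and a Mantel–Haenszel O/E
  ratio side by side.
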