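# odfsp

Rank-based gene-pair prediction of early relapse in ovarian cancer, with
cross-cohort survival meta-analysis, permutation null tests and a
synthetic multi-cohort study generator.

## The problem

High-grade ovarian cancer patients who relapse within a year of surgery
("early relapse") gain little from standard surgery plus platinum
chemotherapy and are candidates for more aggressive regimens or trial
enrolment. Predicting early relapse from tumour transcriptomes is hard
because expression cohorts come from different platforms (RNA-seq,
microarray) with incompatible scales and batch effects, so any predictor
built on absolute expression values transfers poorly.

This package implements a **k-top-scoring-disjoint-pairs (k-TSP)**
predictor, which sidesteps the problem by using only the *within-sample
ordering* of gene pairs. For an ordered pair (i, j) the binary indicator

    b_ij(x) = 1[x_i < x_j]

is invariant to any strictly increasing per-sample transform, so a model
built from such "barcodes" crosses platforms and batches unchanged. It is
aimed at computational biologists building single-sample prognostic
classifiers and evaluating them across heterogeneous cohorts.

## The method

- **Labeling.** Disease-free survival (DFS) is dichotomized at one year:
  an observed relapse at ≤ 365 days is *high* (early relapse), follow-up
  beyond 365 days is *low*, and censoring at ≤ 365 days leaves the label
  *undefined* (excluded from binary evaluation).
- **Pair scoring.** Genes are first filtered by the standardized Wilcoxon
  rank-sum statistic against the label; each pair is then scored by
  Δ_ij = |P̂(X_i < X_j | high) − P̂(X_i < X_j | low)|, with ties broken by
  the mean within-sample rank-difference score γ and then the pair id.
- **Model.** Greedy selection of gene-disjoint pairs by that ordering; k
  (odd) chosen by stratified cross-validated balanced accuracy; a sample
  is called high-risk by pair-majority vote. An ensemble of B such models
  trained on class-balanced resamples gives a continuous risk score in
  [0, 1] (the fraction of models voting high). Dual-platform training
  profiles of the same patients are stacked as separate instances.
- **Evaluation.** Per cohort: AUROC (Mann–Whitney form, Hanley–McNeil SE),
  Harrell's C-index (Noether SE), and the Royston–Sauerbrei D-index — the
  exponentiated Cox coefficient of the risk score's Blom rankits scaled by
  √(8/π), a robust hazard-ratio analogue. Median-split Kaplan–Meier
  curves with log-rank tests show the DFS separation.
- **Pooling.** DerSimonian–Laird random-effects meta-analysis across
  cohorts (τ² by method of moments; AUROC/C-index on the raw scale,
  D-index on the log scale), with leave-one-out influence checks and
  one-sided superiority tests between models.
- **Null tests.** (1) shuffle training labels and retrain the whole
  ensemble; (2) keep the trained architecture but substitute random gene
  pairs. Permutation p = (1 + #{null ≥ observed}) / (B_perm + 1).

Because the real cohorts are controlled-access, the package ships a
synthetic study generator (`odfsp.synthetic`) that reproduces the
*structure* the method assumes: planted prognostic pairs with a controlled
ordering-probability gap, class-linked exponential DFS with uniform
censoring, and per-cohort strictly monotone platform transforms plus batch
shifts.

## Worked example

```python
from odfsp import SimulationConfig, simulate_study, train_ensemble
from odfsp.evaluation import meta_auroc, meta_cindex, meta_dindex

study = simulate_study(SimulationConfig(seed=1))      # 2x50 training, 5 validation cohorts
ens = train_ensemble(study.training, B=20, m=60, seed=1)
print(f"ensemble: {ens.B} models, {len(ens.distinct_pairs)} distinct pairs, "
      f"{len(ens.distinct_genes)} distinct genes")
for name, est in [("AUROC", meta_auroc(ens, study.validation)),
                  ("C-index", meta_cindex(ens, study.validation))]:
    lo, hi = est.display_ci95
    print(f"meta {name}: {est.display_pooled:.3f} (95% CI {lo:.3f}-{hi:.3f}, p={est.p_value:.2e})")
est = meta_dindex(ens, study.validation)
lo, hi = est.display_ci95
print(f"meta D-index: {est.display_pooled:.2f} (95% CI {lo:.2f}-{hi:.2f}, p={est.p_value:.2e})")
```

prints

```
ensemble: 20 models, 89 distinct pairs, 101 distinct genes
meta AUROC: 0.817 (95% CI 0.752-0.881, p=6.67e-22)
meta C-index: 0.703 (95% CI 0.661-0.745, p=2.35e-21)
meta D-index: 2.99 (95% CI 2.07-4.30, p=4.19e-09)
```

The meta-AUROC of 0.82 is the pooled probability that a random
early-relapse case scores above a random non-case across the five
validation cohorts; the D-index of ~3 means a ~3-fold hazard separation
per standard-deviation step of the (rank-transformed) risk score. Both are
far above their nulls (0.5 and 1), as expected with five planted pairs at
an ordering-probability gap of 0.6.

A command-line interface mirrors the library
(`odfsp simulate|train|predict|evaluate|meta|permtest|reduce|compare|run-all`);
`odfsp run-all --config config.yaml` executes the whole pipeline and
writes the model JSON, per-cohort and forest-plot CSVs, null
distributions and a reproducible run log.

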