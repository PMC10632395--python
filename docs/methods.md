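# Methods

## Endpoint and labeling

Disease-free survival (DFS) observations are right-censored pairs
(t, δ) with t in days. The binary early-relapse endpoint dichotomizes at
a threshold T (default 365 days, inclusive):

- *high* — δ = 1 and t ≤ T (relapse observed within a year);
- *low* — t > T regardless of δ (follow-up extends past the threshold);
- *undefined* — δ = 0 and t ≤ T (censored too early to know).

Undefined samples are excluded from all binary-label computations
(training and AUROC/BAC evaluation) but retained for C-index, D-index and
Kaplan–Meier analyses, which use the full censored times. Whether the
threshold is inclusive, and the time unit (days or months at 30.44
days/month), are loader options; the defaults are ≤ 365 days. Missing
clinical covariates (age, FIGO stage) are carried as explicit absent
flags and never imputed; samples lacking a covariate are dropped from any
model that uses it, with a logged count. Gene identifiers are matched as
exact strings; probe-to-symbol harmonization is the caller's
responsibility via an optional two-column mapping file.

## The pair classifier

For an ordered gene pair (i, j), the within-sample indicator
b_ij = 1[x_i < x_j] (ties give 0) is the only feature the classifier ever
sees, so predictions are exactly invariant to strictly increasing
per-sample transforms — the property that lets one model serve RNA-seq and
microarray profiles alike.

Training proceeds in four steps:

1. **Marginal filter.** Genes are ranked by the absolute standardized
   Wilcoxon rank-sum statistic against the label (variance computed from
   the realized rank spread, which reduces to the usual tie-corrected
   form); the top m are kept (ties broken by gene id). Default m = 200
   genes at full scale, m = 60 for the default one-tenth-scale study —
   roughly the top third of its 200-gene universe.
2. **Pair scoring.** Every pair of filtered genes gets the primary score
   Δ_ij = |P̂(X_i < X_j | high) − P̂(X_i < X_j | low)| (within-class
   indicator fractions) and a secondary score γ_ij, the absolute
   between-class difference of the mean within-sample rank difference of
   the two genes. Orientation is toward the class with the larger
   indicator fraction.
3. **Greedy disjoint selection** by (Δ desc, γ desc, lexicographic pair
   id asc), skipping pairs that share a gene with an earlier selection.
   The full ordering is deterministic, so identical data give identical
   models.
4. **k selection.** k is chosen from an odd grid (default 3–25) by
   stratified cross-validated balanced accuracy (default 5 folds, seeded;
   smallest k on ties), then the top-k pairs selected on the full data are
   emitted. A single-k grid skips cross-validation.

A model votes *high* when more than k/2 oriented pair indicators agree
with the high orientation. The ensemble trains B models (default B = 20;
hundreds are appropriate at full scale) on class-balanced resamples
(default 80% of each class, without replacement within a resample) and
scores a sample by the fraction of models voting high — a continuous risk
score in [0, 1] suitable for median splits and concordance statistics. A
single full-data model (B = 1, resample fraction 1) reproduces the
classic k-TSP. Dual-platform training profiles of the same patients are
stacked as separate instances sharing the patient's label; because both
profiles are monotone views of the same measurements, the trained
ensemble scores a patient's two profiles identically.

## Performance statistics

- **AUROC** is computed by the Mann–Whitney rank formulation (ties count
  one half); the p-value is the two-sided tie-corrected normal
  approximation against 0.5, and the SE is Hanley–McNeil, floored at
  1/(n₁·n₀) so that perfectly separating cohorts (SE 0 by the formula)
  remain usable in inverse-variance pooling.
- **Balanced accuracy** is the mean of sensitivity and specificity of the
  majority vote (ensemble score > 0.5).
- **Harrell's C-index** counts pairs in which the patient with the
  shorter time has an observed event (tied times are comparable only when
  exactly one member has an event); concordance means the shorter time
  carries the higher risk score, score ties count one half. The SE is
  Noether's U-statistic approximation from per-subject concordant and
  discordant counts; the p-value is a two-sided Wald test against 0.5.
- **D-index** (Royston–Sauerbrei): risk scores are replaced by their Blom
  rankits Φ⁻¹((r − 3/8)/(n + 1/4)), divided by κ = √(8/π), and a
  univariate Cox model is fitted by Newton–Raphson with Breslow tie
  handling (gradient tolerance 1e-8, at most 100 damped steps). The
  D-index is exp(β̂) with the Cox SE on the log scale; constant scores
  return D = 1 with an undefined-SE flag. Risk scores are continuous in
  intended use, so Breslow and Efron likelihoods coincide to numerical
  precision (verified against lifelines in the tests).
- **Kaplan–Meier / log-rank** go through lifelines; the reported median
  is the first time the survival function reaches 0.5 or below, or
  undefined if never reached. Risk groups are defined within each cohort
  by the median ensemble score, ties at the median going to the low-risk
  group.

## Random-effects meta-analysis

Per-cohort estimates θ_c with variances v_c are pooled by
DerSimonian–Laird: fixed weights w = 1/v give Q = Σ w (θ − θ̄_FE)² and
τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)); random weights w* = 1/(v + τ²)
give the pooled estimate and SE = (Σw*)^{-1/2}. AUROC and C-index pool on
the raw scale (null 0.5), the D-index on the log scale (null 0).
Leave-one-out re-pooling flags influential cohorts. The between-model
superiority test z = (a − b)/√(se_a² + se_b²) treats the two pooled
estimates as independent; since the same cohorts usually underlie both
models this is anti-conservative, and a paired variant that pools
per-cohort differences is provided. A normal reference distribution is
used throughout — any degrees-of-freedom choice for a t reference would
be arbitrary here.

## Permutation nulls

Both tests use "greater or equal" counting with +1 smoothing
(p = (1 + #{null ≥ obs}) / (B_perm + 1)), so p is never zero; B_perm
defaults to 1000 in library calls, while the packaged tests and the
acceptance script run 99 replicates.

- **Label shuffle** permutes the defined training labels across patients
  (exactly preserving prevalence; a patient's platform profiles stay
  paired), retrains the full ensemble with the identical configuration,
  and records the validation meta-AUROC.
- **Random genes** keeps the trained ensemble's architecture — number of
  models, per-model k, pair orientations — and substitutes uniformly
  drawn gene pairs from the training universe, isolating gene identity as
  the tested factor. Orientations are deliberately not re-estimated; on
  exchangeable noise genes an orientation is a coin flip either way, and
  re-estimation would mix a label-overfitting component into a test meant
  to probe gene identity.

## The synthetic study generator

The generator emulates the multi-cohort structure the analysis assumes:
one training cohort profiled on two platforms plus several validation
cohorts, each a strictly monotone per-sample transform (identity, log2,
positive affine, or within-sample rank rescale) of latent log2-scale
expression, plus an additive batch shift.

Each patient carries a latent early-relapse propensity class (high with
probability 0.35 by default). For each planted signal pair, a shared
level Z ~ N(0,1) and a gap D ~ |N(1.5, 0.5²)| (~3-fold on the log2 scale)
are drawn per sample, and the sign of the gap is set so that
P(X_i < X_j) = 0.5 + δ/2 in the high class and 0.5 − δ/2 in the low class
— the ordering probability, the exact quantity a pair score estimates, is
controlled directly. A side effect of the construction is a between-class
marginal shift of about δ·E[D] per pair gene, so planted genes are
differentially expressed, as prognostic pair genes are in real tumours;
this is what makes them discoverable by the marginal rank-sum filter.
Noise genes are i.i.d. normal around gene-specific baselines N(8, 1.5²).

DFS is exponential with λ_low = ln 2 / median_low and λ_high = HR·λ_low.
Defaults median_low = 2920 days and HR = 30 put the high class at a
~97-day median — an idealized platinum-refractory early-progressor versus
durable-responder split in which relapse within one year recovers the
latent class with roughly 90% fidelity, keeping the planted truth
identifiable. Censoring is uniform on (0, c_max) with c_max calibrated by
root-finding so the marginal censoring probability equals the configured
rate (default 0.15). Continuous distributions make ties
probability-zero; a quantization option exists to exercise tie handling.

The default study mirrors a realistic multi-cohort design at one-tenth
scale: 2×50 dual-platform training profiles and five validation cohorts
of 40–80 samples with distinct transforms and batch shifts, a 200-gene
universe, five planted pairs at δ = 0.6. Analysis defaults are scaled to
match (m = 60, B = 20). These sizes keep the full pipeline — including
ensemble retraining inside the permutation tests — tractable on a single
CPU while leaving the planted signal comfortably detectable.

**What passing tests do and do not show.** The generator reproduces the
rank structure, censoring and platform heterogeneity the method relies
on, but not real expression covariance, correlated biological pathways,
probe-level noise (platform transforms here are noise-free and exactly
monotone), cohort-specific case mix, or an early-relapse endpoint that is
only weakly linked to any latent class. Passing the recovery and
calibration tests therefore demonstrates correctness of the machinery
under the model's own assumptions, not expected performance on real
cohorts.

## Numerical conventions and edge cases

- Expression ties score as "not less than" (indicator 0); tied pair
  scores break by γ then lexicographic pair id; pairs are stored with
  genes in lexicographic order, flipping orientation as needed.
- Degenerate inputs raise informative errors: one-class labels, zero
  comparable pairs, all-equal scores in a median split, an empty
  gene-set universe, fewer disjoint pairs than the smallest requested k.
- Logistic fits use IRLS (statsmodels GLM, tolerance 1e-8, ≤ 100
  iterations); complete separation is flagged non-converged with the last
  iterate rather than raising.
- The Cox Newton–Raphson step is clipped to |step| ≤ 5 to prevent
  overshoot on near-separating covariates.
- The signature score rescales each weighted gene to [−1, 1] via its
  2.5%/97.5% quantile range (clipped) before weighted averaging; missing
  weighted genes are dropped from numerator and denominator with a log.
- The model-size reduction sweep varies the per-model pair cap with a
  fixed seed, so resamples are shared across budgets and a smaller
  model's pair list is a prefix of the larger one's — making the
  distinct-gene count non-decreasing in the budget by construction.
- All randomness flows from explicit integer seeds through named
  substreams; the same configuration and seed give byte-identical model
  files and reports.

## Known limitations

- The random-effects superiority test's independence approximation is
  anti-conservative (see above); prefer the paired variant when the same
  cohorts underlie both models.
- The D-index SE is undefined for constant scores, and small cohorts with
  very few events can legitimately fail the Cox fit's n ≥ 10 / ≥ 2 events
  preconditions.
- The AUROC p-value uses the tie-corrected normal approximation; exact
  small-sample Mann–Whitney p-values are out of scope (intended n ≥ 30).
- Cross-platform gene-identifier mapping, probe-level preprocessing and
  downloading of real cohorts are deliberately out of scope.
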