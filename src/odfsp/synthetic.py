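"""Synthetic multi-cohort study generator.

Emulates the structure of a dual-platform training cohort plus several
validation cohorts profiled on heterogeneous platforms: a latent binary
early-relapse propensity class per patient, planted prognostic gene pairs
whose within-sample ordering probability differs between classes by a
controlled amount, exponential disease-free survival with a class-specific
hazard, independent uniform right-censoring calibrated to a target rate,
and per-cohort strictly-monotone platform transforms plus additive batch
shifts.

Because every platform distortion is strictly increasing within a sample,
the within-sample gene ranking — the only thing a rank-based pair
classifier sees — is preserved exactly; this is the property the generator
is designed to exercise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import rankdata

from .data_model import (
    ClinicalRecord,
    CohortProfile,
    ExpressionMatrix,
    Platform,
    SurvivalRecord,
    apply_dichotomization,
    save_clinical,
    save_expression,
)

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class CohortSpec:
    """One cohort to simulate.

    ``transform`` is one of ``identity``, ``log2``, ``quantile_rankscale``
    or ``affine:<a>:<b>`` with a > 0; applied within each sample (strictly
    increasing), after which ``batch_shift`` is added.
    """

    name: str
    n_samples: int
    platform: Platform
    transform: str = "identity"
    batch_shift: float = 0.0


def _default_cohort_specs() -> list[CohortSpec]:
    # one-tenth-scale default study: 2x50 dual-platform training,
    # five validation cohorts of 40-80 with distinct monotone distortions
    return [
        CohortSpec("train", 50, Platform.SEQUENCING, "identity", 0.0),
        CohortSpec("val_A", 80, Platform.SEQUENCING, "identity", 0.5),
        CohortSpec("val_B", 60, Platform.SEQUENCING, "affine:1.4:3.0", 0.0),
        CohortSpec("val_C", 70, Platform.ARRAY, "log2", -0.3),
        CohortSpec("val_D", 40, Platform.ARRAY, "quantile_rankscale", 0.0),
        CohortSpec("val_E", 55, Platform.ARRAY, "log2", 1.5),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_study`.

    ``effect_delta`` is the planted difference in ordering probability
    P(Xi < Xj | high) - P(Xi < Xj | low) for each signal pair.  Survival
    defaults put the high-propensity class at a ~3-month median DFS against
    a multi-year low-class median, so that relapse within one year tracks
    the latent class closely (an idealised early-progressor vs durable-
    responder split).
    """

    n_genes: int = 200
    n_signal_pairs: int = 5
    effect_delta: float = 0.6
    cohort_specs: list[CohortSpec] = field(default_factory=_default_cohort_specs)
    prevalence_high: float = 0.35
    hazard_ratio_high: float = 30.0
    baseline_median_dfs_days: float = 2920.0
    censor_rate: float = 0.15
    dual_platform_training: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.effect_delta <= 1):
            raise ValueError("effect_delta must be in [0, 1]")
        if 2 * self.n_signal_pairs > self.n_genes:
            raise ValueError("need n_genes >= 2 * n_signal_pairs")
        if not (0 < self.prevalence_high < 1):
            raise ValueError("prevalence_high must be in (0, 1)")
        if self.hazard_ratio_high < 1:
            raise ValueError("hazard_ratio_high must be >= 1")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if any(s.n_samples < 1 for s in self.cohort_specs):
            raise ValueError("all cohort sizes must be positive")


@dataclass
class SyntheticStudy:
    training: list[CohortProfile]
    validation: list[CohortProfile]
    truth: dict

    @property
    def all_cohorts(self) -> list[CohortProfile]:
        return list(self.training) + list(self.validation)


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def apply_transform(values: np.ndarray, transform: str, batch_shift: float = 0.0) -> np.ndarray:
    """Apply a within-sample strictly increasing transform to a genes x
    samples matrix, then add ``batch_shift``."""
    if transform == "identity":
        out = values.copy()
    elif transform == "log2":
        # shift each sample to be >= 1 so log2 is defined; the per-sample
        # offset is constant within the sample, preserving strict order
        out = np.log2(values - values.min(axis=0, keepdims=True) + 1.0)
    elif transform == "quantile_rankscale":
        out = (rankdata(values, axis=0, method="ordinal") - 0.5) / values.shape[0]
    elif transform.startswith("affine:"):
        _, a, b = transform.split(":")
        a, b = float(a), float(b)
        if a <= 0:
            raise ValueError("affine slope must be > 0")
        out = a * values + b
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return out + batch_shift


def calibrate_uniform_censoring(
    lam_low: float, lam_high: float, prevalence_high: float, censor_rate: float
) -> float:
    """Upper bound c_max of Uniform(0, c_max) censoring such that
    P(C < T) equals ``censor_rate`` under the two-class exponential mixture.

    P(censored) = (1/c) * integral_0^c S(t) dt with
    S(t) = pi * exp(-lam_high t) + (1 - pi) * exp(-lam_low t).
    """
    pi = prevalence_high

    def prob_censored(c):
        return (pi * (1 - np.exp(-lam_high * c)) / lam_high
                + (1 - pi) * (1 - np.exp(-lam_low * c)) / lam_low) / c

    lo, hi = 1e-6, 1e6 / lam_low
    # prob_censored decreases from 1 (c->0) to 0 (c->inf)
    if not (prob_censored(hi) < censor_rate < prob_censored(lo)):
        raise ValueError(f"cannot calibrate uniform censoring to rate {censor_rate}")
    return float(brentq(lambda c: prob_censored(c) - censor_rate, lo, hi, xtol=1e-9))


def _simulate_latent_expression(
    rng: np.random.Generator,
    config: SimulationConfig,
    classes: np.ndarray,
    gene_means: np.ndarray,
    pair_index: list[tuple[int, int]],
) -> np.ndarray:
    """Latent (pre-transform) genes x samples matrix on a log2-like scale.

    Signal pair (i, j): shared level Z ~ N(0,1), gap D ~ |N(1.5, 0.5^2)| (a
    ~3-fold expression gap on the log2 scale), and sign s = +1 (so Xi < Xj)
    with probability 0.5 + delta/2 in the high class and 0.5 - delta/2 in
    the low class; Xi = mu + Z - s*D/2, Xj = mu + Z + s*D/2.  This controls
    the ordering probability — the quantity a pair score estimates —
    exactly, and as a side effect gives each pair gene a between-class
    marginal shift of about delta * E[D], so planted genes are themselves
    differentially expressed (as prognostic pair genes are in real data)
    and discoverable by the marginal rank-sum filter.  Noise genes are
    i.i.d. N(mu_g, 1) in both classes.
    """
    n = classes.size
    X = gene_means[:, None] + rng.normal(0.0, 1.0, size=(config.n_genes, n))
    p_high = 0.5 + config.effect_delta / 2.0
    p_low = 0.5 - config.effect_delta / 2.0
    p = np.where(classes == 1, p_high, p_low)
    for gi, gj in pair_index:
        mu = (gene_means[gi] + gene_means[gj]) / 2.0
        z = rng.normal(0.0, 1.0, size=n)
        gap = np.abs(rng.normal(1.5, 0.5, size=n)) + 1e-6
        s = np.where(rng.uniform(size=n) < p, 1.0, -1.0)
        X[gi, :] = mu + z - s * gap / 2.0
        X[gj, :] = mu + z + s * gap / 2.0
    return X


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Draw a full multi-cohort study; byte-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    gene_means = rng.normal(8.0, 1.5, size=config.n_genes)

    signal_genes = rng.choice(config.n_genes, size=2 * config.n_signal_pairs, replace=False)
    pair_index = [(int(signal_genes[2 * p]), int(signal_genes[2 * p + 1]))
                  for p in range(config.n_signal_pairs)]

    lam_low = LN2 / config.baseline_median_dfs_days
    lam_high = config.hazard_ratio_high * lam_low
    c_max = None
    if config.censor_rate > 0:
        c_max = calibrate_uniform_censoring(
            lam_low, lam_high, config.prevalence_high, config.censor_rate)

    training: list[CohortProfile] = []
    validation: list[CohortProfile] = []
    truth_classes: dict[str, dict[str, int]] = {}

    for spec in config.cohort_specs:
        is_training = spec is config.cohort_specs[0]
        n = spec.n_samples
        sample_ids = [f"{spec.name}_s{i:03d}" for i in range(n)]
        classes = (rng.uniform(size=n) < config.prevalence_high).astype(int)
        X = _simulate_latent_expression(rng, config, classes, gene_means, pair_index)

        lam = np.where(classes == 1, lam_high, lam_low)
        t_event = rng.exponential(1.0 / lam)
        if c_max is not None:
            t_cens = rng.uniform(0.0, c_max, size=n)
            time = np.minimum(t_event, t_cens)
            event = t_event <= t_cens
        else:
            time, event = t_event, np.ones(n, dtype=bool)
        time = np.maximum(time, 0.5)  # guard against zero-day observations

        def build_cohort(cname, platform, transform, shift):
            expr = ExpressionMatrix(
                list(gene_ids), list(sample_ids), apply_transform(X, transform, shift))
            clinical = [
                ClinicalRecord(
                    sample_id=sid,
                    survival=SurvivalRecord(dfs_time=float(t), dfs_event=bool(e)),
                    age=float(np.round(55 + 10 * a, 1)),
                    figo_stage=int(st),
                    cohort=cname,
                    platform=platform,
                )
                for sid, t, e, a, st in zip(
                    sample_ids, time, event,
                    rng.standard_normal(n),
                    rng.integers(2, 5, size=n),
                )
            ]
            return apply_dichotomization(
                CohortProfile(cname, expr, clinical, platform))

        if is_training and config.dual_platform_training:
            # same patients profiled twice: two deterministic monotone views
            training.append(build_cohort(f"{spec.name}_seq", Platform.SEQUENCING,
                                         spec.transform, spec.batch_shift))
            training.append(build_cohort(f"{spec.name}_array", Platform.ARRAY,
                                         "log2", spec.batch_shift + 0.7))
            truth_classes[f"{spec.name}_seq"] = dict(zip(sample_ids, classes.tolist()))
            truth_classes[f"{spec.name}_array"] = dict(zip(sample_ids, classes.tolist()))
        elif is_training:
            training.append(build_cohort(spec.name, spec.platform,
                                         spec.transform, spec.batch_shift))
            truth_classes[spec.name] = dict(zip(sample_ids, classes.tolist()))
        else:
            validation.append(build_cohort(spec.name, spec.platform,
                                           spec.transform, spec.batch_shift))
            truth_classes[spec.name] = dict(zip(sample_ids, classes.tolist()))

    truth = {
        "pairs": [
            {"gene_i": gene_ids[gi], "gene_j": gene_ids[gj], "orientation": True}
            for gi, gj in pair_index
        ],
        "classes": truth_classes,
        "config": {
            "effect_delta": config.effect_delta,
            "prevalence_high": config.prevalence_high,
            "hazard_ratio_high": config.hazard_ratio_high,
            "baseline_median_dfs_days": config.baseline_median_dfs_days,
            "censor_rate": config.censor_rate,
            "seed": config.seed,
        },
    }
    return SyntheticStudy(training=training, validation=validation, truth=truth)


def truth_report(study: SyntheticStudy) -> dict:
    """Realized per-cohort label counts, censor rates and per-pair effects."""
    from .data_model import RelapseLabel  # local to avoid cycle confusion

    per_cohort = {}
    for cohort in study.all_cohorts:
        labs = cohort.labels()
        times, events = cohort.survival_arrays()
        per_cohort[cohort.name] = {
            "n": cohort.n_samples,
            "high": sum(l is RelapseLabel.HIGH for l in labs),
            "low": sum(l is RelapseLabel.LOW for l in labs),
            "undefined": sum(l is RelapseLabel.UNDEFINED for l in labs),
            "censor_rate": float(1.0 - events.mean()),
        }

    # realized ordering-probability gap per planted pair, pooled over cohorts,
    # using the latent class truth
    pair_effects = []
    for pair in study.truth["pairs"]:
        gi, gj = pair["gene_i"], pair["gene_j"]
        n_hi = n_lo = lt_hi = lt_lo = 0
        for cohort in study.all_cohorts:
            classes = study.truth["classes"][cohort.name]
            sub = cohort.expression.subset_genes([gi, gj])
            less = sub.values[0, :] < sub.values[1, :]
            cls = np.array([classes[s] for s in cohort.expression.sample_ids])
            lt_hi += int(less[cls == 1].sum()); n_hi += int((cls == 1).sum())
            lt_lo += int(less[cls == 0].sum()); n_lo += int((cls == 0).sum())
        pair_effects.append({
            "gene_i": gi, "gene_j": gj,
            "p_less_high": lt_hi / n_hi if n_hi else float("nan"),
            "p_less_low": lt_lo / n_lo if n_lo else float("nan"),
            "realized_delta": (lt_hi / n_hi - lt_lo / n_lo) if n_hi and n_lo else float("nan"),
        })
    return {"cohorts": per_cohort, "planted_pairs": pair_effects}


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write each cohort as TSV/CSV in the package's standard formats,
    plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cohort in study.all_cohorts:
        save_expression(cohort.expression, outdir / f"{cohort.name}.expression.tsv")
        save_clinical(cohort.clinical, outdir / f"{cohort.name}.clinical.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=1)
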