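"""Baseline models and auxiliary analyses.

Clinicopathologic logistic model (age + FIGO stage), univariable screening,
weighted gene-signature scores (quantile-rescaled expression), the
model-size reduction sweep for the pair ensemble, and generic
hypergeometric gene-set enrichment with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hypergeom, norm
from statsmodels.stats.multitest import multipletests

from .data_model import ClinicalRecord, CohortProfile, ExpressionMatrix, RelapseLabel
from .evaluation import meta_auroc
from .ktsp import train_ensemble

logger = logging.getLogger("odfsp")


# ---------------------------------------------------------------------------
# clinicopathologic logistic model
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    coefficients: dict[str, float]  # intercept + one per covariate
    covariates: list[str]
    converged: bool
    n: int
    se: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    deviance_path: list[float] = field(default_factory=list)
    n_dropped: int = 0


def _design_from_records(
    records: list[ClinicalRecord], covariates: list[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Outcome (early relapse = 1) and covariate matrix, dropping samples
    with undefined labels or absent covariates (counted, never imputed)."""
    y, rows = [], []
    dropped = 0
    for rec in records:
        lab = rec.survival.early_relapse_label
        vals = [getattr(rec, c) for c in covariates]
        if lab is RelapseLabel.UNDEFINED or any(v is None for v in vals):
            dropped += 1
            continue
        y.append(1 if lab is RelapseLabel.HIGH else 0)
        rows.append([float(v) for v in vals])
    return np.asarray(y, dtype=float), np.asarray(rows, dtype=float), dropped


def fit_logistic(y: np.ndarray, X: np.ndarray, names: list[str]) -> LogisticModel:
    """Maximum-likelihood logistic fit by IRLS (tolerance 1e-8, <=100 its);
    complete separation is flagged as non-converged with the last iterate."""
    design = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    converged = True
    try:
        with np.errstate(all="ignore"):
            res = model.fit(maxiter=100, tol=1e-8)
        converged = bool(getattr(res, "converged", True))
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)
        # keep only true IRLS iterates (statsmodels prepends init values)
        finite = [float(d) for d in res.fit_history.get("deviance", [])
                  if np.isfinite(d)]
        dev_path = finite[1:]
    except Exception:  # perfect separation or singular design
        converged = False
        params = np.zeros(design.shape[1])
        bse = np.full(design.shape[1], np.nan)
        pvals = np.full(design.shape[1], np.nan)
        dev_path = []
    if np.any(np.abs(params) > 50) or np.any(~np.isfinite(bse)):
        converged = False
    keys = ["intercept"] + names
    return LogisticModel(
        coefficients=dict(zip(keys, params.tolist())),
        covariates=list(names),
        converged=converged,
        n=int(y.size),
        se=dict(zip(keys, bse.tolist())),
        p_values=dict(zip(keys, pvals.tolist())),
        deviance_path=dev_path,
    )


def fit_clinical_model(
    records: list[ClinicalRecord], covariates: tuple[str, ...] = ("age", "figo_stage")
) -> LogisticModel:
    """Logistic early-relapse model on clinicopathologic covariates
    (FIGO stage entered as ordinal numeric, age in years)."""
    names = list(covariates)
    y, X, dropped = _design_from_records(records, names)
    if y.size == 0 or min((y == 1).sum(), (y == 0).sum()) < 10:
        raise ValueError("need >= 10 samples per class with complete covariates")
    if dropped:
        logger.info("clinical model: dropped %d sample(s) with undefined label "
                    "or absent covariates", dropped)
    out = fit_logistic(y, X, names)
    out.n_dropped = dropped
    return out


def predict_logistic(model: LogisticModel, records: list[ClinicalRecord]) -> np.ndarray:
    """Fitted early-relapse probability per record (NaN where covariates
    are absent)."""
    out = np.full(len(records), np.nan)
    for i, rec in enumerate(records):
        vals = [getattr(rec, c) for c in model.covariates]
        if any(v is None for v in vals):
            continue
        eta = model.coefficients["intercept"] + sum(
            model.coefficients[c] * float(v) for c, v in zip(model.covariates, vals))
        out[i] = 1.0 / (1.0 + np.exp(-eta))
    return out


def univariable_screen(
    records: list[ClinicalRecord], covariates: tuple[str, ...] = ("age", "figo_stage")
) -> pd.DataFrame:
    """One logistic fit per covariate; odds ratio per unit with Wald p,
    sorted by p.  Constant covariates are excluded with a warning."""
    rows = []
    for cov in covariates:
        y, X, _ = _design_from_records(records, [cov])
        if y.size == 0 or X.size == 0 or np.ptp(X[:, 0]) == 0:
            logger.warning("univariable screen: covariate %r constant or empty; skipped", cov)
            continue
        fit = fit_logistic(y, X, [cov])
        beta = fit.coefficients[cov]
        rows.append({
            "covariate": cov,
            "odds_ratio": float(np.exp(beta)),
            "coef": beta,
            "se": fit.se[cov],
            "p": fit.p_values[cov],
            "n": fit.n,
            "converged": fit.converged,
        })
    return pd.DataFrame(rows).sort_values("p", ignore_index=True) if rows else pd.DataFrame(
        columns=["covariate", "odds_ratio", "coef", "se", "p", "n", "converged"])


# ---------------------------------------------------------------------------
# weighted gene-signature score
# ---------------------------------------------------------------------------

@dataclass
class SignatureScore:
    gene_weights: dict[str, float]
    scores: np.ndarray  # per sample
    sample_ids: list[str]
    missing_genes: list[str]


def signature_score(
    expr: ExpressionMatrix,
    weights: dict[str, float],
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> SignatureScore:
    """Weighted-average signature score on quantile-rescaled expression.

    Each weighted gene is rescaled per cohort to [-1, 1] using its
    ``quantiles`` range (values outside clipped), then
    score = sum_g w_g * x~_g / sum_g |w_g|.  Weighted genes absent from the
    matrix are dropped from both sums (logged); zero usable genes is an
    error.  Zero-weight genes are ignored.
    """
    usable = {g: w for g, w in weights.items() if w != 0}
    present = [g for g in usable if g in set(expr.gene_ids)]
    missing = sorted(set(usable) - set(present))
    if missing:
        logger.warning("signature_score: %d weighted gene(s) missing: %s",
                       len(missing), missing[:5])
    if not present:
        raise ValueError("no weighted genes present in expression matrix")
    sub = expr.subset_genes(present)
    q_lo = np.quantile(sub.values, quantiles[0], axis=1, keepdims=True)
    q_hi = np.quantile(sub.values, quantiles[1], axis=1, keepdims=True)
    span = np.where(q_hi > q_lo, q_hi - q_lo, 1.0)
    rescaled = np.clip(2.0 * (sub.values - q_lo) / span - 1.0, -1.0, 1.0)
    w = np.array([usable[g] for g in present])
    scores = (w[:, None] * rescaled).sum(axis=0) / np.abs(w).sum()
    return SignatureScore(
        gene_weights={g: usable[g] for g in present},
        scores=scores,
        sample_ids=list(expr.sample_ids),
        missing_genes=missing,
    )


# ---------------------------------------------------------------------------
# model-size reduction sweep
# ---------------------------------------------------------------------------

def reduction_sweep(
    training: list[CohortProfile],
    validation: list[CohortProfile],
    max_pairs_grid: list[int],
    train_config: dict | None = None,
    seed: int = 0,
    tolerance: float = 0.01,
) -> pd.DataFrame:
    """Retrain the ensemble under shrinking model-size budgets.

    Each budget caps the per-model pair count (the k grid is truncated at
    the cap); reported are the distinct gene count and the validation
    meta-AUROC per budget, with the smallest budget within ``tolerance``
    of the full model's AUROC flagged.  With a fixed seed the resamples
    are identical across budgets and a smaller model's pair list is a
    prefix of the larger one's, so the distinct gene count is
    non-decreasing in the budget.
    """
    if len(max_pairs_grid) < 2:
        raise ValueError("need at least two budget sizes")
    cfg = dict(train_config or {})
    base_grid = tuple(cfg.pop("k_grid", tuple(range(3, 26, 2))))
    sizes = sorted(set(int(s) for s in max_pairs_grid))
    rows = []
    for cap in sizes:
        grid = tuple(k for k in base_grid if k <= cap)
        if not grid:
            raise ValueError(f"budget {cap} below the smallest k in {base_grid}")
        ens = train_ensemble(training, k_grid=grid, seed=seed, **cfg)
        est = meta_auroc(ens, validation)
        rows.append({
            "max_pairs": cap,
            "distinct_genes": len(ens.distinct_genes),
            "distinct_pairs": len(ens.distinct_pairs),
            "meta_auroc": est.pooled,
        })
    df = pd.DataFrame(rows)
    full = df["meta_auroc"].iloc[-1]
    df["within_tolerance_of_full"] = df["meta_auroc"] >= full - tolerance
    smallest = df.index[df["within_tolerance_of_full"]].min()
    df["recommended"] = [i == smallest for i in df.index]
    return df


# ---------------------------------------------------------------------------
# hypergeometric gene-set enrichment
# ---------------------------------------------------------------------------

def load_gmt(path: str | Path) -> dict[str, set[str]]:
    """Standard GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def hypergeometric_enrichment(
    signature_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    p = P(X >= overlap) with population |universe|, |set ∩ universe|
    successes, |signature| draws; FDR by Benjamini–Hochberg across sets.
    """
    if not universe:
        raise ValueError("empty universe")
    signature = set(signature_genes) & universe
    rows = []
    for name, genes in gene_sets.items():
        in_univ = genes & universe
        overlap = len(signature & in_univ)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(in_univ), len(signature)))
        rows.append({"set": name, "set_size": len(in_univ), "overlap": overlap, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "set"], ignore_index=True)
    return df
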