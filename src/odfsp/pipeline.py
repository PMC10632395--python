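"""End-to-end orchestration: load or simulate cohorts, train the pair
ensemble, evaluate every cohort, pool by random-effects meta-analysis,
compare against the clinicopathologic baseline, optionally run the
permutation nulls, and write a deterministic artifact bundle."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparators import fit_clinical_model, predict_logistic
from .data_model import CohortProfile, Platform, load_cohort
from .evaluation import (
    cohort_auroc,
    cohort_bac,
    cohort_cindex,
    cohort_dindex,
)
from .ktsp import OdfspEnsemble, save_ensemble, score_ensemble, train_ensemble
from .meta import MetaEstimate, compare_meta, forest_table, leave_one_out, pool_random_effects
from .nulls import label_shuffle_test, random_gene_test
from .survstats import concordance_index, km_curve, logrank, median_split
from .synthetic import SimulationConfig, SyntheticStudy, simulate_study

logger = logging.getLogger("odfsp")


@dataclass
class CohortPaths:
    name: str
    expression: str
    clinical: str
    platform: str
    role: str  # train | validate


@dataclass
class RunConfig:
    cohorts: list[CohortPaths] = field(default_factory=list)
    synthetic: SimulationConfig | None = None
    threshold_days: float = 365.0
    m: int = 60
    k_grid: tuple[int, ...] = tuple(range(3, 26, 2))
    B: int = 20
    resample_fraction: float = 0.8
    cv_folds: int = 5
    B_perm: int = 0  # 0 = skip permutation tests
    seed: int = 0
    outdir: str = "odfsp_run"

    def train_kwargs(self) -> dict:
        return {"B": self.B, "resample_fraction": self.resample_fraction,
                "m": self.m, "k_grid": self.k_grid, "cv_folds": self.cv_folds}


def _load_study(config: RunConfig) -> tuple[list[CohortProfile], list[CohortProfile]]:
    if config.synthetic is not None:
        study: SyntheticStudy = simulate_study(config.synthetic)
        return study.training, study.validation
    training, validation = [], []
    for c in config.cohorts:
        cohort = load_cohort(c.expression, c.clinical, Platform(c.platform),
                             name=c.name, threshold_days=config.threshold_days)
        (training if c.role == "train" else validation).append(cohort)
    if not training:
        raise ValueError("config must define exactly one training cohort group")
    if not validation:
        raise ValueError("config must define at least one validation cohort")
    return training, validation


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:10]


def _meta_row(m: MetaEstimate) -> dict:
    return {"pooled": m.display_pooled, "se": m.se,
            "lo": m.display_ci95[0], "hi": m.display_ci95[1],
            "p": m.p_value, "tau2": m.tau2, "Q": m.Q}


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; identical config + seed gives identical
    outputs.  Returns the report dict (also written as report.json)."""
    outdir = Path(config.outdir) / f"run-{_config_hash(config)}"
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_all_inner(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_all_inner(config: RunConfig, outdir: Path) -> dict:
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(0, 2**31 - 1))
             for name in ("train", "perm_labels", "perm_genes")}
    logger.info("odfsp %s seed=%d substreams=%s", __version__, config.seed, seeds)

    logger.info("stage: load")
    training, validation = _load_study(config)

    logger.info("stage: train ensemble (B=%d)", config.B)
    ens = train_ensemble(training, seed=seeds["train"], **config.train_kwargs())
    save_ensemble(ens, outdir / "model.json",
                  meta={"seed": config.seed, "version": __version__})

    logger.info("stage: per-cohort evaluation")
    rows, km_rows = [], []
    per_stat: dict[str, list] = {"auroc": [], "cindex": [], "dindex_log": []}
    for cohort in validation:
        for fn, stat in ((cohort_auroc, "auroc"), (cohort_cindex, "cindex"),
                         (cohort_dindex, "dindex_log")):
            est = fn(ens, cohort)
            per_stat[stat].append(est)
            rows.append({"cohort": cohort.name, "statistic": stat,
                         "value": est.display_value, "se": est.se,
                         "lo": est.display_ci95[0], "hi": est.display_ci95[1],
                         "p": est.p_value, "n": est.n})
        rows.append({"cohort": cohort.name, "statistic": "bac",
                     "value": cohort_bac(ens, cohort), "se": np.nan,
                     "lo": np.nan, "hi": np.nan, "p": np.nan, "n": cohort.n_samples})
        # median-split Kaplan-Meier + log-rank within cohort
        scores = score_ensemble(ens, cohort.expression)
        times, events = cohort.survival_arrays()
        try:
            groups = median_split(scores)
            chi2, p = logrank(times[groups == 0], events[groups == 0],
                              times[groups == 1], events[groups == 1])
            km_lo = km_curve(times[groups == 0], events[groups == 0])
            km_hi = km_curve(times[groups == 1], events[groups == 1])
            km_rows.append({
                "cohort": cohort.name, "n_low": int((groups == 0).sum()),
                "n_high": int((groups == 1).sum()),
                "median_dfs_low": km_lo.median, "median_dfs_high": km_hi.median,
                "logrank_chi2": chi2, "logrank_p": p,
            })
        except ValueError as exc:
            logger.warning("cohort %s: median split skipped (%s)", cohort.name, exc)
            km_rows.append({"cohort": cohort.name, "n_low": np.nan, "n_high": np.nan,
                            "median_dfs_low": np.nan, "median_dfs_high": np.nan,
                            "logrank_chi2": np.nan, "logrank_p": np.nan})
    pd.DataFrame(rows).to_csv(outdir / "per_cohort.csv", index=False)
    pd.DataFrame(km_rows).to_csv(outdir / "km_median_split.csv", index=False)

    logger.info("stage: meta-analysis")
    metas = {stat: pool_random_effects(per_stat[stat]) for stat in per_stat}
    for stat, m in metas.items():
        forest_table(m).to_csv(outdir / f"forest_{stat}.csv", index=False)
    loo = {stat: [(x.label, x.display_pooled) for x in leave_one_out(per_stat[stat])]
           for stat in per_stat if len(per_stat[stat]) >= 3}

    logger.info("stage: clinicopathologic comparison")
    clinical_cmp = None
    try:
        train_records = [r for c in training for r in c.clinical]
        clin_model = fit_clinical_model(train_records)
        clin_ests = []
        for cohort in validation:
            probs = predict_logistic(clin_model, cohort.clinical)
            mask = np.isfinite(probs)
            times, events = cohort.survival_arrays()
            if mask.sum() >= 10:
                clin_ests.append(concordance_index(
                    probs[mask], times[mask], events[mask], cohort=cohort.name))
        if len(clin_ests) >= 2:
            clin_meta = pool_random_effects(clin_ests)
            z, p_sup = compare_meta(metas["cindex"], clin_meta)
            clinical_cmp = {"clinical_meta_cindex": clin_meta.pooled,
                            "odfsp_meta_cindex": metas["cindex"].pooled,
                            "z": z, "p_one_sided": p_sup,
                            "clinical_converged": clin_model.converged}
    except ValueError as exc:
        logger.warning("clinical comparison skipped: %s", exc)

    perm = {}
    if config.B_perm > 0:
        logger.info("stage: permutation nulls (B_perm=%d)", config.B_perm)
        ls = label_shuffle_test(training, validation, config.train_kwargs(),
                                B_perm=config.B_perm, seed=seeds["perm_labels"])
        rg = random_gene_test(ens, training, validation,
                              B_perm=config.B_perm, seed=seeds["perm_genes"])
        for name, res in (("label_shuffle", ls), ("random_genes", rg)):
            pd.DataFrame({"null_meta_auroc": res.null_values}).to_csv(
                outdir / f"null_{name}.csv", index=False)
            perm[name] = {"observed": res.observed, "p": res.p_value}

    report = {
        "seed": config.seed,
        "version": __version__,
        "n_training_instances": sum(c.n_samples for c in training),
        "n_validation_samples": sum(c.n_samples for c in validation),
        "distinct_pairs": len(ens.distinct_pairs),
        "distinct_genes": len(ens.distinct_genes),
        "meta": {stat: _meta_row(m) for stat, m in metas.items()},
        "leave_one_out": loo,
        "clinical_comparison": clinical_cmp,
        "permutation": perm,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    logger.info("done: outputs in %s", outdir)
    report["outdir"] = str(outdir)
    report["_ensemble"] = ens
    return report
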