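"""Permutation null tests for the gene-pair predictor.

Two complementary nulls establish that the predictor's validation signal
is not chance:

* **label shuffle** — permute the training early-relapse labels (keeping a
  patient's dual-platform instances paired), retrain the full ensemble
  with the identical configuration, and record the validation meta-AUROC;
* **random genes** — keep the trained ensemble's architecture (number of
  models, per-model k, orientations) but substitute uniformly sampled gene
  pairs, isolating the identity of the selected genes as the tested
  factor.

p-values use "greater or equal" counting with +1 smoothing,
p = (1 + #{null >= observed}) / (B_perm + 1), so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import CohortProfile, RelapseLabel, filter_for_binary_eval
from .evaluation import mean_bac, meta_auroc
from .ktsp import KtspModel, OdfspEnsemble, PairRule, train_ensemble


@dataclass
class PermutationResult:
    observed: float
    null_values: list[float]
    p_value: float
    test: str  # label_shuffle | random_genes
    seed: int
    extras: dict = field(default_factory=dict)


def _perm_p(observed: float, nulls: np.ndarray) -> float:
    return float((1 + (nulls >= observed).sum()) / (nulls.size + 1))


def _relabel_cohort(cohort: CohortProfile, label_map: dict[str, RelapseLabel]) -> CohortProfile:
    clinical = [
        replace(rec, survival=replace(rec.survival,
                                      early_relapse_label=label_map[rec.sample_id]))
        for rec in cohort.clinical
    ]
    return CohortProfile(cohort.name, cohort.expression, clinical, cohort.platform)


def label_shuffle_test(
    training: list[CohortProfile],
    validation: list[CohortProfile],
    train_config: dict | None = None,
    B_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Null distribution of the validation meta-AUROC under label permutation.

    Each replicate permutes the defined training labels across patients
    (class prevalence preserved exactly; a patient's platform profiles stay
    paired), retrains the ensemble with the same configuration, and
    evaluates the validation meta-AUROC.
    """
    if B_perm < 1:
        raise ValueError("B_perm must be >= 1")
    cfg = dict(train_config or {})
    rng = np.random.default_rng(seed)

    filtered = [filter_for_binary_eval(c) for c in training]
    ref = filtered[0]
    patients = list(ref.expression.sample_ids)
    labels = [r.survival.early_relapse_label for r in ref.clinical]

    ens = train_ensemble(filtered, seed=int(rng.integers(0, 2**31 - 1)), **cfg)
    observed = float(meta_auroc(ens, validation).pooled)
    observed_bac = mean_bac(ens, validation)

    nulls, null_bacs = [], []
    for _ in range(B_perm):
        perm = rng.permutation(len(patients))
        label_map = {patients[i]: labels[perm[i]] for i in range(len(patients))}
        shuffled = [_relabel_cohort(c, label_map) for c in filtered]
        ens_b = train_ensemble(shuffled, seed=int(rng.integers(0, 2**31 - 1)), **cfg)
        nulls.append(float(meta_auroc(ens_b, validation).pooled))
        null_bacs.append(mean_bac(ens_b, validation))

    nulls = np.array(nulls)
    return PermutationResult(
        observed=observed,
        null_values=nulls.tolist(),
        p_value=_perm_p(observed, nulls),
        test="label_shuffle",
        seed=seed,
        extras={"observed_bac": observed_bac, "null_bacs": null_bacs},
    )


def _random_architecture_clone(
    ens: OdfspEnsemble, universe: list[str], rng: np.random.Generator
) -> OdfspEnsemble:
    models = []
    for model in ens.models:
        picks = rng.choice(len(universe), size=2 * model.k, replace=False)
        pairs = [
            PairRule(universe[picks[2 * q]], universe[picks[2 * q + 1]],
                     0.0, model.pairs[q].orientation, 0.0)
            for q in range(model.k)
        ]
        models.append(KtspModel(pairs=pairs, k=model.k,
                                training_meta={"random_clone": True}))
    return OdfspEnsemble(models=models)


def random_gene_test(
    ensemble: OdfspEnsemble,
    training: list[CohortProfile],
    validation: list[CohortProfile],
    B_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Null distribution from ensembles with the same architecture but
    uniformly resampled gene pairs from the training gene universe."""
    if B_perm < 1:
        raise ValueError("B_perm must be >= 1")
    universe = [g for g in training[0].expression.gene_ids
                if all(g in set(c.expression.gene_ids) for c in training[1:])]
    max_need = 2 * max(m.k for m in ensemble.models)
    if len(universe) <= max(len(ensemble.distinct_genes), max_need):
        raise ValueError("gene universe too small for random-gene null")
    rng = np.random.default_rng(seed)
    observed = float(meta_auroc(ensemble, validation).pooled)
    observed_bac = mean_bac(ensemble, validation)
    nulls, null_bacs = [], []
    for _ in range(B_perm):
        clone = _random_architecture_clone(ensemble, universe, rng)
        nulls.append(float(meta_auroc(clone, validation).pooled))
        null_bacs.append(mean_bac(clone, validation))
    nulls = np.array(nulls)
    return PermutationResult(
        observed=observed,
        null_values=nulls.tolist(),
        p_value=_perm_p(observed, nulls),
        test="random_genes",
        seed=seed,
        extras={"observed_bac": observed_bac, "null_bacs": null_bacs},
    )
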