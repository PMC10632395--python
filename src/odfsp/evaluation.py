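"""Per-cohort scoring and meta-level evaluation of a trained ensemble."""

from __future__ import annotations

import numpy as np

from .data_model import CohortProfile, filter_for_binary_eval
from .ktsp import OdfspEnsemble, score_ensemble
from .meta import MetaEstimate, pool_random_effects
from .survstats import (
    PerfEstimate,
    auroc,
    balanced_accuracy,
    concordance_index,
    d_index,
)


def cohort_auroc(ens: OdfspEnsemble, cohort: CohortProfile) -> PerfEstimate:
    """AUROC of the ensemble risk score against the early-relapse label,
    on the binary-evaluable subset (undefined labels excluded)."""
    sub = filter_for_binary_eval(cohort)
    scores = score_ensemble(ens, sub.expression)
    return auroc(scores, sub.binary_labels(), cohort=cohort.name)


def cohort_bac(ens: OdfspEnsemble, cohort: CohortProfile) -> float:
    """Balanced accuracy of the ensemble majority vote (score > 0.5)."""
    sub = filter_for_binary_eval(cohort)
    scores = score_ensemble(ens, sub.expression)
    return balanced_accuracy((scores > 0.5).astype(int), sub.binary_labels())


def cohort_cindex(ens: OdfspEnsemble, cohort: CohortProfile) -> PerfEstimate:
    times, events = cohort.survival_arrays()
    scores = score_ensemble(ens, cohort.expression)
    return concordance_index(scores, times, events, cohort=cohort.name)


def cohort_dindex(ens: OdfspEnsemble, cohort: CohortProfile) -> PerfEstimate:
    times, events = cohort.survival_arrays()
    scores = score_ensemble(ens, cohort.expression)
    return d_index(scores, times, events, cohort=cohort.name)


def meta_auroc(ens: OdfspEnsemble, cohorts: list[CohortProfile]) -> MetaEstimate:
    return pool_random_effects([cohort_auroc(ens, c) for c in cohorts])


def meta_cindex(ens: OdfspEnsemble, cohorts: list[CohortProfile]) -> MetaEstimate:
    return pool_random_effects([cohort_cindex(ens, c) for c in cohorts])


def meta_dindex(ens: OdfspEnsemble, cohorts: list[CohortProfile]) -> MetaEstimate:
    return pool_random_effects([cohort_dindex(ens, c) for c in cohorts], scale="log")


def mean_bac(ens: OdfspEnsemble, cohorts: list[CohortProfile]) -> float:
    return float(np.mean([cohort_bac(ens, c) for c in cohorts]))
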