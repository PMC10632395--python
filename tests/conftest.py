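import numpy as np
import pytest

from odfsp.data_model import (
    ClinicalRecord,
    CohortProfile,
    ExpressionMatrix,
    Platform,
    SurvivalRecord,
    apply_dichotomization,
)
from odfsp.synthetic import CohortSpec, SimulationConfig, simulate_study


def make_cohort(values, times, events, name="c", platform=Platform.ARRAY,
                gene_ids=None, sample_ids=None):
    """Small cohort builder with labels already dichotomized at 365 d."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    expr = ExpressionMatrix(list(gene_ids), list(sample_ids), values)
    clinical = [
        ClinicalRecord(sample_id=s, survival=SurvivalRecord(float(t), bool(e)),
                       cohort=name, platform=platform)
        for s, t, e in zip(sample_ids, times, events)
    ]
    return apply_dichotomization(CohortProfile(name, expr, clinical, platform))


@pytest.fixture(scope="session")
def small_study():
    """Reduced synthetic study shared by slower integration tests."""
    cfg = SimulationConfig(
        n_genes=80,
        n_signal_pairs=3,
        effect_delta=0.8,
        cohort_specs=[
            CohortSpec("train", 40, Platform.SEQUENCING, "identity", 0.0),
            CohortSpec("valA", 50, Platform.SEQUENCING, "affine:1.5:2.0", 0.3),
            CohortSpec("valB", 50, Platform.ARRAY, "log2", -0.5),
        ],
        seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
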