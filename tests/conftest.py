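import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lmsdiag import (
    ExpressionMatrix,
    Label,
    LabeledCohort,
    PipelineConfig,
    Scale,
    SyntheticParams,
    apply_gene_selection,
    fit_gene_selection,
    generate_cohort,
    partition_by_role,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

STUDY_SEED = 0  # cohort seed used by the seeded end-to-end checks


def make_matrix(values, gene_ids=None, sample_ids=None, scale=Scale.FPKM):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(gene_ids, sample_ids, values, scale=scale)


def make_cohort(values, labels, **kw):
    matrix = make_matrix(values, **kw)
    return LabeledCohort(matrix, dict(zip(matrix.sample_ids, labels)))


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study: full gene count, published sample geometry."""
    params = SyntheticParams(seed=STUDY_SEED)
    cohort, truth = generate_cohort(params)
    parts = partition_by_role(cohort, truth)
    return {"params": params, "cohort": cohort, "truth": truth, "parts": parts}


@pytest.fixture(scope="session")
def fitted_selection(default_study):
    return fit_gene_selection(
        default_study["parts"]["train"],
        default_study["parts"]["benign_ref"],
        PipelineConfig(seed=STUDY_SEED),
    )


@pytest.fixture(scope="session")
def feature_sets(default_study, fitted_selection):
    """samples x genes feature arrays and binary targets for every study role."""
    out = {}
    for role in ("train", "validation", "test1", "test2"):
        cohort = default_study["parts"][role]
        X = apply_gene_selection(fitted_selection, cohort).values.T
        out[role] = (X, cohort.binary_targets())
    return out


@pytest.fixture()
def small_study():
    """A reduced cohort for fast unit-level pipeline tests."""
    params = SyntheticParams(
        n_genes=300, n_planted=8, n_benign_de=20, n_low_expr=60, seed=7,
        n_normal_train=40, n_lms_train=15, n_normal_val=10, n_lms_val=5,
        n_leiomyoma_ref=8, n_leiomyoma_test1=6, n_lms_test1=6,
        n_leiomyoma_test2=5, n_lms_test2=6,
    )
    cohort, truth = generate_cohort(params)
    return {"params": params, "cohort": cohort, "truth": truth,
            "parts": partition_by_role(cohort, truth)}
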