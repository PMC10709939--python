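"""Synthetic labeled cohorts with the statistical structure the pipeline assumes.

The generative model works on the log2 scale.  Each gene g receives a fixed
baseline b_g; the value of gene g in sample s of class c is

    b_g + delta_g(c) + e_{g,s} + L_s

where delta_g(c) is a mean shift applied only to benign-DE genes in leiomyoma
samples, e_{g,s} is Gaussian expression noise whose spread is inflated for
the planted marker genes in leiomyosarcoma samples (sigma_lms vs.
sigma_normal elsewhere), and L_s ~ N(0, libsize_sd) is a per-sample
multiplicative library-size factor shared by every gene of the sample.  One
housekeeping reference gene ("GAPDH") gets damped noise (sigma_normal / 10)
and no shifts, so per-sample standardization against it removes L_s.  The
emitted matrix is on FPKM scale via 2**value, hence strictly positive.

The planted marker genes model transcripts that are well expressed and tightly
regulated in normal and benign tissue but heterogeneous in malignancy.  Their
baselines are drawn in a narrow band around the centre of the top expression
stratum so their standardized level sits close to the NDEG-set average —
markers far from that average would carry a large squared offset into both
MSS terms and dilute the MSS ratio toward 1.

Default sample geometry mirrors the study design this pipeline targets:
92 + 25 training, 22 + 6 validation, 8 benign reference, 9 + 9 and 8 + 9
test samples, 17 planted genes, and a 5x noise-SD inflation (so the expected
per-gene MSS ratio of a planted marker is about 25).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ExpressionMatrix, Label, LabeledCohort, Scale

__all__ = ["SyntheticParams", "SyntheticTruth", "generate_cohort", "partition_by_role"]

ROLES = ("train", "validation", "benign_ref", "test1", "test2")

# baseline strata (log2 FPKM)
_BASELINE_LO, _BASELINE_HI = 4.0, 12.0
_LOW_EXPR_LO, _LOW_EXPR_HI = -6.0, 0.0
_REFERENCE_BASELINE = 10.0
_PLANTED_BASELINE_SD = 0.15


@dataclass
class SyntheticParams:
    """Knobs of the synthetic cohort generator (defaults = study geometry)."""

    n_genes: int = 2000
    n_normal_train: int = 92
    n_lms_train: int = 25
    n_normal_val: int = 22
    n_lms_val: int = 6
    n_leiomyoma_ref: int = 8
    n_leiomyoma_test1: int = 9
    n_lms_test1: int = 9
    n_leiomyoma_test2: int = 8
    n_lms_test2: int = 9
    n_planted: int = 17
    sigma_normal: float = 0.4
    sigma_lms: float = 2.0
    n_benign_de: int = 100
    benign_de_shift: float = 2.0
    n_low_expr: int = 400
    libsize_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_genes, self.n_normal_train, self.n_lms_train, self.n_normal_val,
            self.n_lms_val, self.n_leiomyoma_ref, self.n_leiomyoma_test1,
            self.n_lms_test1, self.n_leiomyoma_test2, self.n_lms_test2,
        ]
        if any(c < 0 for c in counts) or self.n_genes < 1:
            raise ValueError("sample/gene counts must be non-negative (n_genes >= 1)")
        if min(self.n_planted, self.n_benign_de, self.n_low_expr) < 0:
            raise ValueError("gene-subset sizes must be non-negative")
        if not self.sigma_normal > 0:
            raise ValueError("sigma_normal must be > 0")
        if not self.sigma_lms > self.sigma_normal:
            raise ValueError("sigma_lms must exceed sigma_normal")
        if self.libsize_sd < 0:
            raise ValueError("libsize_sd must be >= 0")
        if self.n_planted + self.n_benign_de + self.n_low_expr + 1 > self.n_genes:
            raise ValueError(
                "n_planted + n_benign_de + n_low_expr + 1 reference gene "
                f"({self.n_planted + self.n_benign_de + self.n_low_expr + 1}) "
                f"exceeds n_genes ({self.n_genes})"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    planted_gene_ids: list[str]
    benign_de_gene_ids: list[str]
    low_expr_gene_ids: list[str]
    reference_gene_id: str
    sample_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [
            set(self.planted_gene_ids),
            set(self.benign_de_gene_ids),
            set(self.low_expr_gene_ids),
            {self.reference_gene_id},
        ]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("gene role sets must be disjoint")


def _sample_plan(p: SyntheticParams) -> list[tuple[str, Label, int]]:
    return [
        ("train", Label.NORMAL, p.n_normal_train),
        ("train", Label.LEIOMYOSARCOMA, p.n_lms_train),
        ("validation", Label.NORMAL, p.n_normal_val),
        ("validation", Label.LEIOMYOSARCOMA, p.n_lms_val),
        ("benign_ref", Label.LEIOMYOMA, p.n_leiomyoma_ref),
        ("test1", Label.LEIOMYOMA, p.n_leiomyoma_test1),
        ("test1", Label.LEIOMYOSARCOMA, p.n_lms_test1),
        ("test2", Label.LEIOMYOMA, p.n_leiomyoma_test2),
        ("test2", Label.LEIOMYOSARCOMA, p.n_lms_test2),
    ]


def generate_cohort(params: SyntheticParams) -> tuple[LabeledCohort, SyntheticTruth]:
    """Generate one labeled cohort covering all study roles, plus ground truth.

    Deterministic given ``params.seed`` (a single generator stream drives all
    draws).  The truth object records the planted / benign-DE / low-expression
    gene sets, the reference gene, and each sample's study role.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    width = len(str(p.n_genes))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, p.n_genes + 1)]
    reference_gene = "GAPDH"
    gene_ids[0] = reference_gene

    # assign disjoint gene roles (reference gene excluded from the draw)
    candidates = rng.permutation(np.arange(1, p.n_genes))
    planted_idx = np.sort(candidates[: p.n_planted])
    benign_idx = np.sort(candidates[p.n_planted : p.n_planted + p.n_benign_de])
    low_idx = np.sort(
        candidates[p.n_planted + p.n_benign_de : p.n_planted + p.n_benign_de + p.n_low_expr]
    )

    baselines = rng.uniform(_BASELINE_LO, _BASELINE_HI, size=p.n_genes)
    baselines[low_idx] = rng.uniform(_LOW_EXPR_LO, _LOW_EXPR_HI, size=low_idx.size)
    baselines[0] = _REFERENCE_BASELINE
    # planted markers: narrow band around the centre of the retained stratum
    n_top = max(1, int(np.floor(0.30 * p.n_genes)))
    top_centre = float(np.mean(np.sort(baselines)[-n_top:]))
    baselines[planted_idx] = top_centre + rng.normal(
        0.0, _PLANTED_BASELINE_SD, size=planted_idx.size
    )

    plan = _sample_plan(p)
    sample_ids: list[str] = []
    labels: dict[str, Label] = {}
    roles: dict[str, str] = {}
    columns: list[np.ndarray] = []
    short = {Label.NORMAL: "N", Label.LEIOMYOMA: "LM", Label.LEIOMYOSARCOMA: "LMS"}
    planted_mask = np.zeros(p.n_genes, dtype=bool)
    planted_mask[planted_idx] = True
    for role, label, count in plan:
        for k in range(1, count + 1):
            sid = f"{role.upper()}_{short[label]}{k:03d}"
            sample_ids.append(sid)
            labels[sid] = label
            roles[sid] = role
            lib = rng.normal(0.0, p.libsize_sd) if p.libsize_sd > 0 else 0.0
            noise = rng.normal(0.0, p.sigma_normal, size=p.n_genes)
            if label is Label.LEIOMYOSARCOMA and p.n_planted:
                noise[planted_idx] = rng.normal(0.0, p.sigma_lms, size=planted_idx.size)
            noise[0] = rng.normal(0.0, p.sigma_normal / 10.0)
            value = baselines + noise + lib
            if label is Label.LEIOMYOMA and p.n_benign_de:
                value[benign_idx] += p.benign_de_shift
            columns.append(value)

    log2_values = np.column_stack(columns) if columns else np.empty((p.n_genes, 0))
    matrix = ExpressionMatrix(
        gene_ids, sample_ids, np.exp2(log2_values), scale=Scale.FPKM
    )
    truth = SyntheticTruth(
        planted_gene_ids=[gene_ids[i] for i in planted_idx],
        benign_de_gene_ids=[gene_ids[i] for i in benign_idx],
        low_expr_gene_ids=[gene_ids[i] for i in low_idx],
        reference_gene_id=reference_gene,
        sample_roles=roles,
    )
    return LabeledCohort(matrix, labels), truth


def partition_by_role(
    cohort: LabeledCohort, truth: SyntheticTruth
) -> dict[str, LabeledCohort]:
    """Split a generated cohort into its study-role sub-cohorts."""
    out: dict[str, LabeledCohort] = {}
    for role in ROLES:
        members = [s for s in cohort.matrix.sample_ids if truth.sample_roles.get(s) == role]
        if members:
            out[role] = cohort.subset_samples(members)
    return out
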