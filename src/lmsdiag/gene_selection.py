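"""Variance-based marker-gene selection.

This is the analytical core of the package.  Starting from GAPDH-standardized
log2 expression, it

1. keeps the top fraction of genes by mean raw FPKM in the training samples
   (expression filter),
2. discards genes that differ between benign leiomyoma and normal tissue in
   either mean (Welch t-test) or variance (F test) — the survivors are the
   "not differentially expressed genes" (NDEG),
3. centers every sample to zero mean over the NDEG set ("zero-sum"
   transformation),
4. scores each gene by the ratio of its mean sum of squares (MSS) in
   leiomyosarcoma samples to that in normal samples — for zero-sum data the
   MSS is an empirical variance proxy, so a large ratio flags genes whose
   expression is heterogeneous in malignancy but conserved in normal tissue,
5. picks the genes above the largest gap in the sorted MSS-ratio curve.

The fitted state is captured in :class:`GeneSelectionModel`, which can be
re-applied to new cohorts and round-tripped through a plain-text bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, Label, LabeledCohort, PipelineConfig, Scale
from .preprocessing import intersect_genes, log_transform, reference_standardize

__all__ = [
    "MssRecord",
    "GeneSelectionModel",
    "filter_by_mean_expression",
    "variance_test_p",
    "mean_test_p",
    "select_ndeg",
    "zero_sum_transform",
    "mss",
    "mss_ratio_table",
    "gap_select",
    "fit_gene_selection",
    "apply_gene_selection",
]

logger = logging.getLogger(__name__)

_MSS_FLOOR = 1e-12


@dataclass(frozen=True)
class MssRecord:
    """Per-gene mean-sum-of-squares statistics for the two training groups."""

    gene_id: str
    mss_normal: float
    mss_lms: float
    mss_ratio: float


def filter_by_mean_expression(matrix: ExpressionMatrix, fraction: float) -> list[str]:
    """The ``floor(fraction * n_genes)`` genes with highest mean FPKM.

    Means are taken across the matrix's samples (the training set in the
    pipeline).  Ties are broken lexicographically by gene ID.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if matrix.scale is not Scale.FPKM:
        raise ValueError("expression filter operates on raw FPKM values")
    k = int(np.floor(fraction * matrix.n_genes))
    if k == 0:
        raise ValueError(
            f"fraction {fraction} of {matrix.n_genes} genes retains nothing"
        )
    means = matrix.values.mean(axis=1)
    order = sorted(range(matrix.n_genes), key=lambda i: (-means[i], matrix.gene_ids[i]))
    return [matrix.gene_ids[i] for i in order[:k]]


def variance_test_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided variance-ratio F-test p-value (R's ``var.test`` convention).

    ``F = var(x)/var(y)`` with ``(len(x)-1, len(y)-1)`` degrees of freedom and
    ``p = min(1, 2 * min(P[F' <= F], P[F' >= F]))``.  If exactly one group has
    zero variance the difference is treated as maximally significant (p = 0);
    if both are constant, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("variance test needs at least 2 observations per group")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        return 1.0
    if vx == 0 or vy == 0:
        return 0.0
    f = vx / vy
    dist = stats.f(x.size - 1, y.size - 1)
    return float(min(1.0, 2 * min(dist.cdf(f), dist.sf(f))))


def mean_test_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Welch t-test p-value (unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("mean test needs at least 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def select_ndeg(
    normal: ExpressionMatrix,
    benign_ref: ExpressionMatrix,
    genes: list[str],
    alpha: float = 0.05,
) -> list[str]:
    """Genes with no significant mean or variance difference between groups.

    A gene is excluded when either the F variance test or the Welch t-test
    between the normal samples and the benign (leiomyoma) reference samples
    has p < ``alpha``; retained genes have both p >= ``alpha``.  Input order
    is preserved.  ``alpha = 0`` retains everything.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    kept: list[str] = []
    n_var_reject = 0
    n_mean_reject = 0
    for g in genes:
        x = normal.row(g)
        y = benign_ref.row(g)
        p_var = variance_test_p(x, y)
        p_mean = mean_test_p(x, y)
        if p_var < alpha:
            n_var_reject += 1
        if p_mean < alpha:
            n_mean_reject += 1
        if p_var >= alpha and p_mean >= alpha:
            kept.append(g)
    if not kept:
        raise ValueError(
            "no gene passed the NDEG filter "
            f"(variance-test rejections: {n_var_reject}, "
            f"mean-test rejections: {n_mean_reject}, of {len(genes)} genes)"
        )
    logger.info(
        "NDEG filter kept %d of %d genes (variance rejections %d, mean rejections %d)",
        len(kept), len(genes), n_var_reject, n_mean_reject,
    )
    return kept


def zero_sum_transform(matrix: ExpressionMatrix, ndeg_genes: list[str]) -> ExpressionMatrix:
    """Restrict to the NDEG set and center every sample to zero mean over it."""
    if not ndeg_genes:
        raise ValueError("ndeg_genes must be nonempty")
    sub = matrix.subset_genes(list(ndeg_genes))
    centered = sub.values - sub.values.mean(axis=0, keepdims=True)
    return ExpressionMatrix(
        list(sub.gene_ids), list(sub.sample_ids), centered, scale=Scale.ZEROSUM
    )


def mss(values: np.ndarray) -> float:
    """Mean sum of squares of a zero-sum expression vector: mean(x_i^2)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mss of an empty vector is undefined")
    return float(np.mean(np.square(values)))


def mss_ratio_table(
    zerosum: ExpressionMatrix,
    labels: dict[str, Label],
    positive: Label = Label.LEIOMYOSARCOMA,
    negative: Label = Label.NORMAL,
) -> list[MssRecord]:
    """Per-gene MSS in each group and their ratio (positive / negative).

    Genes whose negative-group MSS is below 1e-12 are dropped with a warning
    rather than producing unbounded ratios.
    """
    pos_cols = [j for j, s in enumerate(zerosum.sample_ids) if labels[s] is positive]
    neg_cols = [j for j, s in enumerate(zerosum.sample_ids) if labels[s] is negative]
    if not pos_cols:
        raise ValueError(f"no {positive.value} samples present")
    if not neg_cols:
        raise ValueError(f"no {negative.value} samples present")
    records: list[MssRecord] = []
    n_dropped = 0
    for i, gene in enumerate(zerosum.gene_ids):
        m_pos = mss(zerosum.values[i, pos_cols])
        m_neg = mss(zerosum.values[i, neg_cols])
        if m_neg < _MSS_FLOOR:
            n_dropped += 1
            logger.warning(
                "gene %s dropped from MSS table: negative-group MSS %.3g < %.0e",
                gene, m_neg, _MSS_FLOOR,
            )
            continue
        records.append(MssRecord(gene, m_neg, m_pos, m_pos / m_neg))
    if n_dropped:
        logger.info("dropped %d genes with near-zero normal-group MSS", n_dropped)
    return records


def _sorted_records(records: list[MssRecord]) -> list[MssRecord]:
    return sorted(records, key=lambda r: (-r.mss_ratio, r.gene_id))


def gap_select(
    records: list[MssRecord], inspect_n: int = 20, fallback_k: int = 17
) -> list[str]:
    """Genes above the largest drop in the sorted MSS-ratio curve.

    Records are ranked by descending ratio (ties broken lexicographically).
    Within the top ``min(inspect_n, len)`` the largest *relative* drop between
    consecutive ratios (the gap on the log scale) is located; every gene
    strictly above that gap is selected.  The relative gap is used because
    MSS ratios live on a multiplicative scale: the sampling spread among the
    top-ranked genes grows with their magnitude, so an absolute-difference
    gap is frequently dominated by noise between the first few ranks, while
    the marker/background boundary (e.g. 13 -> 2.5, a 5-fold drop) remains
    the largest fold change.  If the maximal gap is tied, or all inspected
    ratios are equal, the top ``fallback_k`` genes are returned instead.
    """
    if not records:
        raise ValueError("no MSS records to select from")
    if inspect_n < 2:
        raise ValueError("inspect_n must be >= 2")
    ranked = _sorted_records(records)
    window = ranked[: min(inspect_n, len(ranked))]
    if len(window) < 2:
        return [ranked[0].gene_id]
    ratios = np.array([r.mss_ratio for r in window])
    with np.errstate(divide="ignore", invalid="ignore"):
        drops = np.where(ratios[1:] > 0, ratios[:-1] / ratios[1:],
                         np.where(ratios[:-1] > 0, np.inf, 1.0))
    max_gap = drops.max()
    if max_gap <= 1 or np.sum(drops == max_gap) > 1:
        k = min(fallback_k, len(ranked))
        return [r.gene_id for r in ranked[:k]]
    cut = int(np.argmax(drops))  # first (and only) maximal gap
    return [r.gene_id for r in window[: cut + 1]]


@dataclass
class GeneSelectionModel:
    """Fitted gene-selection state, sufficient to transform any new cohort."""

    pseudo_count: float
    reference_gene: str
    shared_genes: list[str]
    retained_genes: list[str]
    ndeg_genes: list[str]
    mss_table: list[MssRecord]
    selected_genes: list[str]
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        retained = set(self.retained_genes)
        ndeg = set(self.ndeg_genes)
        if not ndeg <= retained:
            raise ValueError("ndeg_genes must be a subset of retained_genes")
        if not set(self.selected_genes) <= ndeg:
            raise ValueError("selected_genes must be a subset of ndeg_genes")

    def stage_counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared_genes),
            "retained": len(self.retained_genes),
            "ndeg": len(self.ndeg_genes),
            "selected": len(self.selected_genes),
        }

    # ---- plain-text bundle -------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.config.to_file(d / "config.yaml")
        (d / "meta.txt").write_text(
            f"pseudo_count\t{self.pseudo_count!r}\nreference_gene\t{self.reference_gene}\n"
        )
        for name, genes in (
            ("shared_genes.txt", self.shared_genes),
            ("retained_genes.txt", self.retained_genes),
            ("ndeg_genes.txt", self.ndeg_genes),
            ("selected_genes.txt", self.selected_genes),
        ):
            (d / name).write_text("".join(g + "\n" for g in genes))
        pd.DataFrame(
            [(r.gene_id, r.mss_normal, r.mss_lms, r.mss_ratio) for r in self.mss_table],
            columns=["gene_id", "mss_normal", "mss_lms", "mss_ratio"],
        ).to_csv(d / "mss_table.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "GeneSelectionModel":
        d = Path(directory)
        meta = dict(
            line.split("\t") for line in (d / "meta.txt").read_text().splitlines()
        )
        genes = {
            name: (d / name).read_text().splitlines()
            for name in (
                "shared_genes.txt", "retained_genes.txt",
                "ndeg_genes.txt", "selected_genes.txt",
            )
        }
        table = pd.read_csv(d / "mss_table.tsv", sep="\t")
        records = [
            MssRecord(str(r.gene_id), float(r.mss_normal), float(r.mss_lms), float(r.mss_ratio))
            for r in table.itertuples(index=False)
        ]
        return cls(
            pseudo_count=float(meta["pseudo_count"]),
            reference_gene=meta["reference_gene"],
            shared_genes=genes["shared_genes.txt"],
            retained_genes=genes["retained_genes.txt"],
            ndeg_genes=genes["ndeg_genes.txt"],
            mss_table=records,
            selected_genes=genes["selected_genes.txt"],
            config=PipelineConfig.from_file(d / "config.yaml"),
        )


def fit_gene_selection(
    train: LabeledCohort,
    benign_ref: LabeledCohort,
    config: PipelineConfig | None = None,
) -> GeneSelectionModel:
    """Run the full selection cascade on a training cohort.

    ``train`` must contain normal and leiomyosarcoma samples (FPKM scale);
    ``benign_ref`` supplies the leiomyoma samples used only for the NDEG
    filter.  Every intermediate gene list is recorded in the returned model.
    """
    config = config or PipelineConfig()
    if not train.samples_with_label(Label.NORMAL):
        raise ValueError("training cohort has no normal samples")
    if not train.samples_with_label(Label.LEIOMYOSARCOMA):
        raise ValueError("training cohort has no leiomyosarcoma samples")
    non_benign = [
        s for s in benign_ref.matrix.sample_ids
        if benign_ref.labels[s] is not Label.LEIOMYOMA
    ]
    if non_benign:
        raise ValueError(f"benign reference cohort has non-leiomyoma samples: {non_benign[:5]}")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    train_fpkm, benign_fpkm = stage(
        "intersect_genes", intersect_genes, train.matrix, benign_ref.matrix
    )
    shared = list(train_fpkm.gene_ids)

    train_std = stage(
        "reference_standardize", reference_standardize,
        stage("log_transform", log_transform, train_fpkm, config.pseudo_count),
        config.reference_gene,
    )
    benign_std = stage(
        "reference_standardize", reference_standardize,
        stage("log_transform", log_transform, benign_fpkm, config.pseudo_count),
        config.reference_gene,
    )

    retained = stage(
        "filter_by_mean_expression", filter_by_mean_expression,
        train_fpkm, config.mean_filter_fraction,
    )

    normal_ids = train.samples_with_label(Label.NORMAL)
    ndeg = stage(
        "select_ndeg", select_ndeg,
        train_std.subset_samples(normal_ids), benign_std, retained, config.ndeg_alpha,
    )

    zerosum = stage("zero_sum_transform", zero_sum_transform, train_std, ndeg)
    table = stage("mss_ratio_table", mss_ratio_table, zerosum, train.labels)
    selected = stage(
        "gap_select", gap_select, table, config.gap_inspect_n, config.fallback_k
    )
    logger.info(
        "gene selection: %d shared -> %d retained -> %d NDEG -> %d selected",
        len(shared), len(retained), len(ndeg), len(selected),
    )
    return GeneSelectionModel(
        pseudo_count=config.pseudo_count,
        reference_gene=config.reference_gene,
        shared_genes=shared,
        retained_genes=retained,
        ndeg_genes=ndeg,
        mss_table=table,
        selected_genes=selected,
        config=config,
    )


def apply_gene_selection(model: GeneSelectionModel, cohort: LabeledCohort) -> ExpressionMatrix:
    """Transform a new cohort with a fitted model's recipe.

    log2 -> reference standardization -> zero-sum over the model's NDEG list
    (per-sample means computed on this cohort) -> restriction to the selected
    genes, in model order.  Applying to the training cohort reproduces the
    feature matrix used during fitting.
    """
    present = set(cohort.matrix.gene_ids)
    missing = [g for g in model.ndeg_genes if g not in present]
    if model.reference_gene not in present:
        missing = [model.reference_gene] + missing
    if missing:
        raise KeyError(f"cohort is missing required genes: {missing[:10]}")
    std = reference_standardize(
        log_transform(cohort.matrix, model.pseudo_count), model.reference_gene
    )
    zerosum = zero_sum_transform(std, model.ndeg_genes)
    return zerosum.subset_genes(list(model.selected_genes))
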