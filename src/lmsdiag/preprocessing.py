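"""Shared-gene intersection, log transform, housekeeping-gene standardization,
and the stratified train/validation split.

The standardization step subtracts, per sample, the log2 expression of a
reference housekeeping gene (GAPDH by default) from every gene.  Because a
per-sample multiplicative library-size factor adds the same constant to every
gene on the log scale, this removes it exactly in the zero-pseudo-count
limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ExpressionMatrix, Label, LabeledCohort, Scale

__all__ = [
    "SplitResult",
    "intersect_genes",
    "log_transform",
    "reference_standardize",
    "stratified_split",
]


@dataclass
class SplitResult:
    train: LabeledCohort
    validation: LabeledCohort


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, lexicographically ordered.

    Sample sets are unchanged.  An empty intersection is an error.
    """
    if a.scale is not b.scale:
        raise ValueError(f"matrices on different scales: {a.scale} vs {b.scale}")
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise ValueError("gene intersection is empty")
    return a.subset_genes(shared), b.subset_genes(shared)


def log_transform(matrix: ExpressionMatrix, pseudo_count: float = 0.001) -> ExpressionMatrix:
    """log2(v + pseudo_count) on every entry of an FPKM matrix."""
    if matrix.scale is not Scale.FPKM:
        raise ValueError(f"log_transform expects an FPKM matrix, got scale={matrix.scale}")
    if not pseudo_count > 0:
        raise ValueError("pseudo_count must be > 0")
    return ExpressionMatrix(
        list(matrix.gene_ids),
        list(matrix.sample_ids),
        np.log2(matrix.values + pseudo_count),
        scale=Scale.LOG2,
    )


def reference_standardize(matrix: ExpressionMatrix, reference_gene: str = "GAPDH") -> ExpressionMatrix:
    """Subtract each sample's reference-gene log2 value from all its genes.

    The reference gene's own row becomes identically zero.
    """
    if matrix.scale is not Scale.LOG2:
        raise ValueError(
            f"reference_standardize expects a log2 matrix, got scale={matrix.scale}"
        )
    if reference_gene not in set(matrix.gene_ids):
        raise KeyError(f"reference gene {reference_gene!r} not in matrix")
    ref = matrix.row(reference_gene)
    return ExpressionMatrix(
        list(matrix.gene_ids),
        list(matrix.sample_ids),
        matrix.values - ref[np.newaxis, :],
        scale=Scale.STANDARDIZED,
    )


def stratified_split(
    cohort: LabeledCohort, split_ratio: float = 0.8, seed: int = 0
) -> SplitResult:
    """Random per-class split into training and validation cohorts.

    Per class, the validation set receives ``floor(n_class * (1 - split_ratio))``
    samples (so 114 normal + 31 leiomyosarcoma at a 4:1 ratio give 92/25
    training and 22/6 validation); the remainder goes to training.  Assignment
    is uniformly random and deterministic given ``seed``.
    """
    if not 0 < split_ratio < 1:
        raise ValueError("split_ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    val_ids: list[str] = []
    for label in Label:
        members = cohort.samples_with_label(label)
        if not members:
            continue
        # epsilon guards the floor against binary round-off (10 * 0.2 -> 1.999…)
        n_val = int(np.floor(len(members) * (1 - split_ratio) + 1e-9))
        if len(members) - n_val < 1:
            raise ValueError(
                f"class {label.value!r} would have no training samples "
                f"({len(members)} total, {n_val} to validation)"
            )
        perm = rng.permutation(len(members))
        chosen = {members[i] for i in perm[:n_val]}
        val_ids.extend(s for s in members if s in chosen)
        train_ids.extend(s for s in members if s not in chosen)
    # keep original matrix sample order within each side
    order = {s: j for j, s in enumerate(cohort.matrix.sample_ids)}
    train_ids.sort(key=order.__getitem__)
    val_ids.sort(key=order.__getitem__)
    return SplitResult(
        train=cohort.subset_samples(train_ids),
        validation=cohort.subset_samples(val_ids),
    )
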