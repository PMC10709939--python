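"""Core data types and plain-text IO for the diagnostic pipeline.

Expression data live in a genes x samples matrix of FPKM values (or a
transformed derivative of them); sample labels are one of three tissue
classes.  Files are plain TSV: the expression matrix carries gene IDs in the
first column and sample IDs in the header, the label file is two columns
(sample_id, label).  Missing values are not permitted anywhere — the pipeline
has no imputation step.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Scale",
    "Label",
    "ExpressionMatrix",
    "LabeledCohort",
    "PipelineConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
]


class Scale(str, enum.Enum):
    """Which transformation stage a matrix's values are on."""

    FPKM = "fpkm"
    LOG2 = "log2"
    STANDARDIZED = "standardized"
    ZEROSUM = "zerosum"


class Label(str, enum.Enum):
    """Tissue class of a sample.

    The binary mapping is fixed throughout the package: leiomyosarcoma is the
    positive class; normal tissue and leiomyoma are both negative.
    """

    NORMAL = "normal"
    LEIOMYOMA = "leiomyoma"
    LEIOMYOSARCOMA = "leiomyosarcoma"

    @property
    def is_positive(self) -> bool:
        return self is Label.LEIOMYOSARCOMA


def _first_duplicate(ids: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of expression values.

    Parameters
    ----------
    gene_ids
        Row identifiers, unique, order preserved.
    sample_ids
        Column identifiers, unique, order preserved.
    values
        2-D float array of shape ``(len(gene_ids), len(sample_ids))``; all
        entries finite, and non-negative when ``scale`` is FPKM.
    scale
        The transformation stage the values are on.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: Scale = Scale.FPKM

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.scale = Scale(self.scale)
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene ID: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample ID: {dup!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.scale is Scale.FPKM and self.values.size and self.values.min() < 0:
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative FPKM value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_lookup[gene_id]
        except AttributeError:
            self._gene_lookup = {g: i for i, g in enumerate(self.gene_ids)}
            return self._gene_lookup[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def subset_genes(self, genes: list[str], scale: Scale | None = None) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order; all must be present."""
        missing = [g for g in genes if g not in set(self.gene_ids)]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(
            list(genes), list(self.sample_ids), self.values[idx, :],
            scale=self.scale if scale is None else scale,
        )

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [lookup[s] for s in samples]
        return ExpressionMatrix(
            list(self.gene_ids), list(samples), self.values[:, idx], scale=self.scale
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )


@dataclass
class LabeledCohort:
    """An expression matrix together with one tissue label per sample."""

    matrix: ExpressionMatrix
    labels: dict[str, Label]

    def __post_init__(self) -> None:
        self.labels = {str(k): Label(v) for k, v in self.labels.items()}
        unlabeled = [s for s in self.matrix.sample_ids if s not in self.labels]
        if unlabeled:
            raise ValueError(f"samples without a label: {unlabeled[:5]}")

    def samples_with_label(self, *labels: Label) -> list[str]:
        wanted = set(labels)
        return [s for s in self.matrix.sample_ids if self.labels[s] in wanted]

    def binary_targets(self) -> np.ndarray:
        """0/1 vector in matrix sample order; 1 = leiomyosarcoma."""
        return np.array(
            [int(self.labels[s].is_positive) for s in self.matrix.sample_ids]
        )

    def subset_samples(self, samples: list[str]) -> "LabeledCohort":
        return LabeledCohort(
            self.matrix.subset_samples(samples), {s: self.labels[s] for s in samples}
        )

    def class_counts(self) -> dict[Label, int]:
        counts = {lab: 0 for lab in Label}
        for s in self.matrix.sample_ids:
            counts[self.labels[s]] += 1
        return counts


@dataclass
class PipelineConfig:
    """Tunable knobs of the full pipeline with their defaults.

    ``tuning_trials`` defaults to a desk-scale 25; the study-scale value is
    500 and can be set explicitly.
    """

    pseudo_count: float = 0.001
    reference_gene: str = "GAPDH"
    mean_filter_fraction: float = 0.30
    ndeg_alpha: float = 0.05
    gap_inspect_n: int = 20
    fallback_k: int = 17
    split_ratio: float = 0.8
    seed: int = 0
    classifier_family: str = "dnn"
    tuning_trials: int = 25
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.pseudo_count > 0:
            raise ValueError("pseudo_count must be > 0")
        if not 0 < self.mean_filter_fraction <= 1:
            raise ValueError("mean_filter_fraction must be in (0, 1]")
        if not 0 < self.ndeg_alpha < 1:
            raise ValueError("ndeg_alpha must be in (0, 1)")
        if self.gap_inspect_n < 2:
            raise ValueError("gap_inspect_n must be >= 2")
        if self.fallback_k < 1:
            raise ValueError("fallback_k must be >= 1")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.classifier_family not in {"dnn", "svm", "rf", "gb"}:
            raise ValueError(f"unknown classifier family {self.classifier_family!r}")
        if self.tuning_trials < 1:
            raise ValueError("tuning_trials must be >= 1")
        if not 0 <= self.decision_threshold <= 1:
            raise ValueError("decision_threshold must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} is not a flat key-value mapping")
        return cls.from_dict(d)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV as an FPKM-scale ExpressionMatrix.

    First column holds gene IDs, header row sample IDs (the first header cell
    is ignored).  Gene and sample order is preserved exactly.  Duplicate IDs,
    non-numeric cells and negative values are rejected with the offending
    coordinate.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    gene_ids = [str(g) for g in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    for name, ids in (("gene", gene_ids), ("sample", sample_ids)):
        dup = _first_duplicate(ids)
        if dup is not None:
            raise ValueError(f"{path}: duplicate {name} ID: {dup!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & ~raw.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-numeric cell {raw.iat[i, j]!r} at gene "
            f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if values.size and values.min() < 0:
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(gene_ids, sample_ids, values, scale=Scale.FPKM)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV, re-readable by :func:`read_expression_matrix`.

    Values are serialized with ``repr`` precision so a round trip is exact to
    well below 1e-12.
    """
    df = matrix.to_frame()
    df.to_csv(Path(path), sep="\t", float_format=None)


def read_labels(path: str | Path) -> dict[str, Label]:
    """Read a two-column (sample_id, label) TSV into a label map.

    A first line ``sample_id<TAB>label`` is treated as a header.  Unknown
    label strings and duplicated sample IDs are rejected.
    """
    path = Path(path)
    labels: dict[str, Label] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sample_id, label_str = parts
            if lineno == 1 and (sample_id, label_str) == ("sample_id", "label"):
                continue
            if sample_id in labels:
                raise ValueError(f"{path}:{lineno}: duplicated sample ID {sample_id!r}")
            try:
                labels[sample_id] = Label(label_str)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unknown label {label_str!r} "
                    f"(expected one of {[l.value for l in Label]})"
                ) from None
    return labels


def write_labels(labels: Mapping[str, Label], path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write("sample_id\tlabel\n")
        for sample_id, label in labels.items():
            fh.write(f"{sample_id}\t{Label(label).value}\n")
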