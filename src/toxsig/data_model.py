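"""Core domain types: expression datasets, sample annotations, binary labels.

Expression data are gene-by-sample matrices of log-scale intensities with
missing values allowed. Samples carry toxicological annotations from which a
binary apical-outcome label ("dysregulated" vs "non_dysregulated") is derived,
either from lactate-dehydrogenase (LDH) activity for in vitro experiments or
from an ordinal histopathology grade for in vivo experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DYSREGULATED = "dysregulated"
NON_DYSREGULATED = "non_dysregulated"

#: The five-level ordinal histopathology scale, mildest first.
HISTOPATHOLOGY_GRADES = ("present", "minimal", "slight", "moderate", "severe")

ANNOTATION_COLUMNS = (
    "chemical",
    "dose",
    "duration",
    "organ",
    "species",
    "ldh_percent",
    "histopathology_grade",
)


class LabelingError(ValueError):
    """A sample could not be assigned a binary outcome label."""


@dataclass
class ExpressionDataset:
    """A gene x sample expression matrix with per-sample annotations.

    Parameters
    ----------
    dataset_id
        Short identifier for the dataset.
    values
        DataFrame indexed by gene symbol with one column per sample id.
        Entries are log-scale intensities; NaN marks a missing measurement.
    annotations
        DataFrame indexed by sample id with the columns of
        :data:`ANNOTATION_COLUMNS` (missing columns are added as NA).
    """

    dataset_id: str
    values: pd.DataFrame
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.values.columns)
        ann = self.annotations.copy()
        for col in ANNOTATION_COLUMNS:
            if col not in ann.columns:
                ann[col] = pd.NA
        missing = set(self.values.columns) - set(ann.index)
        if missing:
            raise ValueError(f"samples without annotation rows: {sorted(missing)!r}")
        self.annotations = ann.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> float:
        """Fraction of matrix entries that are missing, in [0, 1]."""
        if self.values.size == 0:
            return 0.0
        return float(self.values.isna().to_numpy().mean())

    def subset_genes(self, genes) -> "ExpressionDataset":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionDataset(self.dataset_id, self.values.loc[genes], self.annotations)


def binarize_ldh(ldh_percent: float, low: float = 95.0, high: float = 105.0) -> str:
    """Binarize LDH activity (%): strictly outside [low, high] is dysregulated.

    Values exactly at the cut-offs are non_dysregulated (the decision rule is
    strictly "above"/"below" the cut-offs).
    """
    if ldh_percent is None or (isinstance(ldh_percent, float) and np.isnan(ldh_percent)):
        raise LabelingError("LDH activity is missing")
    if ldh_percent < 0:
        raise LabelingError(f"LDH activity must be nonnegative, got {ldh_percent}")
    if ldh_percent > high or ldh_percent < low:
        return DYSREGULATED
    return NON_DYSREGULATED


def binarize_histopathology(grade: str) -> str:
    """Binarize the five-level histopathology grade.

    ``present``, ``minimal`` and ``slight`` map to non_dysregulated;
    ``moderate`` and ``severe`` map to dysregulated.
    """
    if grade not in HISTOPATHOLOGY_GRADES:
        raise LabelingError(
            f"unknown histopathology grade {grade!r}; expected one of {HISTOPATHOLOGY_GRADES}"
        )
    return DYSREGULATED if grade in ("moderate", "severe") else NON_DYSREGULATED


def label_samples(dataset: ExpressionDataset) -> pd.Series:
    """Derive the binary label for every annotated sample of a dataset.

    A sample is labeled from its LDH activity when present, otherwise from its
    histopathology grade. Samples carrying neither annotation raise
    :class:`LabelingError` (labeling must be total on annotated samples).

    Returns
    -------
    pandas.Series
        Sample id -> label, in dataset sample order.
    """
    ann = dataset.annotations
    labels = {}
    for sid in dataset.samples:
        ldh = ann.at[sid, "ldh_percent"]
        grade = ann.at[sid, "histopathology_grade"]
        has_ldh = pd.notna(ldh)
        has_grade = pd.notna(grade)
        if has_ldh and has_grade:
            raise LabelingError(
                f"sample {sid!r} carries both LDH and histopathology annotations; "
                "a dataset is labeled from exactly one endpoint"
            )
        if has_ldh:
            labels[sid] = binarize_ldh(float(ldh))
        elif has_grade:
            labels[sid] = binarize_histopathology(str(grade))
        else:
            raise LabelingError(f"sample {sid!r} has no labeling annotation")
    return pd.Series(labels, name="label").loc[dataset.samples]


def merge_duplicate_genes(dataset: ExpressionDataset) -> ExpressionDataset:
    """Collapse rows sharing a gene symbol to their per-sample mean.

    Missing entries are ignored per sample: the mean of (1, NaN) and (3, 7)
    is (2, 7). Output gene symbols are unique; first-occurrence order is kept.
    """
    if dataset.values.index.is_unique:
        return dataset
    order = list(dict.fromkeys(dataset.values.index))
    merged = dataset.values.groupby(level=0, sort=False).mean()
    return ExpressionDataset(dataset.dataset_id, merged.loc[order], dataset.annotations)


def harmonize_orthologs(datasets: list[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict datasets to their shared gene universe via symbol case-folding.

    Orthologs across species are matched conservatively on gene symbol alone,
    case-insensitively (rat ``Ddr1`` matches human ``DDR1``); genes without a
    match in every dataset are dropped. All outputs use one canonical
    uppercase spelling and an identical gene order.
    """
    if len(datasets) < 2:
        raise ValueError("harmonization needs at least two datasets")
    uppercased = []
    for ds in datasets:
        up = ds.values.copy()
        up.index = [str(g).upper() for g in up.index]
        if not up.index.is_unique:
            up = up.groupby(level=0, sort=False).mean()
        uppercased.append(up)
    shared: set[str] = set(uppercased[0].index)
    for up in uppercased[1:]:
        shared &= set(up.index)
    if not shared:
        raise ValueError("no genes shared across all datasets after case-folded matching")
    order = sorted(shared)
    return [
        ExpressionDataset(ds.dataset_id, up.loc[order], ds.annotations)
        for ds, up in zip(datasets, uppercased)
    ]


# ---------------------------------------------------------------------------
# Tab-separated I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path, dataset_id: str | None = None,
                        annotations: pd.DataFrame | None = None) -> ExpressionDataset:
    """Read an expression TSV (first column gene symbol, header = sample ids,
    empty cell = missing)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    if not values.index.is_unique:
        warnings.warn(f"{path}: duplicate gene symbols; merge with merge_duplicate_genes")
    return ExpressionDataset(dataset_id or str(path), values, annotations)


def write_expression_tsv(dataset: ExpressionDataset, path) -> None:
    dataset.values.to_csv(path, sep="\t", index_label="gene")


def read_annotations_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="sample_id")
    return ann


def write_annotations_tsv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index_label="sample_id")


def read_labels_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["label"].values, index=df["sample_id"].values, name="label")


def write_labels_tsv(labels: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": labels.index, "label": labels.values}).to_csv(
        path, sep="\t", index=False
    )
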