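"""Annotation metrics and dataset descriptors.

Classification quality is summarized by macro-F1 (unweighted mean of
per-class F1, insensitive to class size), Cohen's kappa (accuracy corrected
for chance agreement via the label marginals), macro-averaged per-class
Jaccard, and plain accuracy.  Datasets are described by their sparsity (the
fraction of zero entries in the count matrix) and imbalance degree

    I = 1 + (1/log K) * sum_k (N_k/N) log(N_k/N),

one minus the normalized entropy of the cell-type size distribution: 0 when
all types have equal counts, 1 when a single type holds every cell.

Per-class scores follow the 0/0 -> 0 convention, and macro averages run
over the classes observed in the true labels; classes appearing only in the
predictions contribute false positives but no macro terms of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn import metrics as _skm

from .data_io import PeakMatrix

__all__ = [
    "MetricsReport",
    "DatasetDescriptor",
    "macro_f1",
    "cohens_kappa",
    "jaccard_score",
    "accuracy",
    "imbalance_degree",
    "sparsity",
    "novel_detection_scores",
    "compute_report",
]


@dataclass
class MetricsReport:
    macro_f1: float
    kappa: float
    jaccard: float
    accuracy: float
    per_class_f1: dict[str, float]
    n_cells: int
    n_types: int

    def to_dict(self) -> dict:
        return {
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
            "jaccard": self.jaccard,
            "accuracy": self.accuracy,
            "per_class_f1": self.per_class_f1,
            "n_cells": self.n_cells,
            "n_types": self.n_types,
        }


@dataclass
class DatasetDescriptor:
    sparsity: float
    imbalance_degree: float
    major_type_proportion: float


def _check(true_labels: Sequence, pred_labels: Sequence) -> tuple[list, list, list]:
    t, p = list(true_labels), list(pred_labels)
    if not t:
        raise ValueError("empty label vectors")
    if len(t) != len(p):
        raise ValueError("true and predicted labels differ in length")
    return t, p, sorted(set(t))


def macro_f1(true_labels: Sequence, pred_labels: Sequence) -> float:
    t, p, classes = _check(true_labels, pred_labels)
    return float(
        _skm.f1_score(t, p, labels=classes, average="macro", zero_division=0)
    )


def per_class_f1(true_labels: Sequence, pred_labels: Sequence) -> dict[str, float]:
    t, p, classes = _check(true_labels, pred_labels)
    scores = _skm.f1_score(t, p, labels=classes, average=None, zero_division=0)
    return {str(c): float(s) for c, s in zip(classes, scores)}


def cohens_kappa(true_labels: Sequence, pred_labels: Sequence) -> float:
    t, p, _ = _check(true_labels, pred_labels)
    if set(t) == set(p) and len(set(t)) == 1:
        # both sides constant and equal: chance agreement is total; by
        # convention perfect agreement scores 1
        return 1.0
    return float(_skm.cohen_kappa_score(t, p))


def jaccard_score(
    true_labels: Sequence, pred_labels: Sequence, literal_sets: bool = False
) -> float:
    """Macro-averaged per-class Jaccard (default) or the literal set form.

    The literal form |A∩B|/|A∪B| over the sets of label names is degenerate
    for multi-class vectors (the sets usually coincide); it is kept behind a
    flag for comparison.
    """
    t, p, classes = _check(true_labels, pred_labels)
    if literal_sets:
        A, B = set(p), set(t)
        return len(A & B) / len(A | B)
    return float(
        _skm.jaccard_score(t, p, labels=classes, average="macro", zero_division=0)
    )


def accuracy(true_labels: Sequence, pred_labels: Sequence) -> float:
    t, p, _ = _check(true_labels, pred_labels)
    return float(_skm.accuracy_score(t, p))


def imbalance_degree(type_counts: Mapping[str, int] | Sequence[int]) -> float:
    counts = np.asarray(
        list(type_counts.values())
        if isinstance(type_counts, Mapping)
        else type_counts,
        dtype=np.float64,
    )
    if counts.size == 0:
        raise ValueError("no cell types")
    if np.any(counts <= 0):
        raise ValueError("all type counts must be positive")
    K = counts.size
    if K == 1:
        return 1.0
    f = counts / counts.sum()
    return float(1.0 + (f @ np.log(f)) / np.log(K))


def sparsity(m: PeakMatrix | sp.spmatrix | np.ndarray) -> float:
    if isinstance(m, PeakMatrix):
        m = m.counts
    if sp.issparse(m):
        total = m.shape[0] * m.shape[1]
        nonzero = m.count_nonzero()
    else:
        arr = np.asarray(m)
        total = arr.size
        nonzero = np.count_nonzero(arr)
    return float((total - nonzero) / total)


def novel_detection_scores(
    true_is_novel: Sequence[bool], pred_is_novel: Sequence[bool]
) -> tuple[float, float]:
    """Binary (accuracy, F1) with the novel class as positive."""
    t = np.asarray(true_is_novel, dtype=bool)
    p = np.asarray(pred_is_novel, dtype=bool)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("invalid novel-flag vectors")
    acc = float(_skm.accuracy_score(t, p))
    f1 = float(_skm.f1_score(t, p, pos_label=True, zero_division=0))
    return acc, f1


def compute_report(true_labels: Sequence, pred_labels: Sequence) -> MetricsReport:
    t, p, classes = _check(true_labels, pred_labels)
    return MetricsReport(
        macro_f1=macro_f1(t, p),
        kappa=cohens_kappa(t, p),
        jaccard=jaccard_score(t, p),
        accuracy=accuracy(t, p),
        per_class_f1=per_class_f1(t, p),
        n_cells=len(t),
        n_types=len(classes),
    )


def describe_dataset(m: PeakMatrix) -> DatasetDescriptor:
    if m.labels is None:
        raise ValueError("labels are required to describe a dataset")
    counts = {}
    for l in m.labels:
        counts[l] = counts.get(l, 0) + 1
    major = max(counts.values()) / m.n_cells
    return DatasetDescriptor(
        sparsity=sparsity(m),
        imbalance_degree=imbalance_degree(counts),
        major_type_proportion=major,
    )
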