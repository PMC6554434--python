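"""Detection scores against ground truth.

Supervised scoring treats each window as a binary detection (does it belong
to any detected assembly cluster?) and reports precision, recall,
specificity and their harmonic-mean F-score.  Unsupervised scoring compares
two partitions of the windows — detected clusters vs true clusters plus a
noise class — by purity (are detected clusters homogeneous?) and inverse
purity (are true clusters recovered whole?), combined into the harmonic
mean; the harmonic mean penalises both the all-singletons and the
one-big-cluster trivial solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Confusion",
    "f_supervised",
    "f_unsupervised",
    "partition_from_labels",
]


@dataclass(frozen=True)
class Confusion:
    """Window-level confusion counts against ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, score set to 0")
        return 0.0
    return num / den


def f_supervised(c: Confusion) -> tuple[float, float, float, float]:
    """(precision, recall, specificity, F) from a confusion table.

    F is the harmonic mean of precision and recall; any zero denominator
    yields a 0 score with a warning.
    """
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    specificity = _safe_div(c.tn, c.tn + c.fp, "specificity")
    if precision + recall == 0:
        f = 0.0
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return precision, recall, specificity, f


def _cluster_sets(labels: np.ndarray, include: set[int] | None = None) -> list[np.ndarray]:
    out = []
    for c in np.unique(labels):
        if include is not None and c not in include:
            continue
        out.append(np.flatnonzero(labels == c))
    return out


def f_unsupervised(
    detected: list[np.ndarray] | list[list[int]],
    true: list[np.ndarray] | list[list[int]],
    total: int | None = None,
) -> tuple[float, float, float]:
    """(purity, inverse_purity, F) between two families of clusters.

    ``detected`` and ``true`` are lists of index collections; ``true`` should
    include the noise class as one of its clusters.  ``total`` defaults to
    the number of indices covered by ``true``.  Empty clusters are ignored
    with a warning.

    Purity           = sum_i |C_i|/T * max_j |C_i ∩ L_j| / |C_i|
    Inverse purity   = sum_j |L_j|/T * max_i |C_i ∩ L_j| / |L_j|
    F                = harmonic mean of the two.
    """
    C = [np.asarray(c, dtype=np.int64) for c in detected]
    L = [np.asarray(l, dtype=np.int64) for l in true]
    if any(c.size == 0 for c in C) or any(l.size == 0 for l in L):
        warnings.warn("empty clusters ignored")
        C = [c for c in C if c.size]
        L = [l for l in L if l.size]
    if not C or not L:
        raise ValueError("need at least one non-empty cluster on each side")
    if total is None:
        total = int(np.unique(np.concatenate(L)).size)
    Lsets = [set(l.tolist()) for l in L]
    Csets = [set(c.tolist()) for c in C]
    purity = sum(
        max(len(cs & ls) for ls in Lsets) / total for cs in Csets
    )
    inverse = sum(
        max(len(cs & ls) for cs in Csets) / total for ls in Lsets
    )
    if purity + inverse == 0:
        return purity, inverse, 0.0
    return purity, inverse, 2.0 * purity * inverse / (purity + inverse)


def partition_from_labels(
    detected_labels: np.ndarray, true_labels: np.ndarray, noise: int = -1
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Build the two cluster families from per-window label vectors.

    Windows labelled ``noise`` on the detected side form one detected
    "noise" cluster (mirroring the true noise class), so both families cover
    every window; overlapping memberships must already be resolved to one
    label per window (see :meth:`spikeseq.clustering.ClusterSet.primary_labels`).
    """
    detected_labels = np.asarray(detected_labels)
    true_labels = np.asarray(true_labels)
    if detected_labels.shape != true_labels.shape:
        raise ValueError("label vectors must have equal length")
    detected = _cluster_sets(detected_labels)
    true = _cluster_sets(true_labels)
    return detected, true
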