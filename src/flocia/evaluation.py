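"""Agreement statistics: count matrices, accuracy, precision, Fleiss kappa.

Two square count matrices are used to evaluate a color-classification
pipeline.  A *matching matrix* compares one rater's categorical answers
across two replications (repeatability); a *confusion matrix* compares
ground-truth categories (rows) against automatic predictions (columns).
Accuracy is the diagonal fraction of either matrix; per-category
precision divides each diagonal cell by its predicted-column total.
Fleiss kappa measures chance-corrected agreement among many raters
assigning subjects to nominal categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "RatingTable",
    "build_count_matrix",
    "accuracy",
    "per_category_precision",
    "fleiss_kappa",
    "strength_of_agreement",
]

#: Strength-of-agreement bands for positive kappa.  Bands are
#: left-closed/right-open ([0.2, 0.4) is "fair") with the top band closed
#: at 1.0, so each boundary value belongs to the stronger band.
AGREEMENT_BANDS: tuple[tuple[float, float, str], ...] = (
    (0.0, 0.2, "slight"),
    (0.2, 0.4, "fair"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "substantial"),
    (0.8, 1.0, "almost perfect"),
)


@dataclass(frozen=True)
class CountMatrix:
    """Square category-by-category count matrix.

    Rows are actual (or first-replication) categories, columns predicted
    (or second-replication).
    """

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        if counts.sum() == 0:
            raise ValueError("count matrix must contain at least one item")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class RatingTable:
    """Subjects x categories table of rating counts for Fleiss kappa.

    ``counts[i, j]`` is the number of raters who assigned subject ``i``
    to category ``j``; every row must sum to the same number of raters.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 1 or counts.shape[1] < 2:
            raise ValueError("rating table must be (N subjects, >=2 categories)")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("rating counts must be nonnegative integers")
        row_sums = counts.sum(axis=1)
        if not np.all(row_sums == row_sums[0]):
            raise ValueError("every subject must be rated by the same number of raters")
        if row_sums[0] < 2:
            raise ValueError("at least two raters per subject are required")
        object.__setattr__(self, "counts", counts)

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_raters(self) -> int:
        return int(self.counts.sum(axis=1)[0])


def build_count_matrix(
    first: Sequence[str],
    second: Sequence[str],
    labels: Sequence[str],
) -> CountMatrix:
    """Tally paired label sequences into a count matrix.

    Cell (i, j) counts items labeled ``labels[i]`` in ``first`` and
    ``labels[j]`` in ``second``.
    """
    if len(first) != len(second):
        raise ValueError("label sequences must have equal length")
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for a, b in zip(first, second):
        if a not in index or b not in index:
            unknown = a if a not in index else b
            raise ValueError(f"unknown label {unknown!r}")
        counts[index[a], index[b]] += 1
    return CountMatrix(labels=labels, counts=counts)


def accuracy(m: CountMatrix) -> float:
    """Fraction of items on the diagonal: trace / total."""
    return float(np.trace(m.counts)) / m.total


def per_category_precision(m: CountMatrix) -> dict[str, float | None]:
    """Diagonal cell over predicted-column total, per category.

    A category never predicted (column sum 0) has undefined precision
    and is reported as ``None``, distinct from a precision of 0.
    """
    col_sums = m.counts.sum(axis=0)
    diag = np.diag(m.counts)
    out: dict[str, float | None] = {}
    for lab, d, c in zip(m.labels, diag, col_sums):
        out[lab] = float(d) / float(c) if c > 0 else None
    return out


def fleiss_kappa(table: RatingTable | np.ndarray) -> float:
    """Fleiss' kappa for many raters and nominal categories.

    With ``n`` raters, ``N`` subjects and counts ``n_ij``:

    .. math::

        P_i = \\frac{\\sum_j n_{ij}^2 - n}{n(n-1)}, \\qquad
        \\bar P = \\frac{1}{N}\\sum_i P_i, \\qquad
        p_j = \\frac{\\sum_i n_{ij}}{Nn}, \\qquad
        \\bar P_e = \\sum_j p_j^2,

    and ``kappa = (P_bar - P_e) / (1 - P_e)``.  When all mass falls in a
    single category (``P_e = 1``) the statistic is 1 under unanimity and
    undefined (NaN) otherwise.
    """
    if not isinstance(table, RatingTable):
        table = RatingTable(np.asarray(table))
    counts = table.counts.astype(np.float64)
    n = table.n_raters
    n_subj = table.n_subjects
    p_i = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / (n_subj * n)
    p_e = float((p_j**2).sum())
    if p_e >= 1.0:
        return 1.0 if p_bar == 1.0 else float("nan")
    return float((p_bar - p_e) / (1.0 - p_e))


def strength_of_agreement(kappa: float) -> str:
    """Map a kappa value to its conventional strength-of-agreement label.

    Bands above zero are left-closed/right-open — [0, 0.2) slight,
    [0.2, 0.4) fair, [0.4, 0.6) moderate, [0.6, 0.8) substantial,
    [0.8, 1.0] almost perfect — so a boundary value belongs to the
    stronger band.  Values at or below zero indicate poor/no agreement
    beyond chance.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [-1, 1], got {kappa}")
    if kappa <= 0.0:
        return "poor/none"
    for lo, hi, label in AGREEMENT_BANDS:
        if lo <= kappa < hi:
            return label
    return "almost perfect"  # kappa == 1.0
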