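"""Fisher's inverse chi-square meta-score and its genome-wide threshold objective.

Per gene i, the K study p-values (from the Wilcoxon-Mann-Whitney test at a
candidate threshold q) combine into S_i = -2 * sum_k log p_ik, which is
chi-square with 2K degrees of freedom under the joint null.  The threshold
objective sums S_i over all genes; the candidate maximizing that sum separates
the two patient groups by the largest genome-wide expression difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_MIN_GROUP,
    InvalidSplitError,
    StudyCollection,
    split_by_threshold,
)
from .de_stats import wmw_pvalues

__all__ = [
    "PValueMatrix",
    "fisher_score",
    "fisher_scores",
    "pvalue_matrix",
    "fisher_objective",
    "InvalidSplitError",
    "P_FLOOR",
]

#: p-values are clamped here before the log so numerically-zero approximations
#: cannot produce infinite scores.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class PValueMatrix:
    """WMW p-values, genes x studies, at one threshold (clamped away from 0)."""

    values: np.ndarray  # (I, K)
    threshold_q: float
    study_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        values = np.clip(values, P_FLOOR, 1.0)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "study_ids", tuple(self.study_ids))
        if values.ndim != 2 or values.shape[1] != len(self.study_ids):
            raise ValueError("values must be (I, K) with K == len(study_ids)")


def fisher_score(pvals: np.ndarray) -> float:
    """Combine K p-values into S = -2 * sum(log p); chi2_{2K} under the null."""
    p = np.asarray(pvals, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return float(-2.0 * np.sum(np.log(np.clip(p, P_FLOOR, 1.0))))


def fisher_scores(pmat: PValueMatrix) -> np.ndarray:
    """Per-gene Fisher scores S_i from a genes x studies p-value matrix."""
    return -2.0 * np.sum(np.log(pmat.values), axis=1)


def pvalue_matrix(
    collection: StudyCollection, q: float, min_group: int = DEFAULT_MIN_GROUP
) -> PValueMatrix:
    """WMW p-values per gene per study at threshold ``q``.

    Raises :class:`InvalidSplitError` when any study's split violates the
    group-size floor at ``q`` — scans treat that grid point as undefined.
    """
    cols = []
    for study in collection:
        split = split_by_threshold(study, q, min_group)
        if not split.valid:
            raise InvalidSplitError(
                f"threshold q={q:g} gives groups {split.n_small}/{split.n_large} "
                f"in study {study.study_id!r} (min_group={min_group})"
            )
        cols.append(wmw_pvalues(study.expression, split.small_mask))
    values = np.column_stack(cols)
    return PValueMatrix(values, float(q), tuple(s.study_id for s in collection))


def fisher_objective(
    collection: StudyCollection, q: float, min_group: int = DEFAULT_MIN_GROUP
) -> float:
    """Genome-wide Fisher objective sum_i S_i(q); maximized over candidate q."""
    return float(np.sum(fisher_scores(pvalue_matrix(collection, q, min_group))))
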