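"""DEDS distance synthesis and the cross-study (mDEDS) threshold objective.

Differential Expression via Distance Synthesis ranks genes by how close their
vector of DE statistics comes to an "extreme point" — the coordinate-wise
maximum of the statistics over all genes, further pushed out by permutation:
the group labels are randomly relabeled B times, each relabeling yields its
own extreme point, and the overall extreme E is the coordinate-wise maximum
of the observed and all permuted extremes.  The per-gene distance is

    d_i = sum_j (t_ij - E_j)^2 / MAD_j^2

with MAD_j the (unscaled) median absolute deviation of statistic j across
genes.  The mDEDS threshold objective sums d_i over genes and over the K
matched studies; the candidate threshold minimizing that sum leaves the gene
cloud closest to its own extreme corner, i.e. concentrates differential
expression most strongly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .core import (
    DEFAULT_MIN_GROUP,
    ExpressionStudy,
    GroupSplit,
    InvalidSplitError,
    StudyCollection,
    split_by_threshold,
)
from .de_stats import ALL_STATS, StatMatrix, batch_stat_values

__all__ = [
    "ExtremePoint",
    "DistanceVector",
    "PermutationConfig",
    "FULL_ENUM_MAX",
    "derive_seed",
    "permutation_masks",
    "extreme_from_masks",
    "observed_extreme",
    "permuted_extreme",
    "overall_extreme",
    "deds_distances",
    "study_stats_and_extreme",
    "mdeds_objective",
]

#: Below this many distinct relabelings the permutation space is enumerated
#: exhaustively instead of sampled.
FULL_ENUM_MAX = 500


@dataclass(frozen=True)
class ExtremePoint:
    """Coordinate-wise maximum of J statistics; the DEDS distance origin."""

    coords: np.ndarray  # (J,)
    stat_names: tuple[str, ...]
    provenance: str  # observed | permuted | overall | tep

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "stat_names", tuple(self.stat_names))
        if coords.shape != (len(self.stat_names),):
            raise ValueError("coords length must match stat_names")
        if np.any(~np.isfinite(coords)):
            raise ValueError("extreme point coordinates must be finite")
        if self.provenance not in {"observed", "permuted", "overall", "tep"}:
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass(frozen=True)
class DistanceVector:
    """Per-gene scaled squared distances to an extreme point.

    ``mad_scales`` records the per-statistic scale actually used: the column
    MAD, the column standard deviation when the MAD is zero, or +inf when the
    column is constant (such a column carries no ranking information and
    contributes zero to every distance).
    """

    d: np.ndarray  # (I,)
    mad_scales: np.ndarray  # (J,)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        scales = np.asarray(self.mad_scales, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "mad_scales", scales)
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        if np.any(scales <= 0):
            raise ValueError("mad_scales must be positive (inf marks constant columns)")


@dataclass(frozen=True)
class PermutationConfig:
    """Number of group relabelings and the seed that makes them reproducible."""

    n_permutations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")

    def with_seed(self, seed: int) -> "PermutationConfig":
        return PermutationConfig(self.n_permutations, seed)


def derive_seed(base_seed: int, study_index: int, q: float) -> int:
    """Deterministic per-(study, threshold) seed below 2^31.

    Scans draw independent, reproducible permutations at every grid point; the
    threshold enters via its value in tenths of a millimeter so equal q always
    maps to equal draws regardless of grid construction.
    """
    ss = np.random.SeedSequence([int(base_seed), int(study_index), int(round(q * 100))])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def permutation_masks(split: GroupSplit, perm: PermutationConfig) -> np.ndarray:
    """B small-group masks preserving the observed group sizes.

    The full space of C(n, n_small) relabelings is enumerated when it has at
    most ``FULL_ENUM_MAX`` elements; otherwise ``n_permutations`` relabelings
    are sampled uniformly with replacement.
    """
    if perm.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1 to build permutation masks")
    n = split.small_mask.size
    n_small = split.n_small
    space = math.comb(n, n_small)
    if space <= FULL_ENUM_MAX:
        masks = np.zeros((space, n), dtype=bool)
        for b, idx in enumerate(combinations(range(n), n_small)):
            masks[b, list(idx)] = True
        return masks
    rng = np.random.default_rng(perm.seed)
    masks = np.zeros((perm.n_permutations, n), dtype=bool)
    for b in range(perm.n_permutations):
        masks[b, rng.choice(n, size=n_small, replace=False)] = True
    return masks


def extreme_from_masks(
    study: ExpressionStudy,
    masks: np.ndarray,
    stat_names: Sequence[str] = ALL_STATS,
    fold: bool = True,
) -> ExtremePoint:
    """Coordinate-wise extreme over genes and over the given group masks."""
    values = batch_stat_values(study.expression, masks, stat_names, fold=fold)
    coords = values.max(axis=(0, 1))
    return ExtremePoint(coords, tuple(stat_names), provenance="permuted")


def observed_extreme(stats: StatMatrix) -> ExtremePoint:
    """E_0: coordinate-wise maximum of each statistic column over all genes."""
    if stats.values.shape[0] == 0:
        raise ValueError("empty statistic matrix")
    return ExtremePoint(
        stats.values.max(axis=0), stats.stat_names, provenance="observed"
    )


def permuted_extreme(
    study: ExpressionStudy,
    split: GroupSplit,
    stat_names: Sequence[str],
    perm: PermutationConfig,
    fold: bool = True,
) -> ExtremePoint:
    """E_p: coordinate-wise maximum of extreme points over B random relabelings."""
    if not split.valid:
        raise InvalidSplitError(
            f"invalid split at q={split.threshold_q:g} in study {study.study_id!r}"
        )
    masks = permutation_masks(split, perm)
    return extreme_from_masks(study, masks, stat_names, fold=fold)


def overall_extreme(e0: ExtremePoint, ep: ExtremePoint) -> ExtremePoint:
    """E = max(E_0, E_p), coordinate-wise."""
    if e0.stat_names != ep.stat_names:
        raise ValueError(
            f"stat_names mismatch: {e0.stat_names} vs {ep.stat_names}"
        )
    return ExtremePoint(
        np.maximum(e0.coords, ep.coords), e0.stat_names, provenance="overall"
    )


def _column_scales(values: np.ndarray) -> np.ndarray:
    """Per-column MAD (unscaled); sd where MAD is 0; +inf where both are 0."""
    med = np.median(values, axis=0)
    mad = np.median(np.abs(values - med), axis=0)
    sd = values.std(axis=0)
    scales = np.where(mad > 0, mad, np.where(sd > 0, sd, np.inf))
    return scales


def deds_distances(stats: StatMatrix, e: ExtremePoint) -> DistanceVector:
    """MAD-scaled squared distance from every gene to the extreme point."""
    if stats.stat_names != e.stat_names:
        raise ValueError("StatMatrix and ExtremePoint statistics differ")
    scales = _column_scales(stats.values)
    with np.errstate(invalid="ignore"):
        contrib = ((stats.values - e.coords) / scales) ** 2
    contrib[:, ~np.isfinite(scales)] = 0.0
    return DistanceVector(contrib.sum(axis=1), scales)


def study_stats_and_extreme(
    study: ExpressionStudy,
    q: float,
    stat_names: Sequence[str],
    perm: PermutationConfig,
    min_group: int = DEFAULT_MIN_GROUP,
    fold: bool = True,
) -> tuple[StatMatrix, ExtremePoint]:
    """Observed statistic panel and overall extreme E = max(E_0, E_p) at q.

    The observed labeling and all permuted relabelings are evaluated in one
    batched pass.  Raises :class:`InvalidSplitError` when q violates the
    group-size floor.
    """
    split = split_by_threshold(study, q, min_group)
    if not split.valid:
        raise InvalidSplitError(
            f"threshold q={q:g} gives groups {split.n_small}/{split.n_large} "
            f"in study {study.study_id!r} (min_group={min_group})"
        )
    perm_masks = permutation_masks(split, perm)
    masks = np.vstack([split.small_mask[None, :], perm_masks])
    values = batch_stat_values(study.expression, masks, stat_names, fold=fold)
    observed = StatMatrix(
        values[0], tuple(stat_names), study.study_id, float(q), fold
    )
    coords = values.max(axis=(0, 1))
    e = ExtremePoint(coords, tuple(stat_names), provenance="overall")
    return observed, e


def mdeds_objective(
    collection: StudyCollection,
    q: float,
    stat_names: Sequence[str] = ALL_STATS,
    perm: PermutationConfig = PermutationConfig(),
    min_group: int = DEFAULT_MIN_GROUP,
    fold: bool = True,
) -> float:
    """mDEDS objective at threshold q: sum of distances over genes and studies.

    Each study gets its own split, statistic panel, permutation-calibrated
    extreme point and MAD scales; per-gene distances are then summed across
    studies on the shared matched gene index and over all genes.  Permutation
    seeds derive deterministically from (perm.seed, study index, q).
    """
    total = 0.0
    for k, study in enumerate(collection):
        sub_perm = perm.with_seed(derive_seed(perm.seed, k, q))
        stats_k, e_k = study_stats_and_extreme(
            study, q, stat_names, sub_perm, min_group, fold=fold
        )
        total += float(deds_distances(stats_k, e_k).d.sum())
    return total
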