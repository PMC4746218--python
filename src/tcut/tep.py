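"""The totally extreme point (TEP) extension of the DEDS threshold objective.

The mDEDS objective rebuilds its extreme point at every candidate threshold,
so the distance origin drifts as the scan moves — objective values at
different thresholds are measured against different corners.  The TEP variant
fixes a single origin for the whole scan:

    E_max = max over all valid grid thresholds q, all studies, of
            E_q = max(E_0^(q), E_p^(q))

computed coordinate-wise per statistic.  Distances at each threshold are then
taken to this shared E_max (MAD scales still per study, statistic and
threshold), making the objective comparable across the entire grid.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import (
    DEFAULT_MIN_GROUP,
    InvalidSplitError,
    StudyCollection,
    split_by_threshold,
)
from .de_stats import ALL_STATS, compute_stat_matrix
from .deds import (
    ExtremePoint,
    PermutationConfig,
    deds_distances,
    derive_seed,
    study_stats_and_extreme,
)

__all__ = ["tep_extreme", "tep_objective"]


def tep_extreme(
    collection: StudyCollection,
    grid: Sequence[float],
    stat_names: Sequence[str] = ALL_STATS,
    perm: PermutationConfig = PermutationConfig(),
    min_group: int = DEFAULT_MIN_GROUP,
    fold: bool = True,
) -> ExtremePoint:
    """E_max: coordinate-wise maximum of E_q over the whole grid and all studies.

    Grid points where any study violates the group-size floor are skipped; at
    least one grid point must survive.  Permutation seeds derive from
    (perm.seed, study index, q) exactly as in the per-threshold mDEDS pass, so
    a TEP scan and an mDEDS scan at the same base seed see the same draws.
    """
    if len(grid) == 0:
        raise ValueError("threshold grid is empty")
    coords: np.ndarray | None = None
    for q in grid:
        try:
            for k, study in enumerate(collection):
                sub_perm = perm.with_seed(derive_seed(perm.seed, k, q))
                _, e_q = study_stats_and_extreme(
                    study, q, stat_names, sub_perm, min_group, fold=fold
                )
                coords = e_q.coords if coords is None else np.maximum(coords, e_q.coords)
        except InvalidSplitError:
            continue
    if coords is None:
        raise InvalidSplitError("no grid threshold yields a valid split in all studies")
    return ExtremePoint(coords, tuple(stat_names), provenance="tep")


def tep_objective(
    collection: StudyCollection,
    q: float,
    e_max: ExtremePoint,
    stat_names: Sequence[str] = ALL_STATS,
    min_group: int = DEFAULT_MIN_GROUP,
    fold: bool = True,
) -> float:
    """TEP objective at q: distances of all genes, all studies, to the fixed E_max.

    ``e_max`` is computed once per scan (:func:`tep_extreme`) and reused at
    every threshold; only the observed statistic panels and their MAD scales
    are re-evaluated here.
    """
    if tuple(stat_names) != e_max.stat_names:
        raise ValueError("stat_names do not match the provided E_max")
    total = 0.0
    for study in collection:
        split = split_by_threshold(study, q, min_group)
        if not split.valid:
            raise InvalidSplitError(
                f"threshold q={q:g} gives groups {split.n_small}/{split.n_large} "
                f"in study {study.study_id!r} (min_group={min_group})"
            )
        stats_k = compute_stat_matrix(study, split, stat_names, fold=fold)
        total += float(deds_distances(stats_k, e_max).d.sum())
    return total
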