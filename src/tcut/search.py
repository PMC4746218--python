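"""Threshold-grid construction, objective scanning and optimum selection.

A scan evaluates one of the three objectives (fisher, mdeds, tep) at every
candidate threshold of an ascending grid; grid points where any study's group
falls below the size floor are flagged invalid and excluded from the argopt.
Fisher is maximized, the two distance objectives are minimized; exact ties
break to the largest tied threshold (see :func:`optimal_threshold`).  A
coarse scan can be refined on a finer grid around its optimum.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_MIN_GROUP, InvalidSplitError, StudyCollection, split_by_threshold
from .de_stats import ALL_STATS
from .deds import ExtremePoint, PermutationConfig, mdeds_objective
from .fisher import fisher_objective
from .tep import tep_extreme, tep_objective

__all__ = [
    "METHODS",
    "ThresholdScan",
    "make_grid",
    "scan_thresholds",
    "optimal_threshold",
    "refine_scan",
    "write_scan_tsv",
]

METHODS = ("fisher", "mdeds", "tep")
_DIRECTIONS = {"fisher": "max", "mdeds": "min", "tep": "min"}

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdScan:
    """Objective values over a threshold grid and the selected optimum q0.

    ``objective_values`` is aligned to ``grid``; NaN marks thresholds where
    some study's split violates the group-size floor (excluded from the
    optimum).  ``per_study_group_sizes`` is a long-format table with one row
    per (threshold, study).
    """

    grid: np.ndarray
    objective_values: np.ndarray
    method: str
    q0: float
    per_study_group_sizes: pd.DataFrame
    stat_names: tuple[str, ...] = ALL_STATS
    perm: PermutationConfig = PermutationConfig()
    min_group: int = DEFAULT_MIN_GROUP
    fold: bool = True
    e_max: ExtremePoint | None = None  # set for method="tep"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.objective_values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "objective_values", values)
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if values.shape != grid.shape:
            raise ValueError("objective_values must align with grid")

    @property
    def direction(self) -> str:
        return _DIRECTIONS[self.method]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.objective_values)


def make_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid lo, lo+step, ..., hi with decimal-safe labels.

    The endpoint is included when it lies within half a step of the last
    multiple; values are rounded to the step's decimal places so candidate
    thresholds carry clean labels (2.0, not 2.0000000000000004).
    """
    if not (lo < hi):
        raise ValueError("lo must be < hi")
    if step <= 0:
        raise ValueError("step must be > 0")
    if step >= hi - lo:
        raise ValueError("step must be smaller than the grid range")
    decimals = max(0, int(math.ceil(-math.log10(step) - 1e-9)))
    n = int(math.floor((hi - lo) / step + 0.5 + 1e-9))
    grid = lo + step * np.arange(n + 1)
    grid = grid[grid <= hi + step / 2 + 1e-12]
    return np.round(grid, decimals)


def scan_thresholds(
    collection: StudyCollection,
    grid: Sequence[float],
    method: str,
    stat_names: Sequence[str] = ALL_STATS,
    perm: PermutationConfig = PermutationConfig(),
    min_group: int = DEFAULT_MIN_GROUP,
    fold: bool = True,
) -> ThresholdScan:
    """Evaluate one objective over the grid and select the optimal threshold.

    For the TEP method the totally extreme point is computed once, up front,
    over the whole grid (observed + permutation extremes, all studies) and
    shared by every per-threshold distance evaluation.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    grid = np.asarray(make_grid_like(grid), dtype=float)
    stat_names = tuple(stat_names)

    e_max: ExtremePoint | None = None
    if method == "tep":
        e_max = tep_extreme(collection, grid, stat_names, perm, min_group, fold)

    values = np.full(grid.shape, np.nan)
    rows = []
    for i, q in enumerate(grid):
        all_valid = True
        for study in collection:
            split = split_by_threshold(study, q, min_group)
            rows.append(
                {
                    "q": float(q),
                    "study_id": study.study_id,
                    "n_small": split.n_small,
                    "n_large": split.n_large,
                    "valid": split.valid,
                }
            )
            all_valid &= split.valid
        if not all_valid:
            log.info("method=%s q=%g skipped (group-size floor)", method, q)
            continue
        t_q = time.perf_counter()
        try:
            if method == "fisher":
                values[i] = fisher_objective(collection, q, min_group)
            elif method == "mdeds":
                values[i] = mdeds_objective(
                    collection, q, stat_names, perm, min_group, fold
                )
            else:
                values[i] = tep_objective(
                    collection, q, e_max, stat_names, min_group, fold
                )
        except InvalidSplitError:
            continue
        log.info(
            "method=%s q=%g objective=%g elapsed=%.2fs",
            method, q, values[i], time.perf_counter() - t_q,
        )
    if not np.any(np.isfinite(values)):
        raise InvalidSplitError(
            "no grid threshold yields a valid split in every study"
        )
    scan = ThresholdScan(
        grid=grid,
        objective_values=values,
        method=method,
        q0=np.nan,
        per_study_group_sizes=pd.DataFrame(rows),
        stat_names=stat_names,
        perm=perm,
        min_group=min_group,
        fold=fold,
        e_max=e_max,
    )
    return replace(scan, q0=optimal_threshold(scan))


def make_grid_like(grid: Sequence[float]) -> np.ndarray:
    """Pass through an explicit candidate list as an ascending float array."""
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("grid must be a non-empty 1-D sequence")
    if np.any(np.diff(g) <= 0):
        raise ValueError("grid must be strictly ascending")
    return g


def optimal_threshold(scan: ThresholdScan) -> float:
    """Grid point attaining the scan's extremum; exact ties go to the largest q.

    An exact tie between neighboring thresholds means they induce the same
    sample partition in every study (no sample size falls between them).
    Under the size <= q boundary rule the largest tied q is the natural label
    for that partition: it is the supremum of tumor sizes the optimal small
    group would admit, and it is the value the generative boundary carries
    when the size distributions leave a gap around it.
    """
    values = scan.objective_values
    defined = np.isfinite(values)
    if not np.any(defined):
        raise ValueError("scan has no defined objective values")
    search = np.where(defined, values, -np.inf if scan.direction == "max" else np.inf)
    # argmax/argmin return the first index; reverse to take the last (= largest q)
    rev = search[::-1]
    off = int(np.argmax(rev)) if scan.direction == "max" else int(np.argmin(rev))
    return float(scan.grid[len(search) - 1 - off])


def refine_scan(
    collection: StudyCollection,
    coarse: ThresholdScan,
    half_width: float,
    step: float,
) -> ThresholdScan:
    """Rescan [q0 - half_width, q0 + half_width] at a finer step, same method."""
    if not np.isfinite(coarse.q0):
        raise ValueError("coarse scan has no defined optimum")
    if step >= 2 * half_width:
        raise ValueError("step must be smaller than the refinement window")
    grid = make_grid(coarse.q0 - half_width, coarse.q0 + half_width, step)
    return scan_thresholds(
        collection,
        grid,
        coarse.method,
        stat_names=coarse.stat_names,
        perm=coarse.perm,
        min_group=coarse.min_group,
        fold=coarse.fold,
    )


def write_scan_tsv(scan: ThresholdScan, path: str | Path) -> None:
    """Write the scan table: one row per grid point plus a q0 summary line.

    Columns: q, objective, valid, then per-study n_small/n_large.  For a TEP
    scan a JSON sidecar ``<path>.emax.json`` records the shared extreme-point
    coordinates.
    """
    path = Path(path)
    sizes = scan.per_study_group_sizes
    wide = sizes.pivot(index="q", columns="study_id", values=["n_small", "n_large"])
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    table = pd.DataFrame(
        {
            "q": scan.grid,
            "objective": scan.objective_values,
            "valid": scan.valid.astype(int),
        }
    ).merge(wide.reset_index(), on="q", how="left")
    with open(path, "w") as fh:
        fh.write(
            f"# method={scan.method}\tdirection={scan.direction}\t"
            f"q0={scan.q0:g}\tB={scan.perm.n_permutations}\tseed={scan.perm.seed}\n"
        )
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    if scan.e_max is not None:
        sidecar = {
            "stat_names": list(scan.e_max.stat_names),
            "coords": [float(c) for c in scan.e_max.coords],
        }
        Path(f"{path}.emax.json").write_text(json.dumps(sidecar, indent=2) + "\n")
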