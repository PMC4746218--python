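"""Core data model and tabular I/O.

An :class:`ExpressionStudy` holds one cohort's features x samples expression
matrix together with the per-sample tumor sizes (cm).  Several studies with a
shared, identically ordered feature list form a :class:`StudyCollection`, the
unit on which the meta-analytic threshold objectives operate.  A candidate
threshold ``q`` splits each study's samples into a "small" group (size <= q)
and a "large" group; :class:`GroupSplit` records that partition and whether it
satisfies the minimum-group-size floor.

File formats are plain tab-delimited text: the expression matrix has a header
row of sample identifiers and a first column of feature identifiers; the sizes
table has two columns, ``sample_id`` and ``size_cm``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionStudy",
    "StudyCollection",
    "GroupSplit",
    "InvalidSplitError",
    "read_expression_study",
    "write_expression_study",
    "match_features",
    "split_by_threshold",
    "DEFAULT_MIN_GROUP",
]

#: Smallest group size accepted as a valid two-group comparison.  Three is the
#: smallest n for which the rank test is not fully degenerate; configurable in
#: every operation that takes a ``min_group`` argument.
DEFAULT_MIN_GROUP = 3


class InvalidSplitError(ValueError):
    """A candidate threshold leaves some study's group below the size floor."""


@dataclass(frozen=True)
class ExpressionStudy:
    """One study's expression matrix with per-sample tumor sizes.

    Parameters
    ----------
    expression
        Array of shape ``(I, n)``: I features by n samples.  Log-scale or raw;
        the downstream statistics are scale-agnostic.
    feature_ids
        I unique feature (gene / probe) identifiers, one per matrix row.
    sample_ids
        n unique sample identifiers, one per matrix column.
    sizes
        n strictly positive tumor sizes in cm, aligned to ``sample_ids``.
    study_id
        Short label used in scan tables and error messages.
    """

    expression: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    sizes: np.ndarray
    study_id: str

    def __post_init__(self) -> None:
        expr = np.asarray(self.expression, dtype=float)
        sizes = np.asarray(self.sizes, dtype=float)
        object.__setattr__(self, "expression", expr)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if expr.ndim != 2:
            raise ValueError(f"expression must be 2-D, got shape {expr.shape}")
        I, n = expr.shape
        if len(self.feature_ids) != I:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {I} matrix rows"
            )
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} matrix columns"
            )
        if sizes.shape != (n,):
            raise ValueError(f"sizes has shape {sizes.shape}, expected ({n},)")
        dup = _first_duplicate(self.feature_ids)
        if dup is not None:
            raise ValueError(f"duplicate feature id {dup!r} in study {self.study_id!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample id {dup!r} in study {self.study_id!r}")
        if not np.all(np.isfinite(expr)):
            bad = np.argwhere(~np.isfinite(expr))[0]
            raise ValueError(
                f"non-finite expression value at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if not np.all(np.isfinite(sizes)) or np.any(sizes <= 0):
            raise ValueError("sizes must be strictly positive and finite")

    @property
    def n_features(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def restrict_features(self, feature_ids: Sequence[str]) -> "ExpressionStudy":
        """Return a copy limited to ``feature_ids``, in the given order."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            rows = [index[f] for f in feature_ids]
        except KeyError as exc:
            raise KeyError(
                f"feature {exc.args[0]!r} absent from study {self.study_id!r}"
            ) from None
        return ExpressionStudy(
            expression=self.expression[rows, :],
            feature_ids=tuple(feature_ids),
            sample_ids=self.sample_ids,
            sizes=self.sizes,
            study_id=self.study_id,
        )


@dataclass(frozen=True)
class StudyCollection:
    """K matched studies sharing one feature list in one order."""

    studies: tuple[ExpressionStudy, ...]

    def __post_init__(self) -> None:
        studies = tuple(self.studies)
        object.__setattr__(self, "studies", studies)
        if len(studies) < 1:
            raise ValueError("a StudyCollection needs at least one study")
        ref = studies[0].feature_ids
        for s in studies[1:]:
            if s.feature_ids != ref:
                raise ValueError(
                    f"study {s.study_id!r} feature ids differ from "
                    f"study {studies[0].study_id!r}; run match_features first"
                )

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return self.studies[0].feature_ids

    @property
    def n_features(self) -> int:
        return self.studies[0].n_features

    def __iter__(self):
        return iter(self.studies)

    def __len__(self) -> int:
        return len(self.studies)


@dataclass(frozen=True)
class GroupSplit:
    """Two-group sample partition at a tumor-size threshold.

    ``small_mask[j]`` is True when sample j's size is <= ``threshold_q`` (ties
    at the threshold go to the small group, mirroring the clinical convention
    that T1 means size <= 2.0 cm).  ``valid`` is True iff both groups reach the
    minimum size floor.
    """

    threshold_q: float
    small_mask: np.ndarray
    min_group: int = DEFAULT_MIN_GROUP

    def __post_init__(self) -> None:
        mask = np.asarray(self.small_mask, dtype=bool)
        object.__setattr__(self, "small_mask", mask)

    @property
    def n_small(self) -> int:
        return int(np.count_nonzero(self.small_mask))

    @property
    def n_large(self) -> int:
        return int(self.small_mask.size - self.n_small)

    @property
    def valid(self) -> bool:
        return min(self.n_small, self.n_large) >= self.min_group


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def read_expression_study(
    matrix_path: str | Path, sizes_path: str | Path, study_id: str
) -> ExpressionStudy:
    """Read a study from an expression-matrix TSV and a sizes TSV.

    The matrix file is tab-delimited with a header row of sample ids and a
    first column of feature ids.  The sizes file has two columns
    (sample_id, size_cm) with a header; it may list extra samples, but every
    matrix sample must be present.  Samples are kept in matrix column order.
    """
    matrix_path, sizes_path = Path(matrix_path), Path(sizes_path)
    frame = pd.read_csv(matrix_path, sep="\t", header=0, index_col=0, dtype=str)
    feature_ids = [str(f) for f in frame.index]
    sample_ids = [str(c) for c in frame.columns]
    dup = _first_duplicate(feature_ids)
    if dup is not None:
        raise ValueError(f"duplicate feature id {dup!r} in {matrix_path}")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError:
        values = _parse_matrix_strict(frame, matrix_path)
    if np.any(~np.isfinite(values)):
        values = _parse_matrix_strict(frame, matrix_path)  # pinpoint the cell

    # round_trip: the default C float parser is not correctly rounded and
    # breaks bit-exact matrix/sizes round-trips
    sizes_table = pd.read_csv(sizes_path, sep="\t", header=0, float_precision="round_trip")
    if sizes_table.shape[1] < 2:
        raise ValueError(f"sizes file {sizes_path} needs two columns (sample_id, size_cm)")
    size_map = dict(
        zip(sizes_table.iloc[:, 0].astype(str), sizes_table.iloc[:, 1].astype(float))
    )
    missing = [s for s in sample_ids if s not in size_map]
    if missing:
        raise ValueError(
            f"sizes file {sizes_path} is missing sample(s) {missing} "
            f"present in {matrix_path}"
        )
    sizes = np.array([size_map[s] for s in sample_ids], dtype=float)
    return ExpressionStudy(values, feature_ids, sample_ids, sizes, study_id)


def _parse_matrix_strict(frame: pd.DataFrame, path: Path) -> np.ndarray:
    """Cell-by-cell parse that names the offending row/column on failure."""
    out = np.empty(frame.shape, dtype=float)
    for i, (fid, row) in enumerate(frame.iterrows()):
        for j, (sid, cell) in enumerate(row.items()):
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"malformed numeric cell {cell!r} at feature {fid!r}, "
                    f"sample {sid!r} in {path}"
                ) from None
            if not np.isfinite(v):
                raise ValueError(
                    f"non-finite value {cell!r} at feature {fid!r}, "
                    f"sample {sid!r} in {path} (missing values are not supported)"
                )
            out[i, j] = v
    return out


def write_expression_study(
    study: ExpressionStudy, matrix_path: str | Path, sizes_path: str | Path
) -> None:
    """Write the study back out in the same TSV dialect read_expression_study reads."""
    frame = pd.DataFrame(
        study.expression, index=list(study.feature_ids), columns=list(study.sample_ids)
    )
    frame.index.name = "feature_id"
    frame.to_csv(matrix_path, sep="\t", float_format="%.17g")
    sizes = pd.DataFrame(
        {"sample_id": list(study.sample_ids), "size_cm": study.sizes}
    )
    sizes.to_csv(sizes_path, sep="\t", index=False, float_format="%.17g")


def match_features(studies: Sequence[ExpressionStudy]) -> StudyCollection:
    """Restrict each study to the shared features, in lexicographic order.

    Cross-study meta-analysis needs one gene index common to all studies; the
    intersection of feature ids is taken and rows are reordered to a canonical
    lexicographic order so gene i means the same probe everywhere.
    """
    if len(studies) < 1:
        raise ValueError("need at least one study")
    common = set(studies[0].feature_ids)
    for s in studies[1:]:
        common &= set(s.feature_ids)
    if not common:
        raise ValueError(
            "no features shared by all studies: "
            + ", ".join(s.study_id for s in studies)
        )
    order = sorted(common)
    return StudyCollection(tuple(s.restrict_features(order) for s in studies))


def split_by_threshold(
    study: ExpressionStudy, q: float, min_group: int = DEFAULT_MIN_GROUP
) -> GroupSplit:
    """Partition a study's samples at threshold ``q`` (size <= q -> small).

    Invalidity (a group below ``min_group``) is reported via the ``valid``
    flag rather than an exception so threshold scans can skip such points.
    """
    if not np.isfinite(q):
        raise ValueError("threshold q must be finite")
    if min_group < 2:
        raise ValueError("min_group must be >= 2")
    return GroupSplit(float(q), study.sizes <= q, min_group)
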