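"""Synthetic expression studies with a known tumor-size boundary.

The generator builds features x samples matrices in which a known fraction of
rows is differentially expressed between samples below and above a
tumor-size boundary of 3.0 cm: sizes are drawn uniformly on [1.0, 2.9] cm for
the small group and [3.0, 5.0] cm for the large group, DE rows take their
values from a block-specific distribution in the large-group samples and from
the dataset's background distribution in the small-group samples, and all
remaining rows are background everywhere.  Three built-in presets cover a
normal, a gamma and a Poisson DE regime:

========  ========  =============  ==============================  ============
preset    features  small/large    DE blocks (large samples)       background
========  ========  =============  ==============================  ============
simdat1   10,000    55 / 45        3500 x N(10, 10), 3500 x N(-2, 10)   N(3, 1)
simdat2   10,000    35 / 45        2000 x Gamma(5, 10), 4500 x Gamma(3, 6)  N(0.5, 10)
simdat3   10,000    120 / 80       2500 x Pois(10), 3500 x Pois(8)  N(0.1, 20)
========  ========  =============  ==============================  ============

Normal parameters are (mean, sd); gamma are (shape, scale); Poisson is its
rate.  :func:`simulate_de_fraction_suite` rescales the DE blocks of any spec
to a chosen overall DE fraction (block proportions preserved), which is how
robustness at 5-80 % DE genes is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import ExpressionStudy, StudyCollection

__all__ = [
    "Distribution",
    "DEBlock",
    "SimulationSpec",
    "BOUNDARY_CM",
    "simdat1_spec",
    "simdat2_spec",
    "simdat3_spec",
    "preset_specs",
    "simulate_sizes",
    "simulate_dataset",
    "simulate_collection",
    "simulate_de_fraction_suite",
]

#: Generative boundary between small and large tumors (cm).
BOUNDARY_CM = 3.0


@dataclass(frozen=True)
class Distribution:
    """A named sampling distribution: normal(mean, sd), gamma(shape, scale), poisson(rate)."""

    name: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        expected = {"normal": 2, "gamma": 2, "poisson": 1}
        if self.name not in expected:
            raise ValueError(f"unknown distribution {self.name!r}")
        if len(self.params) != expected[self.name]:
            raise ValueError(
                f"{self.name} takes {expected[self.name]} parameter(s), "
                f"got {len(self.params)}"
            )

    def sample(self, rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
        if self.name == "normal":
            mean, sd = self.params
            return rng.normal(mean, sd, size=shape)
        if self.name == "gamma":
            k, scale = self.params
            return rng.gamma(k, scale, size=shape)
        rate = self.params[0]
        return rng.poisson(rate, size=shape).astype(float)


@dataclass(frozen=True)
class DEBlock:
    """A block of DE rows: large-group samples follow ``distribution``."""

    n_rows: int
    distribution: Distribution

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError("a DE block needs at least one row")


@dataclass(frozen=True)
class SimulationSpec:
    """Full parameterization of one synthetic study."""

    study_id: str
    n_features: int
    n_small: int
    n_large: int
    size_small_range: tuple[float, float] = (1.0, 2.9)
    size_large_range: tuple[float, float] = (BOUNDARY_CM, 5.0)
    de_blocks: tuple[DEBlock, ...] = ()
    background: Distribution = Distribution("normal", (0.0, 1.0))
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "de_blocks", tuple(self.de_blocks))
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_small < 1 or self.n_large < 1:
            raise ValueError("both sample groups must be non-empty")
        lo_s, hi_s = self.size_small_range
        lo_l, hi_l = self.size_large_range
        if not (0 < lo_s < hi_s <= lo_l < hi_l):
            raise ValueError(
                "size ranges must be positive, ordered and non-overlapping "
                "(small below large)"
            )
        if self.n_de_rows > self.n_features:
            raise ValueError("DE blocks exceed n_features")

    @property
    def n_de_rows(self) -> int:
        return sum(b.n_rows for b in self.de_blocks)

    @property
    def de_fraction(self) -> float:
        return self.n_de_rows / self.n_features


def simdat1_spec(seed: int = 0) -> SimulationSpec:
    """Normal-block preset: 55/45 samples, 70 % DE rows, N(3, 1) background."""
    return SimulationSpec(
        study_id="simdat1",
        n_features=10_000,
        n_small=55,
        n_large=45,
        de_blocks=(
            DEBlock(3500, Distribution("normal", (10.0, 10.0))),
            DEBlock(3500, Distribution("normal", (-2.0, 10.0))),
        ),
        background=Distribution("normal", (3.0, 1.0)),
        seed=seed,
    )


def simdat2_spec(seed: int = 0) -> SimulationSpec:
    """Gamma-block preset: 35/45 samples, 65 % DE rows, N(0.5, 10) background."""
    return SimulationSpec(
        study_id="simdat2",
        n_features=10_000,
        n_small=35,
        n_large=45,
        de_blocks=(
            DEBlock(2000, Distribution("gamma", (5.0, 10.0))),
            DEBlock(4500, Distribution("gamma", (3.0, 6.0))),
        ),
        background=Distribution("normal", (0.5, 10.0)),
        seed=seed,
    )


def simdat3_spec(seed: int = 0) -> SimulationSpec:
    """Poisson-block preset: 120/80 samples, 60 % DE rows, N(0.1, 20) background."""
    return SimulationSpec(
        study_id="simdat3",
        n_features=10_000,
        n_small=120,
        n_large=80,
        de_blocks=(
            DEBlock(2500, Distribution("poisson", (10.0,))),
            DEBlock(3500, Distribution("poisson", (8.0,))),
        ),
        background=Distribution("normal", (0.1, 20.0)),
        seed=seed,
    )


def preset_specs(seed: int = 0) -> tuple[SimulationSpec, SimulationSpec, SimulationSpec]:
    """The three presets with per-study seeds derived from one base seed."""
    seeds = np.random.SeedSequence(seed).generate_state(3, dtype=np.uint32) % (2**31)
    return (
        simdat1_spec(int(seeds[0])),
        simdat2_spec(int(seeds[1])),
        simdat3_spec(int(seeds[2])),
    )


def simulate_sizes(
    n_small: int,
    n_large: int,
    small_range: tuple[float, float] = (1.0, 2.9),
    large_range: tuple[float, float] = (BOUNDARY_CM, 5.0),
    seed: int = 0,
) -> np.ndarray:
    """Tumor sizes: n_small uniform draws on the small range, then n_large on the large."""
    if n_small < 1 or n_large < 1:
        raise ValueError("both groups need at least one sample")
    rng = np.random.default_rng(seed)
    small = rng.uniform(small_range[0], small_range[1], size=n_small)
    large = rng.uniform(large_range[0], large_range[1], size=n_large)
    return np.concatenate([small, large])


def simulate_dataset(spec: SimulationSpec) -> ExpressionStudy:
    """Draw one synthetic study from its spec.

    Rows are laid out DE blocks first, background rows last; the DE signal
    lives only in the large-group columns of the block rows, with the
    small-group columns of those rows (and every other cell) drawn from the
    background distribution.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = simulate_sizes(
        spec.n_small,
        spec.n_large,
        spec.size_small_range,
        spec.size_large_range,
        seed=int(rng.integers(2**31)),
    )
    n = spec.n_small + spec.n_large
    large_cols = np.arange(n) >= spec.n_small

    X = spec.background.sample(rng, (spec.n_features, n))
    row = 0
    for block in spec.de_blocks:
        X[row : row + block.n_rows, large_cols] = block.distribution.sample(
            rng, (block.n_rows, spec.n_large)
        )
        row += block.n_rows

    width = len(str(spec.n_features))
    feature_ids = [f"g{i + 1:0{width}d}" for i in range(spec.n_features)]
    sample_ids = [f"{spec.study_id}_s{j + 1:03d}" for j in range(n)]
    return ExpressionStudy(X, feature_ids, sample_ids, sizes, spec.study_id)


def simulate_collection(seed: int = 0, specs: Sequence[SimulationSpec] | None = None) -> StudyCollection:
    """Generate the three-preset study collection (or any list of specs).

    The presets share one feature-id vocabulary of equal length, so no
    feature matching is needed; an explicit spec list is honored as given.
    """
    if specs is None:
        specs = preset_specs(seed)
    return StudyCollection(tuple(simulate_dataset(s) for s in specs))


def rescale_de_blocks(spec: SimulationSpec, fraction: float) -> SimulationSpec:
    """Rescale a spec's DE blocks so they total ``fraction`` of all features.

    Block proportions are preserved with largest-remainder rounding; block
    distributions, sample layout and size ranges are untouched.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    total = int(round(fraction * spec.n_features))
    raw = [total * b.n_rows / spec.n_de_rows for b in spec.de_blocks]
    counts = [int(np.floor(r)) for r in raw]
    remainders = np.argsort([c - r for c, r in zip(counts, raw)], kind="stable")
    for idx in remainders[: total - sum(counts)]:
        counts[idx] += 1
    if any(c < 1 for c in counts):
        raise ValueError(
            f"fraction {fraction:g} leaves an empty DE block in {spec.study_id!r}"
        )
    blocks = tuple(DEBlock(c, b.distribution) for c, b in zip(counts, spec.de_blocks))
    return replace(spec, de_blocks=blocks)


def simulate_de_fraction_suite(
    base_specs: Sequence[SimulationSpec],
    fraction: float,
    seed: int = 0,
) -> list[ExpressionStudy]:
    """Regenerate each spec with its DE blocks rescaled to a total DE fraction."""
    seeds = np.random.SeedSequence(seed).generate_state(
        len(base_specs), dtype=np.uint32
    ) % (2**31)
    return [
        simulate_dataset(replace(rescale_de_blocks(spec, fraction), seed=int(s)))
        for spec, s in zip(base_specs, seeds)
    ]
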