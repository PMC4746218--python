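"""Shared fixtures: small deterministic studies built in memory."""

import numpy as np
import pytest

from tcut.core import ExpressionStudy, StudyCollection
from tcut.simulate import DEBlock, Distribution, SimulationSpec, simulate_dataset


def make_study(
    n_features: int = 20,
    n_small: int = 5,
    n_large: int = 5,
    n_de: int = 8,
    effect: float = 4.0,
    seed: int = 0,
    study_id: str = "toy",
) -> ExpressionStudy:
    """Small study with the first ``n_de`` rows shifted by ``effect`` in the large group."""
    rng = np.random.default_rng(seed)
    n = n_small + n_large
    X = rng.normal(0.0, 1.0, size=(n_features, n))
    X[:n_de, n_small:] += effect
    sizes = np.concatenate(
        [rng.uniform(1.0, 2.9, n_small), rng.uniform(3.0, 5.0, n_large)]
    )
    return ExpressionStudy(
        X,
        [f"g{i:03d}" for i in range(n_features)],
        [f"s{j:02d}" for j in range(n)],
        sizes,
        study_id,
    )


@pytest.fixture
def toy_study() -> ExpressionStudy:
    return make_study()


@pytest.fixture
def toy_collection() -> StudyCollection:
    return StudyCollection(
        tuple(make_study(seed=s, study_id=f"toy{s}") for s in (1, 2))
    )


def tiny_sim_specs(seed: int = 0, n_features: int = 400):
    """Scaled-down versions of the three presets (same block proportions)."""
    from tcut.simulate import preset_specs

    scaled = []
    for spec in preset_specs(seed):
        factor = spec.n_features // n_features
        blocks = tuple(
            DEBlock(max(b.n_rows // factor, 1), b.distribution) for b in spec.de_blocks
        )
        scaled.append(
            SimulationSpec(
                study_id=spec.study_id,
                n_features=n_features,
                n_small=spec.n_small,
                n_large=spec.n_large,
                de_blocks=blocks,
                background=spec.background,
                seed=spec.seed,
            )
        )
    return scaled


@pytest.fixture
def tiny_sim_collection() -> StudyCollection:
    return StudyCollection(tuple(simulate_dataset(s) for s in tiny_sim_specs(7)))
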