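import numpy as np
import pytest

from icudce.config import AttributeSpec, default_attributes
from icudce.design import generate_design, inject_quality_tasks
from icudce.synthetic import (
    PreferenceClassSpec,
    default_population,
    pooled_beta,
)


@pytest.fixture(scope="session")
def attributes():
    return default_attributes()


@pytest.fixture(scope="session")
def toy_attributes():
    return [
        AttributeSpec("size", "Size", ("small", "large"), "small", ordinal=True),
        AttributeSpec("speed", "Speed", ("slow", "medium", "fast"), "slow", ordinal=True),
        AttributeSpec("colour", "Colour", ("red", "blue"), "red", ordinal=False),
    ]


@pytest.fixture(scope="session")
def study_design(attributes):
    """Seeded study-default design: 24 standard tasks in 2 blocks + quality tasks."""
    design = generate_design(attributes, n_tasks=24, n_blocks=2, n_sweeps=3, seed=1)
    return inject_quality_tasks(design, seed=1)


@pytest.fixture(scope="session")
def population(attributes):
    return default_population(attributes)


@pytest.fixture(scope="session")
def pooled(population):
    return pooled_beta(population)


@pytest.fixture(scope="session")
def single_class_population(pooled):
    """Two identical classes: a one-preference population with valid shares."""
    return [
        PreferenceClassSpec("a", 0.5, pooled),
        PreferenceClassSpec("b", 0.5, pooled),
    ]
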