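"""Shared fixtures: small seeded datasets reused across test modules."""

import numpy as np
import pytest

from relbench.datasets import (
    EnclosureConfig,
    build_enclosure_train,
    build_more_fewer,
    build_same_different_train,
)


@pytest.fixture(scope="session")
def sd_small():
    """Small same-different corpus (20 shapes, 30 per class)."""
    return build_same_different_train(n_shapes=20, n_per_class=30, seed=101)


@pytest.fixture(scope="session")
def enclosure_small():
    """Small enclosure corpus (8 per class, full 22-fragment clutter)."""
    return build_enclosure_train(EnclosureConfig(n_per_class=8), seed=202)


@pytest.fixture(scope="session")
def more_fewer_small():
    return build_more_fewer(n_per_class=30, seed=303)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
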