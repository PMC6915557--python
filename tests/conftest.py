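"""Shared fixtures: synthetic images are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from plateletquant.pipeline import analyze
from plateletquant.synthetic import FixtureSpec, fixture_suite, generate, rim_only_spec


@pytest.fixture(scope="session")
def dense_fixture():
    """A misaligned channel densely covered with aggregates."""
    return generate(FixtureSpec(seed=7, true_alpha_deg=2.0))


@pytest.fixture(scope="session")
def dense_result(dense_fixture):
    """Full pipeline output on the dense fixture (automatic alignment)."""
    return analyze(dense_fixture.image)


@pytest.fixture(scope="session")
def sparse_fixture():
    """An almost-empty channel: three small aggregates."""
    return generate(
        FixtureSpec(
            seed=11,
            true_alpha_deg=-1.2,
            n_aggregates=3,
            aggregate_area_um2_range=(25.0, 64.0),
        ),
        condition="untreated",
    )


@pytest.fixture(scope="session")
def empty_fixture():
    """Pure background plus walls: no aggregates anywhere."""
    return generate(FixtureSpec(seed=5, n_aggregates=0), condition="untreated")


@pytest.fixture(scope="session")
def rim_fixture():
    """All aggregates confined to the 50 um near-wall rim."""
    return generate(rim_only_spec(seed=3))


@pytest.fixture(scope="session")
def validation_suite():
    """The 10-image validation suite (5 untreated + 5 activated)."""
    return fixture_suite(n_images=10, base_seed=1, condition_mix=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
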