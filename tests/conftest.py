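"""Shared fixtures: small phantom specs sized for fast, exact checks."""

from __future__ import annotations

import numpy as np
import pytest

from alfa.phantoms import PhantomSpec, make_cohort, make_template


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A 32^3 head phantom: quick to warp, register and fuse."""
    return PhantomSpec(shape=(32, 32, 32), brain_axes=(10.0, 8.0, 9.0),
                       skull_thickness=2.0, scalp_thickness=2.0,
                       noise_sigma=2.0, deform_amplitude=1.5,
                       deform_scale=5.0, seed=42)


@pytest.fixture(scope="session")
def standard_spec() -> PhantomSpec:
    """The 64^3 cohort conditions used for end-to-end experiments."""
    return PhantomSpec(noise_sigma=2.0, deform_amplitude=2.5, seed=100)


@pytest.fixture(scope="session")
def small_template(small_spec):
    return make_template(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return make_cohort(small_spec, 4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
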