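"""Shared fixtures.

Small, fast synthetic configurations for unit tests, plus one
session-scoped study engine (the full replica configuration) shared by the
acceptance-level tests so PSF records, forward models and Gram matrices are
built once.
"""

import numpy as np
import pytest

from sparsebeam import (
    PA,
    SourceSet,
    StudyEngine,
    make_grid,
    make_linear_probe,
    make_pulse,
    select_elements,
    synthesize_rf,
)


@pytest.fixture(scope="session")
def probe128():
    return make_linear_probe(128, 100e-6)


@pytest.fixture(scope="session")
def small_probe():
    """16 elements, 100 µm pitch — big enough aperture for beamforming
    tests, small enough to keep matrices tiny."""
    return make_linear_probe(16, 100e-6)


@pytest.fixture(scope="session")
def pulse():
    return make_pulse(15e6, 0.93, 62.5e6)


@pytest.fixture(scope="session")
def small_grid():
    """5 × 5 grid, 12.5 µm step, centred on (0, 5 mm)."""
    return make_grid(-25e-6, 25e-6, 5e-3 - 25e-6, 5e-3 + 25e-6, 12.5e-6)


@pytest.fixture(scope="session")
def small_scene_rf(small_probe, pulse):
    subset = select_elements(small_probe, 16, "all")
    sources = SourceSet(positions=[(0.0, 5e-3)], amplitudes=[1.0])
    return synthesize_rf(sources, small_probe, subset, pulse, PA, 1500.0)


@pytest.fixture(scope="session")
def engine():
    """Replica-configuration study engine shared across acceptance tests."""
    return StudyEngine()
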