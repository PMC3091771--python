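from __future__ import annotations

import numpy as np
import pytest

from imprintcons.pipeline import run_analysis_on_bundle
from imprintcons.synthetic_data import (
    SyntheticGenomeConfig,
    generate,
    study_shaped_fixture,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A default-condition synthetic genome (200 genes, 2 chromosomes)."""
    return generate(SyntheticGenomeConfig(seed=7))


@pytest.fixture(scope="session")
def small_result(small_bundle):
    return run_analysis_on_bundle(small_bundle)


@pytest.fixture(scope="session")
def study_bundle():
    """58 labelled genes (28 maternal + 30 paternal) vs 1000 autosomal."""
    return study_shaped_fixture()


@pytest.fixture(scope="session")
def study_result(study_bundle):
    return run_analysis_on_bundle(study_bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(20101122)
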