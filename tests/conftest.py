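"""Shared fixtures: expensive objects (JTT model, simulated family, fitted
reconstructions) are built once per session."""

import numpy as np
import pytest

from nitromet import AncestralReconstruction, jtt
from nitromet.simulate import FamilySpec, generate_family


@pytest.fixture(scope="session")
def model():
    return jtt()


@pytest.fixture(scope="session")
def family():
    """Default synthetic family (seed 1): alignment, truth, newick."""
    return generate_family(FamilySpec(seed=1))


@pytest.fixture(scope="session")
def family_asr(family, model):
    alignment, truth, newick = family
    return AncestralReconstruction(newick, alignment, model).fit()


@pytest.fixture(scope="session")
def active_site_alignment(family):
    alignment, truth, _ = family
    return alignment.take_columns(truth.site_columns)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
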