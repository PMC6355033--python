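"""Session-scoped fixtures: default toy landscape, its MSM and kinetics."""

from __future__ import annotations

import pytest

from chromwalk.msm import kinetic_matrices
from chromwalk.toy import ToyLandscapeSpec, generate_hierarchical_profile, toy_msm

TOY_BETA = 10.0


@pytest.fixture(scope="session")
def toy_profile():
    """Default three-level toy chromosome (N=500, branching 2/3/3)."""
    return generate_hierarchical_profile(ToyLandscapeSpec())


@pytest.fixture(scope="session")
def toy_model(toy_profile):
    """MSM of the default toy chromosome at beta = 10."""
    return toy_msm(toy_profile, beta=TOY_BETA)


@pytest.fixture(scope="session")
def toy_kinetics(toy_model):
    """MFPT / MRT / pairwise committor of the beta=10 toy MSM."""
    return kinetic_matrices(toy_model)
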