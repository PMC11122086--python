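"""Shared fixtures: desk-scale phantom data generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from mriqa import phantom, pipeline


@pytest.fixture(scope="session")
def textured_slice() -> np.ndarray:
    """A clean 192x192 phantom slice with tissue structure and texture."""
    spec = phantom.default_breast_spec(shape=(8, 192, 192), seed=42)
    return phantom.make_volume(spec).slices[4].pixels


@pytest.fixture(scope="session")
def clean_volume():
    """A 30-slice clean phantom volume (timepoint 0 of the default study)."""
    spec = phantom.default_breast_spec(seed=0)
    return phantom.make_volume(spec)


@pytest.fixture(scope="session")
def blurred_study():
    """The feasibility experiment: 7 phases, 7x7 blur injected at phases 3 and 5."""
    spec = phantom.default_breast_spec(
        degradations={3: ("blur", 7), 5: ("blur", 7)}, seed=0)
    return phantom.make_dce_study(spec)


@pytest.fixture(scope="session")
def blurred_study_profiles(blurred_study):
    """NR and FR profiles of the blurred study (computed once per session)."""
    return pipeline.assess_dynamic(blurred_study)
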