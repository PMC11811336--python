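"""Shared fixtures: tiny synthetic cases and cohorts, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from gazemap.synthetic_data import SessionProfile, generate_slide, plan_session


@pytest.fixture(scope="session")
def small_case():
    """One 384x384 synthetic case with two lesions."""
    return generate_slide(384, 384, n_lesions=2, seed=11)


@pytest.fixture(scope="session")
def clean_profile():
    """Session profile with no distractor visits and no diagnosis errors."""
    return SessionProfile(distractor_visit_prob=0.0, diagnosis_error_prob=0.0)


@pytest.fixture(scope="session")
def small_session(small_case, clean_profile):
    """A planned session over the small case (with planted-behavior truth)."""
    return plan_session(small_case, clean_profile, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
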