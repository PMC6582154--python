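"""Shared fixtures: small seeded simulations used across test modules."""

import pytest

from skimgt.pipeline import run_study, study_config


@pytest.fixture(scope="session")
def small_study():
    """A small but fully featured two-platform DH study (fixed seed)."""
    cfg = study_config(n_loci=1200, seed=11)
    return run_study(cfg)


@pytest.fixture(scope="session")
def small_config():
    return study_config(n_loci=1200, seed=11)
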