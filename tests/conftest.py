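"""Shared fixtures: one full synthetic bundle per session, plus small
hand-built objects."""

from __future__ import annotations

import numpy as np
import pytest

from photoclose.simulate import SimConfig, simulate_dataset

SESSION_SEED = 1


@pytest.fixture(scope="session")
def bundle():
    """Full synthetic study at default (study) conditions."""
    return simulate_dataset(SimConfig(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def small_bundle():
    """A fast, small bundle for I/O and smoke tests."""
    cfg = SimConfig(
        seed=7,
        genome_length=1_000_000,
        n_chromosomes=2,
        peak_counts={"shared_PR": 60, "rod_specific": 8, "cone_specific": 20, "non_PR": 12},
        closed_domain_spans=[(100_000, 1)],
        n_genes=60,
        cre_n_constructs=40,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
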