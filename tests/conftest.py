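"""Shared fixtures: small synthetic datasets and one reusable MCMC fit."""

import numpy as np
import pytest

from famix import (
    CCSet,
    ConsumerDataset,
    FAProfile,
    FattyAcidMixingModel,
    SourceSummary,
    apply_ccs,
    simulate_consumers_from_summary,
)

FA3 = ["16:1n-7", "20:5n-3", "22:6n-3"]


@pytest.fixture
def unit_cc():
    return CCSet(FA3, np.ones(3))


@pytest.fixture
def prey_sources():
    return [
        SourceSummary("krill", FA3, [30.0, 8.0, 12.0], [3.0, 1.0, 2.0]),
        SourceSummary("herring", FA3, [6.0, 25.0, 15.0], [2.0, 3.0, 2.0]),
    ]


@pytest.fixture
def predator_sources(prey_sources, unit_cc):
    return apply_ccs(prey_sources, unit_cc)


@pytest.fixture
def mixed_consumers(predator_sources):
    """Eight consumers at an exact 60/40 krill/herring tissue mixture."""
    w = np.array([0.6, 0.4])
    mu = np.column_stack([s.means for s in predator_sources]) @ w
    sd = np.column_stack([s.sds for s in predator_sources]) @ w
    return simulate_consumers_from_summary(mu, sd, n=8, seed=1234, fa_names=FA3)


@pytest.fixture(scope="session")
def toy_fit():
    """One moderately long 2-source fit shared by results-inspection tests."""
    sources = [
        SourceSummary("krill", FA3, [30.0, 8.0, 12.0], [3.0, 1.0, 2.0]),
        SourceSummary("herring", FA3, [6.0, 25.0, 15.0], [2.0, 3.0, 2.0]),
    ]
    pred = apply_ccs(sources, CCSet(FA3, np.ones(3)))
    w = np.array([0.6, 0.4])
    mu = np.column_stack([s.means for s in pred]) @ w
    sd = np.column_stack([s.sds for s in pred]) @ w
    cons = simulate_consumers_from_summary(mu, sd, n=8, seed=1234, fa_names=FA3)
    model = FattyAcidMixingModel(cons, pred)
    return model.fit(n_chains=3, n_iter=60_000, n_burnin=30_000, thin=20, seed=7)


def make_profiles(matrix, prefix="s"):
    matrix = np.asarray(matrix, dtype=float)
    fa = [f"FA{j + 1}" for j in range(matrix.shape[1])]
    return [
        FAProfile(fa, row, subject_id=f"{prefix}{i}") for i, row in enumerate(matrix)
    ]


@pytest.fixture
def profile_factory():
    return make_profiles
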