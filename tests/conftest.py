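import numpy as np
import pytest

import tractclust as tc


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    spec = tc.CohortSpec(seed=11)
    profiles, behaviour, truth = tc.generate_cohort(spec)
    return spec, profiles, behaviour, truth


@pytest.fixture(scope="session")
def residualized(default_cohort):
    _, profiles, _, _ = default_cohort
    return tc.residualize(profiles)


def planted_network(n_per=5, within=0.9, between=-0.5, noise=0.0, seed=0):
    """Two-block planted signed network used as a community-detection oracle."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    w = np.full((n, n), between)
    w[:n_per, :n_per] = within
    w[n_per:, n_per:] = within
    if noise:
        e = rng.normal(0, noise, (n, n))
        w = np.clip(w + (e + e.T) / 2, -1, 1)
    np.fill_diagonal(w, 0.0)
    return tc.SimilarityNetwork(ids=[f"p{i}" for i in range(n)], weights=w)


@pytest.fixture
def two_clique_net():
    return planted_network()
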