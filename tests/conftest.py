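import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from betacall import (
    PosteriorDraws,
    SimConfig,
    fit_mixture,
    select_training_snps,
    simulate_counts,
)

# Generative truth used across fitting/calling tests: ~60% hom-ref calls,
# het mean pulled below 0.5 by reference mapping bias with strong
# ASE overdispersion, near-deterministic homozygotes.
TRUTH_THETA = (0.6, 0.25, 0.15)
TRUTH_MU = (0.002, 0.48, 0.998)
TRUTH_KAPPA = (500.0, 20.0, 500.0)


def truth_config(n_sites=4000, depth=("poisson", 30.0), seed=11):
    return SimConfig(
        n_sites=n_sites,
        theta=TRUTH_THETA,
        mu=TRUTH_MU,
        kappa=TRUTH_KAPPA,
        depth=depth,
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One synthetic sample at the default study conditions."""
    return simulate_counts(truth_config())


@pytest.fixture(scope="session")
def default_fit(default_sim):
    """Full-budget fit (4 chains x 1000 kept after 1000 warmup) on 1000
    training SNPs with >= 10 reads; shared across tests that only need a
    converged posterior."""
    training = select_training_snps(default_sim.counts, 1000, 10, seed=21)
    return fit_mixture(training, seed=31)


@pytest.fixture()
def point_mass_draws():
    """Degenerate draws: every chain/iteration at the same parameter point,
    so Monte-Carlo averaging reduces to a single-draw Bayes rule."""
    mu = np.array([0.002, 0.5, 0.998])
    kappa = np.array([500.0, 20.0, 500.0])
    theta = np.array([1 / 3, 1 / 3, 1 / 3])
    shape = (2, 50, 3)
    return PosteriorDraws(
        theta=np.broadcast_to(theta, shape).copy(),
        mu=np.broadcast_to(mu, shape).copy(),
        kappa=np.broadcast_to(kappa, shape).copy(),
        n_warmup=0,
        seed=0,
    )
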