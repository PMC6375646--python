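import numpy as np
import pytest

import sortbind as sb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced simulated Sort-Seq experiment shared across inference tests.

    Short site and small library keep the MCMC tests fast; the full-scale
    (21 bp, 10^4 variants) recovery checks live in the acceptance tests.
    """
    cfg = sb.SimulationConfig(
        reference_seq="ACGTGACGTA", n_variants=3000, mutation_rate=0.15, seed=0
    )
    ds, truth = sb.simulate_experiment(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def small_posterior(small_experiment):
    ds, truth = small_experiment
    est = sb.EnergyMatrixMCMC(
        reference_seq=ds.reference_seq, n_iterations=2500, n_burnin=800,
        proposal_sd=0.2, random_state=0,
    ).fit(ds.codes, ds.bins, sample_weight=ds.counts)
    return est, ds, truth
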