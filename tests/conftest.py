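import pytest
from hypothesis import settings

from mtcsim.network import network_from_tables
from mtcsim.pipeline import SimulationConfig, run_experiment
from mtcsim.engine import MCMCConfig
from mtcsim.synthetic import GeneratorConfig, generate_skeleton

settings.register_profile("default", derandomize=True, max_examples=40)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_skeleton():
    """The emulated 12-treatment network skeleton (fixed seed)."""
    return generate_skeleton(GeneratorConfig(seed=0))


@pytest.fixture()
def tiny_network():
    """Two two-arm trials over treatments A, B with responses set."""
    return network_from_tables(
        [
            ("S1", [("A", 100, 57), ("B", 100, 60)]),
            ("S2", [("A", 80, 45), ("B", 80, 41)]),
        ]
    )


@pytest.fixture()
def symmetric_trial():
    """One perfectly symmetric two-arm trial: 57/100 responders per arm."""
    return network_from_tables([("S1", [("A", 100, 57), ("B", 100, 57)])])


# Desk-scale sampler: enough draws for stable posterior means/SDs on the
# small test networks while keeping the suite quick.
@pytest.fixture(scope="session")
def quick_mcmc():
    return MCMCConfig(chains=2, burn_in=1000, draws=2500, seed=11)


@pytest.fixture(scope="session")
def headline_summary():
    """Shared 100-replication null run on the default emulated network.

    This is the desk-scale version of the full Monte Carlo experiment:
    the 117-trial / 236-arm / 12-treatment skeleton, null response
    probability 0.57, alpha = 0.05, normal-approximation rule, with a
    half-length sampler per replication.  Session-scoped because several
    family-wise error checks interrogate the same run.
    """
    cfg = SimulationConfig(
        mcmc=MCMCConfig(chains=2, burn_in=2500, draws=5000),
        n_reps=100,
        master_seed=1,
    )
    return run_experiment(cfg)
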