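import pytest

from scampr import pooling, synthdata


@pytest.fixture(scope="session")
def canonical_design():
    return pooling.build_design(4, "canonical384")


@pytest.fixture(scope="session")
def recovery_sim(canonical_design):
    """The canonical recovery experiment: one 1,600 bp amplicon, 12 pools
    at 5,000x, error 5e-4, 10 planted mutations, 3 homeolog positions."""
    params = synthdata.SimParams(depth=5000, error_rate=5e-4, seed=42)
    amplicons = {"amp1": synthdata.random_amplicon(1600, seed=42)}
    truth = synthdata.simulate_population(
        amplicons, params, n_mutations=10, n_homeologs=3
    )
    counts = synthdata.simulate_pool_counts(truth, canonical_design, params)
    return truth, counts
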