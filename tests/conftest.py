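import pytest
from hypothesis import HealthCheck, settings

import epiconnect as ec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> ec.SimConfig:
    """A fast study: 300 proteins, 6 hubs, 30 terms, one planted link each."""
    return ec.SimConfig(
        n_proteins=300,
        n_replicates=4,
        n_chaperome=6,
        n_terms=30,
        term_size_range=(5, 20),
        hub_degree=40,
        min_planted_dc_interactors=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def study(small_config, tmp_path_factory):
    """A complete simulated study written to disk once per session."""
    out = tmp_path_factory.mktemp("study")
    return ec.simulate_study(small_config, out)


@pytest.fixture(scope="session")
def processed_dc(study, small_config):
    """Preprocessed matrix and DC table for the session study."""
    from epiconnect.preprocess import preprocess

    truth = study["truth"]
    processed = preprocess(study["matrix"], truth.design)
    table = ec.dc_table(processed, truth.design, "A", "B")
    return processed, table
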