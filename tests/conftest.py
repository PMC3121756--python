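import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_pair():
    """One simulated locus pair with truth, shared across tests (seed 11)."""
    from zeinhap.synthetic_data import SimulationConfig, simulate_locus_pair

    cfg = SimulationConfig(seed=11)
    hap_a, hap_b, truth = simulate_locus_pair(cfg)
    return cfg, hap_a, hap_b, truth
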