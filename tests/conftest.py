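import pytest

from hijackscan import ScanConfig, SimulationSpec, simulate_cohort


@pytest.fixture
def config():
    return ScanConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with all three event classes, shared read-only."""
    spec = SimulationSpec(n_samples=15, n_genes=40, n_hijack_events=2,
                          n_amplification_decoys=2, n_breakpoint_decoys=4,
                          rng_seed=7)
    return simulate_cohort(spec)
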