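import pytest

from macall import SimulationConfig, build_catalog, generate_reference, simulate


@pytest.fixture(scope="session")
def study_catalog():
    """Catalog reconstructed from the published study's marginal totals."""
    return build_catalog()


@pytest.fixture(scope="session")
def small_genome():
    return generate_reference(6000, 0.5, 0.5, seed=11)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset shared across calling/IO tests."""
    cfg = SimulationConfig(
        n_lines=6,
        genome_length=20_000,
        coverage_mean=80,
        error_rate=0.005,
        n_bps=15,
        n_insertions=4,
        n_deletions=4,
        generations=200,
        seed=42,
    )
    return simulate(cfg)
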