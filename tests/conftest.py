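import pytest

from mksubloc import WorldConfig, generate_world


@pytest.fixture(scope="session")
def micro_world():
    """2-class, 10-protein world for cheap unit tests."""
    config = WorldConfig(
        n_classes=2, n_proteins=10, seed=5, multiplex_fractions={2: 0.2}
    )
    return generate_world(config)


@pytest.fixture(scope="session")
def tiny_world():
    """3-class, 40-protein world exercising multiplex structure."""
    return generate_world(
        WorldConfig(
            n_classes=3, n_proteins=40, seed=3,
            multiplex_fractions={2: 0.15, 3: 0.05},
        )
    )


@pytest.fixture(scope="session")
def default_world():
    """The standard benchmark conditions (600 proteins, 6 classes), seed 7."""
    return generate_world(WorldConfig(seed=7))
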