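import pytest

from scvarmap import SimulationConfig


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Scaled-down cohort for fast unit tests."""
    return SimulationConfig(
        seed=7,
        n_cells_per_group={
            "tumor": 120,
            "panin": 80,
            "adm": 40,
            "normal_duct": 80,
            "acinar": 40,
        },
        n_variants=8,
        n_genes=300,
        n_clusters=3,
        program_size=30,
        n_call_records=300,
    )


@pytest.fixture(scope="session")
def small_obs(small_cfg):
    from scvarmap import simulate_read_observations

    return simulate_read_observations(small_cfg)
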