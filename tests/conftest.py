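"""Shared fixtures: a tiny simulated run reused across test modules."""

import pytest

from coipipe.simdata import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """8 species, 2 sites, modest coverage — fast enough for unit tests."""
    return SimulationConfig(
        seed=11, n_families=2, n_genera_per_family=2, n_species_per_genus=2,
        n_sites=2, specimens_per_site=6, coverage_mean=40.0,
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_config):
    return simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def clean_config(tiny_config):
    """Same community, error-free reads."""
    from dataclasses import replace

    return replace(tiny_config, sub_rate=0.0, ins_rate=0.0, del_rate=0.0)


@pytest.fixture(scope="session")
def clean_run(clean_config):
    return simulate_dataset(clean_config)
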