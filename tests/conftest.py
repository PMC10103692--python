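import pytest

import linetester as lt


@pytest.fixture(scope="session")
def design():
    return lt.RICE_DESIGN


@pytest.fixture(scope="session")
def means():
    """Packaged genotype x trait mean table (31 entries, 10 traits, 2 conditions)."""
    return lt.load_fixture("table3_means")


@pytest.fixture(scope="session")
def ms_sets():
    """Packaged mean-square sets keyed by (trait, condition)."""
    return lt.load_fixture("table2_ms")


@pytest.fixture(scope="session")
def table7():
    return lt.load_fixture("table7_params").set_index(["trait", "condition", "parameter"])[
        "value"
    ]


@pytest.fixture(scope="session")
def sim_trial():
    """One deterministic simulated single-trait trial at the rice design size."""
    config = lt.single_trait_config(
        seed=42,
        sigma2_block=1.0,
        sigma2_gca_line=25.0,
        sigma2_gca_tester=25.0,
        sigma2_sca=10.0,
        sigma2_error=1.0,
    )
    plots, truth = lt.simulate_trial(config)
    return config, plots, truth
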