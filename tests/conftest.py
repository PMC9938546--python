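import pytest

from immunoscreen import (
    CompoundEffect,
    SimulationConfig,
    make_control_layout,
    make_screen_layout,
    simulate_plateset,
)

THREE_DONORS = ("D1", "D2", "D3")


@pytest.fixture(scope="session")
def toy_effects():
    """Three mechanistically distinct compounds for small screens."""
    return {
        "cytotox": CompoundEffect("cytotox", d_max=0.03, ec50_direct=2.0),
        "potentiator": CompoundEffect("potentiator", p_max=3.0, ec50_pot=1.0),
        "inert": CompoundEffect("inert"),
    }


@pytest.fixture(scope="session")
def toy_layout():
    return make_screen_layout(
        n_compounds=3,
        n_controls=4,
        compound_ids=["cytotox", "inert", "potentiator"],
    )


@pytest.fixture(scope="session")
def noisefree_plates(toy_layout, toy_effects):
    """Deterministic noise-free screen of the three toy compounds."""
    config = SimulationConfig(seed=11, noise_cv=0.0)
    return simulate_plateset(config, toy_layout, toy_effects)


@pytest.fixture(scope="session")
def noisy_plates(toy_layout, toy_effects):
    config = SimulationConfig(seed=11, noise_cv=0.05)
    return simulate_plateset(config, toy_layout, toy_effects)


@pytest.fixture(scope="session")
def qc_plates():
    """Default QC control scenario: 64 untreated wells per culture group."""
    config = SimulationConfig(seed=1, noise_cv=0.05)
    return simulate_plateset(config, make_control_layout(64))
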