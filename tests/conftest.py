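import pytest

from sgeintegrate import (
    FunctionalGMM,
    SimulationConfig,
    VarCallModel,
    rescale_assay,
    simulate_screen,
)


@pytest.fixture(scope="session")
def screen500():
    """Default well-separated 500-variant two-assay screen."""
    return simulate_screen(SimulationConfig(n_variants=500, seed=7))


@pytest.fixture(scope="session")
def harmonized500(screen500):
    variants, scores, _ = screen500
    return rescale_assay(scores, variants)


@pytest.fixture(scope="session")
def varcall500(screen500, harmonized500):
    variants, _, _ = screen500
    return VarCallModel(seed=20260409).fit(harmonized500, variants)


@pytest.fixture(scope="session")
def gmm500(screen500, harmonized500):
    variants, _, _ = screen500
    return FunctionalGMM(seed=7).fit(harmonized500, variants)


@pytest.fixture()
def small_screen():
    """Cheap 150-variant screen for tests that refit models."""
    return simulate_screen(SimulationConfig(n_variants=150, seed=21))
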