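import pytest

from tdrsim import (
    ScannerConstraints,
    generate_directions,
    optimise,
    preset_substrates,
)


@pytest.fixture(scope="session")
def dirs60():
    """The default 60-direction repulsion set used throughout."""
    return generate_directions(60, seed=1234).vectors


@pytest.fixture(scope="session")
def substrates():
    return preset_substrates()


@pytest.fixture(scope="session")
def preclinical_optimum(substrates):
    """Optimised shell pair for large cylinders, b=8, G<600 mT/m, Δ+δ<45 ms."""
    return optimise(substrates["large_cylinders"], ScannerConstraints(600.0, 45.0), b=8.0)
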