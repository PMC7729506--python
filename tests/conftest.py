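import pytest

from tagphase import CalibrationInput, GEParams, calibrate


@pytest.fixture(scope="session")
def trilaurin() -> GEParams:
    """Trilaurin (LLL) parameters calibrated from the measured latent heat."""
    return calibrate(CalibrationInput())


@pytest.fixture(scope="session")
def toy_discontinuous() -> GEParams:
    """Small discontinuous model (T* = 150 K < Tc = 200 K) with fast MC dynamics."""
    return GEParams(J=50.0, H0=150.0, ln_deg=2.0, z=4)


@pytest.fixture(scope="session")
def toy_crossover() -> GEParams:
    """Crossover model (T* = 300 K > Tc = 200 K): no metastability."""
    return GEParams(J=50.0, H0=300.0, ln_deg=2.0, z=4)
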