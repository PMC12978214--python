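import numpy as np
import pytest

from icenuc import (
    AssayDesign,
    NucleationSurface,
    SubpopulationMixture,
    ThermoModel,
    calibrate,
)

MONOMER_WIDTH = 3.4e-9
EN_LENGTH = 19e-9
MO_LENGTH = 25.3e-9
TRIMER_MODE_C = -7.5  # observed freezing mode attributed to trimers


@pytest.fixture(scope="session")
def three_mode_mixture() -> SubpopulationMixture:
    """Three equally weighted subpopulations 0.9-1.0 degC apart."""
    return SubpopulationMixture(
        weights=[1 / 3, 1 / 3, 1 / 3],
        modes=[-5.6, -6.5, -7.5],
        spreads=[0.3, 0.3, 0.3],
        n_tot=1e5,
    )


@pytest.fixture(scope="session")
def default_design() -> AssayDesign:
    return AssayDesign(n_dilutions=5)


@pytest.fixture(scope="session")
def clean_design() -> AssayDesign:
    """Sampling structure the spectrum inversion assumes: no background,
    no instrument temperature noise."""
    return AssayDesign(n_dilutions=5, background_enabled=False, temp_noise_sd=0.0)


@pytest.fixture(scope="session")
def en_trimer() -> NucleationSurface:
    return NucleationSurface(monomer_length=EN_LENGTH, n_monomers=3)


@pytest.fixture(scope="session")
def calibrated_thermo(en_trimer) -> ThermoModel:
    """Interfacial energy scale calibrated so the trimer freezes at -7.5 degC."""
    return calibrate(en_trimer, TRIMER_MODE_C, ThermoModel())
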