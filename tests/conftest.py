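import numpy as np
import pytest

from ctcspectro import data_path
from ctcspectro.characterization import load_charge_table
from ctcspectro.synth import EquilibriumSystem


@pytest.fixture(scope="session")
def cla_system() -> EquilibriumSystem:
    """Donor/chloranilic-acid equilibrium with the bundled scenario's
    association constant and molar absorptivity."""
    return EquilibriumSystem(
        K=147.0, epsilon=1.29e4, path=1.0, acceptor_total=4.79e-3
    )


@pytest.fixture(scope="session")
def cla_donor_concs() -> np.ndarray:
    """Donor span of the bundled titration scenario (mol/L)."""
    return np.array([3.67e-5, 5.5e-5, 7.3e-5, 9.1e-5, 1.06e-4, 1.22e-4])


@pytest.fixture(scope="session")
def rux_charges():
    return load_charge_table(data_path("rux_partial_charges.csv"))


@pytest.fixture(scope="session")
def tauc_grid() -> np.ndarray:
    return np.arange(1.5, 3.5 + 1e-9, 0.01)
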