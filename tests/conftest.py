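import numpy as np
import pytest

from hemeqmc import AndersonModel, ImaginaryTimeGrid
from hemeqmc.constants import K_B


@pytest.fixture
def two_level_model():
    """1 host (eps=1) + 1 orbital (eps=-1), V=0.5, noninteracting."""
    return AndersonModel(host_energies=[1.0], impurity_energies=[-1.0],
                         hybridization=[[0.5]], U=0.0, J=0.0)


@pytest.fixture
def hubbard_dimer():
    """1 orbital + 1 host at the Fermi level, U=2: smallest correlated cluster."""
    return AndersonModel(host_energies=[0.3], impurity_energies=[-0.5],
                         hybridization=[[0.5]], U=1.0, J=0.0)


@pytest.fixture
def toy_interacting():
    """1 orbital + 2 symmetric hosts, U=2, particle-hole symmetric."""
    return AndersonModel(host_energies=[0.6, -0.6], impurity_energies=[-1.0],
                         hybridization=[[0.5], [0.5]], U=2.0, J=0.0)


def temperature_of_beta(beta: float) -> float:
    return 1.0 / (K_B * beta)


@pytest.fixture
def beta2_grid():
    return ImaginaryTimeGrid(beta=2.0, L=16)
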