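import numpy as np
import pytest

import gausspb as g


@pytest.fixture
def params():
    return g.GaussianParams(sigma=0.93, eps_in=2.0, eps_out=80.0)


@pytest.fixture
def born_ion():
    return g.single_ion(radius=2.0, charge=1.0)


@pytest.fixture
def small_grid():
    return g.GridSpec(origin=(-8.0, -8.0, -8.0), spacing=1.0, shape=(17, 17, 17))


@pytest.fixture
def two_atom_structure():
    a = g.Atom(name="A1", position=(-2.0, 0.0, 0.0), radius=2.0, charge=1.0)
    b = g.Atom(name="A2", position=(2.0, 0.0, 0.0), radius=2.0, charge=-1.0)
    return g.Structure(atoms=[a, b], label="diatomic")


def coulomb_kt(q: float, eps: float, r: np.ndarray, temperature: float = 298.15) -> np.ndarray:
    """Analytic Coulomb potential in kT/e."""
    return g.KCOUL * q / (eps * np.asarray(r)) / g.kT_kcal(temperature)


def born_energy(q: float, radius: float, eps_in: float, eps_out: float) -> float:
    """Analytic Born solvation energy, kcal/mol."""
    return -g.KCOUL * q * q / (2.0 * radius) * (1.0 / eps_in - 1.0 / eps_out)
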