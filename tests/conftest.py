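import numpy as np
import pytest

from remass.builder import build_solute, build_toy_system
from remass.engine import minimize_energy


@pytest.fixture(scope="session")
def vacuum_solute():
    """22-atom capped-alanine-like solute, no solvent, no box."""
    top, coords = build_solute()
    return top, coords


@pytest.fixture(scope="session")
def small_solvated():
    """Solute + 20 rigid waters in a 10 Å cube, energy-minimised."""
    top, state = build_toy_system(20, box_edge=10.0, seed=11)
    state = minimize_energy(top, state)
    return top, state


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
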