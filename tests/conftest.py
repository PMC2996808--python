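"""Shared fixtures: all inputs are generated programmatically at test time."""

import warnings

import numpy as np
import pytest

import swarmdock as sd

warnings.filterwarnings("ignore", category=DeprecationWarning)


@pytest.fixture(scope="session")
def helix10():
    return sd.make_helix(10, seed=3)


@pytest.fixture(scope="session")
def helix10_modes(helix10):
    return sd.compute_modes(helix10)


@pytest.fixture(scope="session")
def hinge_mode_pair():
    """Hinge fixture whose bound form is unbound + 2 Å along exact mode 1."""
    return sd.make_hinge_pair(24, seed=1, mode_index=1, amplitude=2.0)


@pytest.fixture(scope="session")
def hinge_transition(hinge_mode_pair):
    return sd.make_transition(hinge_mode_pair.unbound, hinge_mode_pair.bound)


@pytest.fixture(scope="session")
def hinge_modes(hinge_mode_pair):
    return sd.compute_modes(hinge_mode_pair.unbound)


@pytest.fixture(scope="session")
def binding_pair():
    """Salt-bridge designed receptor/ligand pair (shared: generation is the
    most expensive fixture, ~30 s)."""
    return sd.make_binding_pair(seed=0)


@pytest.fixture(scope="session")
def nonbonded_table():
    return sd.load_params()


def two_atom_structure(coords, masses=(12.011, 12.011), names=("CA", "CA"),
                       res_names=("ALA", "ALA")):
    """Minimal hand-built structure for analytic oracles."""
    n = len(coords)
    return sd.Structure(
        serials=np.arange(1, n + 1),
        names=np.array(names[:n]),
        elements=np.array(["C"] * n),
        res_names=np.array(res_names[:n]),
        chain_ids=np.array(["A"] * n),
        res_seqnums=np.arange(1, n + 1),
        icodes=np.array([""] * n),
        coords=np.asarray(coords, dtype=float),
        masses=np.asarray(masses[:n], dtype=float),
        is_hetero=np.zeros(n, dtype=bool),
    )


@pytest.fixture
def make_tiny_structure():
    return two_atom_structure
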