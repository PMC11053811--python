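import numpy as np
import pytest

from demicell.forcefield import build_interaction_table
from demicell.system import BoxSpec, SystemState, assemble_system


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def default_table():
    return build_interaction_table()


@pytest.fixture
def strong_cargo_table():
    return build_interaction_table({"B-C": 1.4, "C-C": 1.4})


@pytest.fixture
def small_mixture():
    """Two linear chains plus one cargo trimer, deterministic seed."""
    return assemble_system({"A30B30": 2, "C3": 1}, 0.12, seed=42)


def make_state(positions, types, bonds=(), L=20.0, mol=None, species=None):
    """Hand-built SystemState for geometric unit tests."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    types = np.asarray(types, dtype=np.int8)
    bonds = (np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
             if len(bonds) else np.zeros((0, 2), dtype=np.int64))
    mol = np.asarray(mol if mol is not None else np.zeros(n), dtype=np.int64)
    n_mol = int(mol.max()) + 1 if n else 0
    species = list(species) if species is not None else ["A30B30"] * n_mol
    return SystemState(
        positions=np.mod(positions, L), velocities=np.zeros((n, 3)),
        images=np.zeros((n, 3), dtype=np.int64), types=types,
        bonds=bonds, bond_active=np.ones(len(bonds), dtype=bool),
        molecule_id=mol, mol_species=species,
        box=BoxSpec(phi=n / L ** 3, n_beads=n, length=L),
    )


@pytest.fixture
def state_factory():
    return make_state
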