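"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cdftfold.qm_io import ElectronicStructure
from cdftfold.structures import MolecularStructure

GLYCINE_PDB = """\
HEADER    TEST
ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER B   1       0.000   5.000   0.000  1.00  0.00           C
ATOM      4  CA  VAL B   2       3.800   5.000   0.000  1.00  0.00           C
END
"""


def ca_structure(coords, names=None) -> MolecularStructure:
    """CA-only structure, one residue per atom."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if names is None:
        names = ["GLY"] * n
    return MolecularStructure(
        elements=["C"] * n,
        coords=coords,
        atom_names=["CA"] * n,
        residue_index=np.arange(n),
        residue_names=list(names),
        residue_seq=[str(i + 1) for i in range(n)],
        residue_chain=["A"] * n,
    )


def point_structure(coords) -> MolecularStructure:
    """Generic heavy-atom structure, one residue per atom (for the
    condensed pairwise potentials)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return MolecularStructure(
        elements=["C"] * n,
        coords=coords,
        atom_names=[f"C{i+1}" for i in range(n)],
        residue_index=np.arange(n),
        residue_names=["UNK"] * n,
        residue_seq=[str(i + 1) for i in range(n)],
        residue_chain=["A"] * n,
    )


def es_from_energies(energies, occupations, coefficients=None,
                     ao_atom_map=None, overlap=None) -> ElectronicStructure:
    """Build an ElectronicStructure directly from MO data (identity
    coefficients by default: one AO per MO, one atom per AO)."""
    energies = np.asarray(energies, dtype=float)
    occupations = np.asarray(occupations, dtype=float)
    n = len(energies)
    if coefficients is None:
        coefficients = np.eye(n)
    coefficients = np.asarray(coefficients, dtype=float)
    if ao_atom_map is None:
        ao_atom_map = np.arange(coefficients.shape[0])
    return ElectronicStructure(
        mo_energies=energies,
        occupations=occupations,
        coefficients=coefficients,
        ao_atom_map=np.asarray(ao_atom_map),
        n_electrons=int(round(occupations.sum())),
        overlap=overlap,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
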