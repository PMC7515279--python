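"""Shared molecule fixtures built programmatically (no data files).

Geometries are idealised but exact where it matters: methyl hydrogens are
placed with threefold symmetry about the bond axis so united-atom centres
of mass fall exactly on the heavy-atom skeleton.
"""

import numpy as np
import pytest

from mccentropy.topology import AtomRecord, MolecularTopology

MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}


def _atom(i, el):
    return AtomRecord(index=i, element=el, mass=MASS[el])


def _methyl_hydrogens(carbon, axis, offset=0.36, radius=1.04, phase=0.0):
    """Three H with exact threefold symmetry about ``axis`` through carbon."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    perp1 = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp1) < 1e-8:
        perp1 = np.cross(axis, [0.0, 1.0, 0.0])
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(axis, perp1)
    out = []
    for k in range(3):
        ang = phase + 2.0 * np.pi * k / 3.0
        out.append(
            carbon - offset * axis + radius * (np.cos(ang) * perp1 + np.sin(ang) * perp2)
        )
    return out


def chain_alkane(n_carbons, **kwargs):
    """Linear alkane C_nH_{2n+2} topology (no reference geometry)."""
    atoms, bonds = [], []
    h_counts = [3] + [2] * (n_carbons - 2) + [3] if n_carbons > 1 else [4]
    idx = 0
    carbon_idx = []
    for c, nh in enumerate(h_counts):
        atoms.append(_atom(idx, "C"))
        carbon_idx.append(idx)
        idx += 1
        for _ in range(nh):
            atoms.append(_atom(idx, "H"))
            bonds.append((carbon_idx[-1], idx))
            idx += 1
        if c > 0:
            bonds.append((carbon_idx[-2], carbon_idx[-1]))
    return MolecularTopology.from_atoms(atoms, bonds, **kwargs)


def ring_molecule(n_heavy, h_per_heavy, include_ring_dihedrals=True, **kwargs):
    """Ring of CH_k united atoms (benzene: k=1, cyclohexane: k=2)."""
    atoms, bonds = [], []
    idx = 0
    heavy_idx = []
    for c in range(n_heavy):
        atoms.append(_atom(idx, "C"))
        heavy_idx.append(idx)
        idx += 1
        for _ in range(h_per_heavy):
            atoms.append(_atom(idx, "H"))
            bonds.append((heavy_idx[-1], idx))
            idx += 1
    for c in range(n_heavy):
        bonds.append((heavy_idx[c], heavy_idx[(c + 1) % n_heavy]))
    return MolecularTopology.from_atoms(
        atoms, bonds, include_ring_dihedrals=include_ring_dihedrals, **kwargs
    )


@pytest.fixture
def methane():
    atoms = [_atom(0, "C")] + [_atom(i, "H") for i in range(1, 5)]
    bonds = [(0, i) for i in range(1, 5)]
    return MolecularTopology.from_atoms(atoms, bonds)


@pytest.fixture
def ethane():
    return chain_alkane(2)


@pytest.fixture
def butane():
    return chain_alkane(4)


@pytest.fixture
def benzene():
    # rigid aromatic ring: ring dihedrals suppressed
    return ring_molecule(6, 1, include_ring_dihedrals=False)


@pytest.fixture
def cyclohexane():
    return ring_molecule(6, 2)


@pytest.fixture
def methanol():
    atoms = [
        _atom(0, "C"), _atom(1, "O"),
        _atom(2, "H"), _atom(3, "H"), _atom(4, "H"),  # on C
        _atom(5, "H"),  # on O
    ]
    bonds = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 5)]
    return MolecularTopology.from_atoms(atoms, bonds)


@pytest.fixture
def carbon_dioxide():
    atoms = [_atom(0, "O"), _atom(1, "C"), _atom(2, "O")]
    bonds = [(0, 1), (1, 2)]
    coords = np.array([[-1.16, 0.0, 0.0], [0.0, 0.0, 0.0], [1.16, 0.0, 0.0]])
    return MolecularTopology.from_atoms(atoms, bonds, reference_coordinates=coords)


@pytest.fixture
def acetonitrile():
    """CH3-C≡N with exact geometry: UA centres collinear on x."""
    c1 = np.array([0.0, 0.0, 0.0])
    atoms = [_atom(0, "C"), _atom(1, "C"), _atom(2, "N")]
    coords = [c1, np.array([1.46, 0.0, 0.0]), np.array([2.62, 0.0, 0.0])]
    bonds = [(0, 1), (1, 2)]
    for k, h in enumerate(_methyl_hydrogens(c1, [1.0, 0.0, 0.0])):
        atoms.append(_atom(3 + k, "H"))
        coords.append(h)
        bonds.append((0, 3 + k))
    return MolecularTopology.from_atoms(
        atoms, bonds, reference_coordinates=np.array(coords)
    )
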