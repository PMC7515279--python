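"""Two-level structural model of a molecule: united atoms over atoms.

A united atom (UA) is a heavy (non-hydrogen) atom together with its bonded
hydrogens, treated as a rigid body.  The rotational degrees of freedom of a
UA follow from its hydrogen count and geometry:

* no hydrogens        -> point body, 0 rotational dof
* one hydrogen        -> linear body (heavy->H axis), 2 rotational dof
* two or more         -> nonlinear body, 3 rotational dof, unless the
  hydrogens and heavy atom are collinear (then linear).

The molecule itself is classified as linear or nonlinear with respect to
its united-atom centres; a molecule of one or two united atoms is linear by
construction.  Degree-of-freedom bookkeeping between the molecule and
united-atom levels is handled by :func:`count_vibrational_modes`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, TopologyError

log = logging.getLogger(__name__)

#: maximum perpendicular deviation (Å) from the best-fit axis below which a
#: set of reference points is considered collinear
COLLINEARITY_TOL = 1e-2

ROTATION_NONLINEAR = "nonlinear"
ROTATION_LINEAR = "linear"
ROTATION_POINT = "point"

_ROT_DOF = {ROTATION_NONLINEAR: 3, ROTATION_LINEAR: 2, ROTATION_POINT: 0}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: 0-based index, element symbol and mass in g mol⁻¹."""

    index: int
    element: str
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise TopologyError(f"atom {self.index}: mass must be > 0, got {self.mass}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True)
class UnitedAtom:
    """A heavy atom plus its bonded hydrogens, treated as one rigid body."""

    heavy_atom: int
    hydrogens: tuple[int, ...]
    rotation_class: str
    mass: float

    @property
    def members(self) -> tuple[int, ...]:
        return (self.heavy_atom,) + self.hydrogens

    @property
    def rotational_dof(self) -> int:
        return _ROT_DOF[self.rotation_class]


@dataclass(frozen=True)
class ModeCount:
    """Vibrational mode bookkeeping for one molecule."""

    m_transvib: int
    m_rovib: int
    ua_transvib: int
    ua_rovib: int


def build_united_atoms(
    atoms: Sequence[AtomRecord],
    bonds: Iterable[tuple[int, int]],
    reference_coordinates: np.ndarray | None = None,
) -> list[UnitedAtom]:
    """Partition atoms into united atoms (heavy atom + bonded hydrogens).

    Each hydrogen must have exactly one bond, to a heavy atom.  If
    ``reference_coordinates`` are supplied, a UA whose heavy atom and ≥2
    hydrogens are collinear is downgraded from nonlinear to linear.
    """
    bonds = [tuple(b) for b in bonds]
    n = len(atoms)
    for i, j in bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise TopologyError(f"bond ({i},{j}) references invalid atom index")
        if atoms[i].is_hydrogen and atoms[j].is_hydrogen:
            raise TopologyError(f"hydrogen bonded to hydrogen: bond ({i},{j})")

    neighbours: dict[int, list[int]] = {a.index: [] for a in atoms}
    for i, j in bonds:
        neighbours[i].append(j)
        neighbours[j].append(i)

    uas: list[UnitedAtom] = []
    for atom in atoms:
        if atom.is_hydrogen:
            deg = len(neighbours[atom.index])
            if deg != 1:
                raise TopologyError(
                    f"hydrogen {atom.index} has {deg} bonds; expected exactly 1"
                )
            continue
        hydrogens = tuple(
            sorted(h for h in neighbours[atom.index] if atoms[h].is_hydrogen)
        )
        mass = atom.mass + sum(atoms[h].mass for h in hydrogens)
        if len(hydrogens) == 0:
            rot = ROTATION_POINT
        elif len(hydrogens) == 1:
            rot = ROTATION_LINEAR
        else:
            rot = ROTATION_NONLINEAR
            if reference_coordinates is not None:
                pts = reference_coordinates[[atom.index, *hydrogens]]
                if _is_collinear(pts):
                    rot = ROTATION_LINEAR
        uas.append(
            UnitedAtom(
                heavy_atom=atom.index, hydrogens=hydrogens, rotation_class=rot, mass=mass
            )
        )
    return uas


def _is_collinear(points: np.ndarray, tol: float = COLLINEARITY_TOL) -> bool:
    """True if every point lies within ``tol`` Å of the best-fit axis."""
    if len(points) <= 2:
        return True
    centred = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    perp = centred - np.outer(centred @ vt[0], vt[0])
    return float(np.abs(perp).max()) < tol and s[0] > 0


def molecule_linearity(
    ua_positions: np.ndarray, tol: float = COLLINEARITY_TOL
) -> bool:
    """Whether united-atom centres are collinear (≤2 centres are always linear)."""
    if len(ua_positions) <= 2:
        return True
    return _is_collinear(np.asarray(ua_positions, dtype=float), tol)


@dataclass
class MolecularTopology:
    """Structural model of one molecular species, replicated ``n_molecules`` times.

    ``dihedrals`` are ordered 4-tuples of united-atom indices forming simple
    bonded paths; ``symmetry_number`` is the external rotational symmetry of
    the united-atom skeleton (user input, defaults to 1).
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]]
    united_atoms: list[UnitedAtom]
    ua_bonds: list[tuple[int, int]]
    dihedrals: list[tuple[int, int, int, int]]
    molecule_linear: bool
    symmetry_number: int = 1
    n_molecules: int = 1
    #: masses per atom (derived)
    masses: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.symmetry_number < 1:
            raise TopologyError(f"symmetry number must be >= 1, got {self.symmetry_number}")
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)

    # -- derived sizes ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_united_atoms(self) -> int:
        return len(self.united_atoms)

    @property
    def n_dihedrals(self) -> int:
        return len(self.dihedrals)

    @property
    def molecular_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def rotational_dof(self) -> int:
        """Molecule-level rotational degrees of freedom.

        A single-UA molecule rotates as its one united atom does; otherwise
        linearity with respect to united atoms decides between 2 and 3.
        """
        if self.n_united_atoms == 1:
            return self.united_atoms[0].rotational_dof
        return 2 if self.molecule_linear else 3

    @classmethod
    def from_atoms(
        cls,
        atoms: Sequence[AtomRecord],
        bonds: Iterable[tuple[int, int]],
        *,
        symmetry_number: int = 1,
        n_molecules: int = 1,
        reference_coordinates: np.ndarray | None = None,
        include_ring_dihedrals: bool = True,
    ) -> "MolecularTopology":
        atoms = list(atoms)
        bonds = [tuple(sorted(b)) for b in bonds]
        uas = build_united_atoms(atoms, bonds, reference_coordinates)
        heavy_to_ua = {ua.heavy_atom: k for k, ua in enumerate(uas)}
        ua_bonds = sorted(
            {
                tuple(sorted((heavy_to_ua[i], heavy_to_ua[j])))
                for i, j in bonds
                if i in heavy_to_ua and j in heavy_to_ua
            }
        )
        dihedrals = find_ua_dihedrals(len(uas), ua_bonds, include_ring_dihedrals)
        if reference_coordinates is not None:
            ua_pos = np.array(
                [
                    np.average(
                        reference_coordinates[list(ua.members)],
                        axis=0,
                        weights=[atoms[m].mass for m in ua.members],
                    )
                    for ua in uas
                ]
            )
            linear = molecule_linearity(ua_pos)
        else:
            linear = len(uas) <= 2
        return cls(
            atoms=atoms,
            bonds=bonds,
            united_atoms=uas,
            ua_bonds=ua_bonds,
            dihedrals=dihedrals,
            molecule_linear=linear,
            symmetry_number=symmetry_number,
            n_molecules=n_molecules,
        )


def find_ua_dihedrals(
    n_ua: int,
    ua_bonds: Sequence[tuple[int, int]],
    include_ring_dihedrals: bool = True,
) -> list[tuple[int, int, int, int]]:
    """Enumerate dihedrals: simple paths of four consecutively bonded UAs.

    A path and its reverse count once.  With ``include_ring_dihedrals``
    False, any 4-path whose central bond is part of a cycle is dropped
    (appropriate for rigid rings such as aromatics).
    """
    adjacency: dict[int, set[int]] = {k: set() for k in range(n_ua)}
    for i, j in ua_bonds:
        adjacency[i].add(j)
        adjacency[j].add(i)

    ring_bonds: set[tuple[int, int]] = set()
    if not include_ring_dihedrals:
        ring_bonds = _bonds_in_cycles(n_ua, ua_bonds)

    dihedrals: set[tuple[int, int, int, int]] = set()
    for b, c in ua_bonds:
        for b_, c_ in ((b, c), (c, b)):
            if tuple(sorted((b_, c_))) in ring_bonds:
                continue
            for a in adjacency[b_] - {c_}:
                for d in adjacency[c_] - {b_, a}:
                    path = (a, b_, c_, d)
                    dihedrals.add(min(path, path[::-1]))
    return sorted(dihedrals)


def _bonds_in_cycles(
    n_ua: int, ua_bonds: Sequence[tuple[int, int]]
) -> set[tuple[int, int]]:
    """Bonds that lie on at least one cycle (removal keeps endpoints connected)."""
    in_cycle = set()
    for bond in ua_bonds:
        others = [b for b in ua_bonds if b != bond]
        adj: dict[int, set[int]] = {k: set() for k in range(n_ua)}
        for i, j in others:
            adj[i].add(j)
            adj[j].add(i)
        # BFS from one endpoint
        start, target = bond
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            if u == target:
                in_cycle.add(tuple(sorted(bond)))
                break
            for v in adj[u] - seen:
                seen.add(v)
                stack.append(v)
    return in_cycle


def count_vibrational_modes(topology: MolecularTopology) -> ModeCount:
    """Degree-of-freedom bookkeeping across the molecule and UA levels.

    Molecule translation always carries 3 modes; molecule rotation carries
    3, 2 or 0 depending on molecular shape.  United-atom translation
    carries 3N−6 modes for a nonlinear molecule of N united atoms (3N−5 if
    linear): the removed modes are whole-molecule translation and rotation,
    already counted above.  United-atom rotation carries the sum of per-UA
    rotational dof; for a single-UA molecule that rotation *is* the
    molecule rotation, so the UA level contributes nothing.
    """
    n = topology.n_united_atoms
    if n == 1:
        ua_trans = 0
        ua_rot = 0
    else:
        removed = 5 if topology.molecule_linear else 6
        ua_trans = max(0, 3 * n - removed)
        ua_rot = sum(ua.rotational_dof for ua in topology.united_atoms)
    return ModeCount(
        m_transvib=3,
        m_rovib=topology.rotational_dof,
        ua_transvib=ua_trans,
        ua_rovib=ua_rot,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_topology(path, fmt: str = "plain", **kwargs) -> MolecularTopology:
    """Read a topology file.

    ``fmt='plain'`` is the key-value dialect written by
    :func:`write_topology`; ``fmt='amber'`` reads an AMBER-style parameter/
    topology file through MDAnalysis (first molecule taken as the species,
    replica count from the number of identical fragments).
    """
    if fmt == "plain":
        return _read_plain_topology(path, **kwargs)
    if fmt == "amber":
        return _read_amber_topology(path, **kwargs)
    raise FormatError(f"unknown topology format {fmt!r}")


def _read_plain_topology(path, **kwargs) -> MolecularTopology:
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    meta = {"nmol": 1, "symmetry": 1}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            key = fields[0].lower()
            if key == "atom":
                atoms.append(
                    AtomRecord(index=int(fields[1]), element=fields[2], mass=float(fields[3]))
                )
            elif key == "bond":
                bonds.append((int(fields[1]), int(fields[2])))
            elif key in ("nmol", "symmetry", "natoms"):
                meta[key] = int(fields[1])
            else:
                raise FormatError(f"unrecognised topology record {key!r}")
    if "natoms" in meta and meta["natoms"] != len(atoms):
        raise FormatError(
            f"header declares {meta['natoms']} atoms but file has {len(atoms)}"
        )
    atoms.sort(key=lambda a: a.index)
    if [a.index for a in atoms] != list(range(len(atoms))):
        raise FormatError("atom indices must be 0..natoms-1 without gaps")
    kwargs.setdefault("symmetry_number", meta["symmetry"])
    kwargs.setdefault("n_molecules", meta["nmol"])
    return MolecularTopology.from_atoms(atoms, bonds, **kwargs)


def write_topology(path, topology: MolecularTopology) -> None:
    with open(path, "w") as fh:
        fh.write(f"natoms {topology.n_atoms}\n")
        fh.write(f"nmol {topology.n_molecules}\n")
        fh.write(f"symmetry {topology.symmetry_number}\n")
        for a in topology.atoms:
            fh.write(f"atom {a.index} {a.element} {a.mass:.6f}\n")
        for i, j in topology.bonds:
            fh.write(f"bond {i} {j}\n")


def _read_amber_topology(path, **kwargs) -> MolecularTopology:
    import MDAnalysis as mda

    u = mda.Universe(str(path), format="PRMTOP", to_guess=())
    frags = u.atoms.fragments
    first = frags[0]
    n_per = len(first)
    if any(len(f) != n_per for f in frags):
        raise FormatError("fragments differ in size; pure liquids only")
    atoms = []
    for k, a in enumerate(first.atoms):
        element = getattr(a, "element", "") or ("H" if a.mass < 1.5 else a.name[:1])
        atoms.append(AtomRecord(index=k, element=element, mass=float(a.mass)))
    offset = first.atoms[0].index
    bonds = [
        (b.atoms[0].index - offset, b.atoms[1].index - offset)
        for b in first.atoms.bonds
    ]
    kwargs.setdefault("n_molecules", len(frags))
    return MolecularTopology.from_atoms(atoms, bonds, **kwargs)
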