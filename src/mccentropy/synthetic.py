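"""Seeded synthetic inputs with known ground truth.

These generators stand in for molecular-dynamics output when testing the
entropy pipeline:

* Gaussian net-force trajectories with a prescribed weighted-force second
  moment λ* (hence a known harmonic frequency) on static coordinates;
* a rigid diatomic "liquid" with prescribed translational *and* rotational
  frequencies (force couples supply the torque);
* categorical 3-state dihedral label series with prescribed marginals and
  pairwise lock probability;
* periodic point configurations (random, fcc lattice, octahedral probe)
  with known neighbour structure.

All randomness flows from explicit integer seeds; no global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .constants import KB, LAMBDA_INTERNAL_TO_SI
from .errors import ConfigError, GeometryError
from .topology import MolecularTopology
from .trajectory import Frame, write_plain

__all__ = [
    "HarmonicSpec",
    "lambda_from_frequency",
    "gen_gaussian_force_frames",
    "gen_rigid_diatomic_frames",
    "gen_dihedral_series",
    "gen_periodic_configuration",
    "write_fixture",
]


@dataclass
class HarmonicSpec:
    """Target for a harmonic-liquid fixture.

    ``lambda_star`` is the desired eigenvalue of the weighted force
    covariance in internal units, (kJ mol⁻¹ Å⁻¹)²/(g mol⁻¹), identical on
    all three axes.
    """

    lambda_star: float
    temperature: float
    n_frames: int
    n_molecules: int
    seed: int
    halve: bool = True  # generator inverts the pipeline's mean-field halving

    def __post_init__(self) -> None:
        if self.lambda_star <= 0:
            raise ConfigError(f"lambda_star must be > 0, got {self.lambda_star}")
        if self.n_frames < 2:
            raise ConfigError(f"n_frames must be >= 2, got {self.n_frames}")


def lambda_from_frequency(frequency_hz: float, temperature: float) -> float:
    """Internal-unit eigenvalue λ* whose harmonic frequency is ``frequency_hz``."""
    lam_si = (2.0 * np.pi * frequency_hz) ** 2 * KB * temperature
    return lam_si / LAMBDA_INTERNAL_TO_SI


def _molecule_grid(n_molecules: int, spacing: float) -> tuple[np.ndarray, float]:
    """Cubic grid of molecule origins; returns (origins, box edge)."""
    side = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    idx = np.arange(side)
    grid = np.array(np.meshgrid(idx, idx, idx, indexing="ij")).reshape(3, -1).T
    origins = (grid[:n_molecules] + 0.5) * spacing
    return origins, side * spacing


def gen_gaussian_force_frames(
    spec: HarmonicSpec, topology: MolecularTopology
) -> list[Frame]:
    """Static-coordinate frames with Gaussian per-molecule net forces.

    Net force components are i.i.d. N(0, s²) with s chosen so the
    pipeline's weighted second moment ⟨((F/2)/√m)²⟩ equals λ* per axis
    (the factor 2 is omitted when ``spec.halve`` is False).  The net force
    is distributed over atoms proportionally to mass, so the molecule
    neither rotates nor vibrates internally.
    """
    rng = np.random.default_rng(spec.seed)
    mass = topology.molecular_mass
    factor = 4.0 if spec.halve else 1.0
    sigma = np.sqrt(factor * mass * spec.lambda_star)

    nmol = spec.n_molecules
    na = topology.n_atoms
    coords_mol = _default_molecule_geometry(topology)
    spacing = max(4.0, 2.5 * (coords_mol.max() - coords_mol.min() + 1.0))
    origins, edge = _molecule_grid(nmol, spacing)
    coords = (origins[:, None, :] + coords_mol[None, :, :]).reshape(nmol * na, 3)
    weights = (topology.masses / mass)[None, :, None]

    frames = []
    for f in range(spec.n_frames):
        net = rng.normal(0.0, sigma, size=(nmol, 3))
        forces = (net[:, None, :] * weights).reshape(nmol * na, 3)
        frames.append(
            Frame(coordinates=coords.copy(), forces=forces, box=np.full(3, edge), time=float(f))
        )
    return frames


def _default_molecule_geometry(topology: MolecularTopology) -> np.ndarray:
    """A deterministic non-degenerate geometry for one molecule (Å).

    Atoms are placed on a coarse helix; adequate for fixtures whose
    observables do not depend on realistic geometry.
    """
    n = topology.n_atoms
    if n == 1:
        return np.zeros((1, 3))
    t = np.arange(n, dtype=float)
    return np.column_stack(
        [1.5 * np.cos(2.0 * t), 1.5 * np.sin(2.0 * t), 0.9 * t]
    )


def gen_rigid_diatomic_frames(
    trans_lambda: float,
    rot_lambda: float,
    *,
    mass_per_atom: float = 20.0,
    bond_length: float = 3.0,
    n_frames: int = 100,
    n_molecules: int = 100,
    seed: int = 0,
) -> tuple[list[Frame], MolecularTopology]:
    """Rigid homonuclear diatomic fixture with prescribed λ* per channel.

    Two point united atoms of equal mass at ±d/2 along x.  Per frame each
    molecule receives a mass-distributed net force (translational channel,
    second moment 4Mλ_t per axis before weighting) and an equal-and-
    opposite force couple perpendicular to the bond (rotational channel,
    torque second moment 4Iλ_r per finite-inertia axis).
    """
    from .topology import AtomRecord

    if trans_lambda <= 0 or rot_lambda <= 0:
        raise ConfigError("prescribed eigenvalues must be > 0")
    rng = np.random.default_rng(seed)
    m = mass_per_atom
    mass_total = 2.0 * m
    d = bond_length
    inertia = 2.0 * m * (d / 2.0) ** 2  # about either perpendicular axis

    atoms = [AtomRecord(0, "C", m), AtomRecord(1, "C", m)]
    topo = MolecularTopology.from_atoms(
        atoms, [(0, 1)], n_molecules=n_molecules, symmetry_number=2
    )

    sigma_f = np.sqrt(4.0 * mass_total * trans_lambda)  # molecule force halved
    sigma_c = 2.0 * np.sqrt(inertia * rot_lambda) / d  # torque halved

    local = np.array([[-d / 2.0, 0.0, 0.0], [d / 2.0, 0.0, 0.0]])
    spacing = max(4.0, 2.5 * d)
    origins, edge = _molecule_grid(n_molecules, spacing)
    coords = (origins[:, None, :] + local[None, :, :]).reshape(-1, 3)
    box = np.full(3, edge)

    frames = []
    for f in range(n_frames):
        net = rng.normal(0.0, sigma_f, size=(n_molecules, 3))
        couple = np.zeros((n_molecules, 3))
        couple[:, 1:] = rng.normal(0.0, sigma_c, size=(n_molecules, 2))
        f_a = net / 2.0 + couple
        f_b = net / 2.0 - couple
        forces = np.stack([f_a, f_b], axis=1).reshape(-1, 3)
        frames.append(Frame(coordinates=coords.copy(), forces=forces, box=box, time=float(f)))
    return frames, topo


def gen_dihedral_series(
    marginals: np.ndarray,
    pair_correlation: float | np.ndarray,
    n_samples: int,
    seed: int,
) -> np.ndarray:
    """Correlated 3-state label series, shape (n_samples, n_dihedrals).

    Dihedral 0 samples its marginal; each further dihedral m copies
    dihedral 0's label index with probability ``pair_correlation[m]``
    (scalar broadcast), otherwise samples its own marginal independently.
    A correlation of 1 with identical marginals yields a locked copy; 0
    yields independence.
    """
    marg = np.atleast_2d(np.asarray(marginals, dtype=float))
    ndih = marg.shape[0]
    if marg.shape[1] != 3 or np.any(marg < 0) or not np.allclose(marg.sum(axis=1), 1.0):
        raise ConfigError("each marginal must be a 3-state probability vector")
    corr = np.broadcast_to(np.asarray(pair_correlation, dtype=float), (ndih,)).copy()
    if np.any((corr < 0) | (corr > 1)):
        raise ConfigError("pair_correlation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = np.empty((n_samples, ndih), dtype=np.int8)
    labels[:, 0] = rng.choice(3, size=n_samples, p=marg[0])
    for mdx in range(1, ndih):
        own = rng.choice(3, size=n_samples, p=marg[mdx])
        copy = rng.random(n_samples) < corr[mdx]
        labels[:, mdx] = np.where(copy, labels[:, 0], own)
    return labels


def gen_periodic_configuration(
    kind: str,
    n_centers: int,
    box: float | np.ndarray,
    seed: int = 0,
    min_separation: float = 1.0,
) -> np.ndarray:
    """Periodic point configurations for coordination-number tests.

    ``random`` draws uniform points with a minimum-image separation floor;
    ``fcc`` fills the cubic box with a perfect face-centred-cubic lattice
    (n_centers must be 4c³); ``octahedral_probe`` puts one centre at the
    box middle with six equidistant axial neighbours (n_centers = 7).
    """
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    if np.any(box <= 0):
        raise ConfigError("box edges must be positive")
    rng = np.random.default_rng(seed)

    if kind == "random":
        pts: list[np.ndarray] = []
        attempts = 0
        while len(pts) < n_centers:
            attempts += 1
            if attempts > 1000 * n_centers:
                raise GeometryError(
                    f"cannot place {n_centers} centres with separation "
                    f">= {min_separation} in box {box}"
                )
            cand = rng.random(3) * box
            if pts:
                d = np.asarray(pts) - cand
                d = (d + box / 2.0) % box - box / 2.0
                if np.min(np.linalg.norm(d, axis=1)) < min_separation:
                    continue
            pts.append(cand)
        return np.asarray(pts)

    if kind == "fcc":
        c = round((n_centers / 4.0) ** (1.0 / 3.0))
        if 4 * c**3 != n_centers:
            raise ConfigError(f"fcc needs n_centers = 4c^3; got {n_centers}")
        if not np.allclose(box, box[0]):
            raise ConfigError("fcc fills a cubic box")
        a = box[0] / c
        basis = np.array(
            [[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]]
        )
        cells = np.array(
            np.meshgrid(np.arange(c), np.arange(c), np.arange(c), indexing="ij")
        ).reshape(3, -1).T
        return ((cells[:, None, :] + basis[None, :, :]).reshape(-1, 3)) * a

    if kind == "octahedral_probe":
        if n_centers != 7:
            raise ConfigError("octahedral_probe has exactly 7 centres")
        r = float(box.min()) / 4.0
        centre = box / 2.0
        offsets = np.array(
            [[r, 0, 0], [-r, 0, 0], [0, r, 0], [0, -r, 0], [0, 0, r], [0, 0, -r]]
        )
        return np.vstack([centre, centre + offsets])

    raise ConfigError(f"unknown configuration kind {kind!r}")


def write_fixture(path, frames: list[Frame], spec=None) -> None:
    """Write frames in the plain dialect plus a JSON manifest beside it."""
    write_plain(path, frames)
    manifest = {"n_frames": len(frames), "n_atoms": frames[0].n_atoms}
    if spec is not None:
        manifest["spec"] = asdict(spec) if hasattr(spec, "__dataclass_fields__") else spec
    with open(str(path) + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
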