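"""Single-pass assembly of the six-term entropy decomposition.

    S_total = S_M_transvib + S_M_rovib + S_M_topo
            + S_UA_transvib + S_UA_rovib + S_UA_topo

One streaming pass over the trajectory fills molecule- and united-atom-
level force/torque covariance accumulators, the RAD coordination
histogram and the dihedral conformation label series; finalisation then
yields the six terms, all in J K⁻¹ mol⁻¹ per molecule of liquid.  All
molecules in the box are identical copies of the topology and are pooled
into the same accumulators.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from . import topographical as topo
from . import vibrational as vib
from .errors import ConfigError, InsufficientDataError, UnusableInputError
from .topology import MolecularTopology, count_vibrational_modes
from .trajectory import Frame

log = logging.getLogger(__name__)

TERM_ORDER = (
    "S_M_transvib",
    "S_M_rovib",
    "S_M_topo",
    "S_UA_transvib",
    "S_UA_rovib",
    "S_UA_topo",
)


@dataclass
class RunConfig:
    """User-facing knobs of one entropy computation.

    ``temperature`` in K is mandatory and never inferred from the
    trajectory.  ``symmetry_number`` overrides the topology's σ;  when
    neither is set σ defaults to 1 with a warning.  ``coordination_stride``
    evaluates the RAD histogram on every k-th frame only (the histogram
    converges with very few frames, so this is a cheap speedup).
    """

    temperature: float
    symmetry_number: int | None = None
    single_ua_orientational: bool = False
    rad_unsorted: bool = False
    ua_rovib_removal: bool = False
    coordination_stride: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigError(f"temperature must be > 0 K, got {self.temperature}")
        if self.coordination_stride < 1:
            raise ConfigError("coordination_stride must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class EntropyDecomposition:
    """The six entropy terms plus bookkeeping and diagnostics."""

    S_M_transvib: float
    S_M_rovib: float
    S_M_topo: float
    S_UA_transvib: float
    S_UA_rovib: float
    S_UA_topo: float
    temperature: float
    n_frames: int
    n_molecules: int
    mode_counts: dict = field(default_factory=dict)
    frequencies_s1: dict = field(default_factory=dict)
    eigenvalues: dict = field(default_factory=dict)
    coordination_probabilities: dict = field(default_factory=dict)
    conformation_eigenvalues: list = field(default_factory=list)
    zero_mode_exclusions: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def S_total(self) -> float:
        return (
            self.S_M_transvib
            + self.S_M_rovib
            + self.S_M_topo
            + self.S_UA_transvib
            + self.S_UA_rovib
            + self.S_UA_topo
        )

    def terms(self) -> dict[str, float]:
        out = {name: getattr(self, name) for name in TERM_ORDER}
        out["S_total"] = self.S_total
        return out


def compute_decomposition(
    topology: MolecularTopology,
    frames: Iterable[Frame],
    config: RunConfig,
) -> EntropyDecomposition:
    """Run the full multiscale computation over a force trajectory."""
    sigma = config.symmetry_number
    if sigma is None:
        sigma = topology.symmetry_number
        if sigma == 1:
            log.warning("symmetry number defaulting to 1; set it if the molecule is symmetric")

    nmol = topology.n_molecules
    na = topology.n_atoms
    n_ua = topology.n_united_atoms
    masses = topology.masses
    modes = count_vibrational_modes(topology)
    rot_dof = topology.rotational_dof

    acc_mf = vib.CovarianceAccumulator(3, level="molecule", channel="force")
    acc_mt = (
        vib.CovarianceAccumulator(rot_dof, level="molecule", channel="torque")
        if rot_dof > 0
        else None
    )
    acc_uf = (
        vib.CovarianceAccumulator(3 * n_ua, level="united-atom", channel="force")
        if n_ua > 1
        else None
    )
    ua_rot_dims = sum(ua.rotational_dof for ua in topology.united_atoms) if n_ua > 1 else 0
    acc_ut = (
        vib.CovarianceAccumulator(ua_rot_dims, level="united-atom", channel="torque")
        if ua_rot_dims > 0
        else None
    )

    # membership matrix G: UA x atom, and mass-weighted version for UA centres
    G = np.zeros((n_ua, na))
    for k, ua in enumerate(topology.united_atoms):
        G[k, list(ua.members)] = 1.0
    ua_masses = np.array([ua.mass for ua in topology.united_atoms])
    Gw = G * masses[None, :] / ua_masses[:, None]

    need_orientational = nmol >= 2 and (
        n_ua > 1 or config.single_ua_orientational
    )
    hist = topo.CoordinationHistogram()
    dihedral_quads = np.array(topology.dihedrals, dtype=int).reshape(-1, 4)
    label_chunks: list[np.ndarray] = []

    n_frames = 0
    for frame in frames:
        if frame.n_atoms != nmol * na:
            raise UnusableInputError(
                f"frame {n_frames}: {frame.n_atoms} atoms, topology expects {nmol * na}"
            )
        coords = frame.coordinates.reshape(nmol, na, 3)
        forces = frame.forces.reshape(nmol, na, 3)
        box = frame.box
        # make molecules whole across periodic boundaries
        rel0 = coords - coords[:, :1, :]
        rel0 = (rel0 + box / 2.0) % box - box / 2.0
        coords = coords[:, :1, :] + rel0

        origins, axes, inertia = vib.principal_frames_batch(coords, masses)

        net = forces.sum(axis=1)
        wf = np.einsum("mij,mj->mi", axes, net) * 0.5 / np.sqrt(topology.molecular_mass)
        acc_mf.add_batch(wf)

        if acc_mt is not None:
            rel = coords - origins[:, None, :]
            tau = np.cross(rel, forces).sum(axis=1)
            tau_local = np.einsum("mij,mj->mi", axes, tau)[:, :rot_dof]
            keep_inertia = inertia[:, :rot_dof]
            acc_mt.add_batch(tau_local * 0.5 / np.sqrt(keep_inertia))

        if acc_uf is not None:
            f_ua = np.einsum("un,mnj->muj", G, forces)
            f_rot = np.einsum("mij,muj->mui", axes, f_ua)
            acc_uf.add_batch(
                (f_rot / np.sqrt(ua_masses)[None, :, None]).reshape(nmol, 3 * n_ua)
            )

        if acc_ut is not None:
            acc_ut.add_batch(_ua_torque_batch(coords, forces, topology))

        if len(dihedral_quads):
            ua_pos = np.einsum("un,mnj->muj", Gw, coords)
            angles = topo.dihedral_angles(ua_pos, dihedral_quads)
            label_chunks.append(topo.assign_conformations(angles))

        if need_orientational and n_frames % config.coordination_stride == 0:
            centres = np.einsum("a,mai->mi", masses, coords) / topology.molecular_mass
            centres = centres % box
            for i in range(nmol):
                hist.add(
                    topo.rad_coordination(
                        centres, i, box, sorted_variant=not config.rad_unsorted
                    )
                )
        n_frames += 1

    if n_frames < 2:
        raise InsufficientDataError(f"trajectory has {n_frames} frame(s); need >= 2")

    T = config.temperature
    frequencies: dict[str, list] = {}
    eigvals_out: dict[str, list] = {}
    zero_excl: dict[str, int] = {}

    def _vib_term(acc, level, channel) -> float:
        if acc is None:
            return 0.0
        cov = acc.finalize()
        lam = np.linalg.eigvalsh(cov)[::-1]
        lam = np.clip(lam, 0.0, None)
        spec = vib.select_modes(
            lam, level, channel, topology, ua_rovib_removal=config.ua_rovib_removal
        )
        nu = vib.frequencies_from_eigenvalues(spec.eigenvalues, T)
        key = f"{level}_{channel}"
        frequencies[key] = nu.tolist()
        eigvals_out[key] = lam.tolist()
        zero_excl[key] = spec.n_zero_excluded
        return vib.qho_entropy(nu, T)

    s_m_trans = _vib_term(acc_mf, "molecule", "force")
    s_m_rot = _vib_term(acc_mt, "molecule", "torque")
    s_ua_trans = _vib_term(acc_uf, "united-atom", "force")
    s_ua_rot = _vib_term(acc_ut, "united-atom", "torque")

    if need_orientational and hist.n_samples > 0:
        s_m_topo = topo.orientational_entropy(hist, sigma, rot_dof == 2)
        coord_probs = {str(k): v for k, v in hist.probabilities().items()}
    else:
        if nmol < 2 and n_ua > 1:
            log.warning("single molecule in box: orientational entropy set to 0")
        s_m_topo = 0.0
        coord_probs = {}

    conf_eigs: list[float] = []
    if len(dihedral_quads):
        labels = np.concatenate(label_chunks, axis=0).reshape(-1, len(dihedral_quads))
        model = topo.build_conformation_matrix(labels)
        s_ua_topo = topo.conformational_entropy(model)
        conf_eigs = model.eigenvalues.tolist()
    else:
        s_ua_topo = 0.0

    return EntropyDecomposition(
        S_M_transvib=s_m_trans,
        S_M_rovib=s_m_rot,
        S_M_topo=s_m_topo,
        S_UA_transvib=s_ua_trans,
        S_UA_rovib=s_ua_rot,
        S_UA_topo=s_ua_topo,
        temperature=T,
        n_frames=n_frames,
        n_molecules=nmol,
        mode_counts=asdict(modes),
        frequencies_s1=frequencies,
        eigenvalues=eigvals_out,
        coordination_probabilities=coord_probs,
        conformation_eigenvalues=conf_eigs,
        zero_mode_exclusions=zero_excl,
        provenance={"config_digest": config.digest(), "symmetry_number": sigma},
    )


def _ua_torque_batch(
    coords: np.ndarray, forces: np.ndarray, topology: MolecularTopology
) -> np.ndarray:
    """Halved, inertia-weighted UA torque components for all molecules of a
    frame; shape (n_mol, Σ per-UA rotational dof)."""
    nmol = coords.shape[0]
    parts: list[np.ndarray] = []
    for ua in topology.united_atoms:
        if ua.rotational_dof == 0:
            continue
        members = list(ua.members)
        m = topology.masses[members]
        pts = coords[:, members, :]
        fm = forces[:, members, :]
        if ua.rotation_class == "linear":
            com = np.einsum("a,mai->mi", m, pts) / m.sum()
            axis = pts[:, 1:, :].mean(axis=1) - pts[:, 0, :]
            axis /= np.linalg.norm(axis, axis=1, keepdims=True)
            # deterministic perpendicular pair per molecule
            e = np.eye(3)[np.argmin(np.abs(axis), axis=1)]
            v = np.cross(axis, e)
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            w = np.cross(axis, v)
            rel = pts - com[:, None, :]
            proj = np.einsum("mai,mi->ma", rel, axis)
            inertia = np.einsum("a,ma->m", m, (rel**2).sum(axis=2) - proj**2)
            tau = np.cross(rel, fm).sum(axis=1)
            comp = np.stack(
                [(tau * v).sum(axis=1), (tau * w).sum(axis=1)], axis=1
            )
            parts.append(comp * 0.5 / np.sqrt(inertia)[:, None])
        else:
            origins, axes_u, inertia = vib.principal_frames_batch(pts, m)
            rel = pts - origins[:, None, :]
            tau = np.cross(rel, fm).sum(axis=1)
            tau_local = np.einsum("mij,mj->mi", axes_u, tau)
            parts.append(tau_local * 0.5 / np.sqrt(inertia))
    return np.concatenate(parts, axis=1) if parts else np.empty((nmol, 0))
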