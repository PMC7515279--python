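"""Vibrational entropy from force and torque fluctuations.

The liquid's potential energy surface is approximated, per molecule and per
united atom, by harmonic wells whose stiffness is inferred from the second
moments of mass-weighted forces and inertia-weighted torques accumulated
over the trajectory.  Eigenvalues λ of those covariance matrices convert to
harmonic frequencies ν = (1/2π)·√(λ/kBT), and the entropy is that of the
corresponding quantum harmonic oscillators,

    S = R Σ_i [ x_i/(e^{x_i} − 1) − ln(1 − e^{−x_i}) ],   x_i = hν_i/kBT.

Weighting conventions (mean-field halving assigns half of each pairwise
force to each partner, valid only for weakly correlated degrees of freedom):

* molecule force:   (F_net / 2) / √m        — halved
* molecule torque:  (τ / 2) / √I_axis       — halved
* UA force:         F_net / √m_UA           — NOT halved (bonded forces are
  strongly correlated; the correlation lives in the covariance matrix)
* UA torque:        (τ / 2) / √I_axis       — halved
* dihedral modes:   the N_dih smallest retained eigenvalues of the UA force
  covariance are divided by 4 (halving applied at the eigenvalue, i.e.
  force-squared, level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import H_PLANCK, KB, LAMBDA_INTERNAL_TO_SI, R_GAS
from .errors import ConfigError, GeometryError, InsufficientDataError, MCCError
from .topology import MolecularTopology, ROTATION_LINEAR, ROTATION_POINT

log = logging.getLogger(__name__)

#: eigenvalues below this fraction of the largest are treated as zero
EIGENVALUE_CLAMP = 1e-10
#: inertia below this fraction of the largest marks a (near-)zero-inertia axis
INERTIA_ZERO_TOL = 1e-8
#: principal inertias closer than this fraction of the largest are treated as
#: degenerate and their eigenbasis is re-fixed canonically (symmetric tops)
INERTIA_DEGENERACY_TOL = 1e-6


@dataclass
class LocalFrame:
    """Principal-axis frame of a rigid body.

    ``axes`` rows are the principal axes ordered by *descending* moment of
    inertia; ``zero_inertia`` flags axes whose inertia is (near) zero
    (the long axis of a linear body, or all axes of a point body).
    """

    origin: np.ndarray  # (3,) centre of mass, Å
    axes: np.ndarray  # (3, 3) rows = axes, right-handed
    principal_inertia: np.ndarray  # (3,) g mol^-1 Å^2, descending
    zero_inertia: np.ndarray  # (3,) bool


def principal_frame(coordinates: np.ndarray, masses: np.ndarray) -> LocalFrame:
    """Centre of mass and principal inertia axes of a set of point masses.

    Axes are ordered by descending inertia; each of the first two axes has
    its largest-magnitude component made positive and the third enforces
    right-handedness, so the frame is deterministic for non-degenerate
    bodies.
    """
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    masses = np.asarray(masses, dtype=float).ravel()
    if masses.sum() <= 0:
        raise GeometryError("total mass must be positive")
    origin = masses @ coords / masses.sum()
    if len(coords) == 1:
        return LocalFrame(
            origin=origin,
            axes=np.eye(3),
            principal_inertia=np.zeros(3),
            zero_inertia=np.ones(3, dtype=bool),
        )
    rel = coords - origin
    inertia = _inertia_tensor(rel, masses)
    evals, evecs = np.linalg.eigh(inertia)  # ascending
    if evals[-1] <= 0:
        raise GeometryError("all points coincident: inertia tensor is zero")
    order = [2, 1, 0]  # descending inertia
    evals = evals[order]
    axes = evecs[:, order].T  # rows = axes
    axes = _resolve_degeneracy(axes, evals)
    axes = _fix_axis_signs(axes)
    zero = evals < INERTIA_ZERO_TOL * evals[0]
    return LocalFrame(
        origin=origin,
        axes=axes,
        principal_inertia=np.clip(evals, 0.0, None),
        zero_inertia=zero,
    )


def _inertia_tensor(rel: np.ndarray, masses: np.ndarray) -> np.ndarray:
    r2 = (rel**2).sum(axis=1)
    return float((masses * r2).sum()) * np.eye(3) - np.einsum(
        "a,ai,aj->ij", masses, rel, rel
    )


def _canonical_perp_pair(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair spanning the plane perpendicular to n."""
    e = np.eye(3)[int(np.argmin(np.abs(n)))]
    v1 = np.cross(n, e)
    v1 /= np.linalg.norm(v1)
    return v1, np.cross(n, v1)


def _resolve_degeneracy(axes: np.ndarray, evals: np.ndarray) -> np.ndarray:
    """Replace eigensolver-arbitrary bases of degenerate inertia subspaces.

    For a symmetric top the eigenbasis within the degenerate pair is fixed
    canonically from the unique axis; for a spherical top any basis
    diagonalises the tensor and the laboratory basis is used.  This keeps
    the local frame a deterministic function of the body orientation.
    """
    tol = INERTIA_DEGENERACY_TOL * max(evals[0], 1e-300)
    d01 = abs(evals[0] - evals[1]) <= tol
    d12 = abs(evals[1] - evals[2]) <= tol
    out = axes.copy()
    if d01 and d12:
        return np.eye(3)
    if d01:
        v1, v2 = _canonical_perp_pair(out[2])
        out[0], out[1] = v1, v2
    elif d12:
        v1, v2 = _canonical_perp_pair(out[0])
        out[1], out[2] = v1, v2
    return out


def _fix_axis_signs(axes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention + right-handedness (det = +1)."""
    out = axes.copy()
    for k in range(2):
        i = int(np.argmax(np.abs(out[k])))
        if out[k, i] < 0:
            out[k] = -out[k]
    out[2] = np.cross(out[0], out[1])
    return out


# -- batched variant used by the pipeline -----------------------------------

def principal_frames_batch(
    coords: np.ndarray, masses: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`principal_frame` over molecules.

    ``coords`` has shape (n_mol, n_atoms, 3).  Returns (origins (m,3),
    axes (m,3,3), inertia (m,3) descending).
    """
    m = masses.ravel()
    total = m.sum()
    origins = np.einsum("a,mai->mi", m, coords) / total
    rel = coords - origins[:, None, :]
    r2 = np.einsum("mai,mai->ma", rel, rel)
    eye = np.eye(3)
    inertia = np.einsum("a,ma->m", m, r2)[:, None, None] * eye[None] - np.einsum(
        "a,mai,maj->mij", m, rel, rel
    )
    evals, evecs = np.linalg.eigh(inertia)
    evals = evals[:, ::-1]
    axes = np.transpose(evecs[:, :, ::-1], (0, 2, 1))  # rows = axes, descending
    # canonical bases inside degenerate subspaces (symmetric/spherical tops)
    tol = INERTIA_DEGENERACY_TOL * np.maximum(evals[:, 0], 1e-300)
    d01 = np.abs(evals[:, 0] - evals[:, 1]) <= tol
    d12 = np.abs(evals[:, 1] - evals[:, 2]) <= tol
    if (d01 | d12).any():
        for idx in np.nonzero(d01 | d12)[0]:
            axes[idx] = _resolve_degeneracy(axes[idx], evals[idx])
    # sign convention, vectorised
    for k in range(2):
        idx = np.argmax(np.abs(axes[:, k, :]), axis=1)
        sign = np.sign(axes[np.arange(len(axes)), k, idx])
        sign[sign == 0] = 1.0
        axes[:, k, :] *= sign[:, None]
    axes[:, 2, :] = np.cross(axes[:, 0, :], axes[:, 1, :])
    return origins, axes, np.clip(evals, 0.0, None)


# ---------------------------------------------------------------------------
# per-molecule weighted samples
# ---------------------------------------------------------------------------

def molecule_weighted_force(
    forces: np.ndarray, local_frame: LocalFrame, mass: float, halve: bool = True
) -> np.ndarray:
    """Mean-field mass-weighted net force in the molecular frame.

    (ΣF)·½ rotated into principal axes, each component divided by √m.
    """
    net = np.asarray(forces, dtype=float).sum(axis=0)
    scale = 0.5 if halve else 1.0
    return (local_frame.axes @ net) * scale / np.sqrt(mass)


def molecule_weighted_torque(
    coordinates: np.ndarray,
    forces: np.ndarray,
    local_frame: LocalFrame,
    rotational_dof: int | None = None,
) -> np.ndarray:
    """Inertia-weighted, halved torque components about the centre of mass.

    Components along (near-)zero-inertia axes are omitted, so a linear
    body yields 2 components, a nonlinear one 3.
    """
    keep = ~local_frame.zero_inertia
    if rotational_dof is not None:
        if rotational_dof == 0:
            raise MCCError("torque requested on a point body")
        keep = np.zeros(3, dtype=bool)
        keep[:rotational_dof] = True  # axes sorted by descending inertia
    elif not keep.any():
        raise MCCError("torque requested on a point body")
    rel = np.asarray(coordinates, dtype=float) - local_frame.origin
    tau = np.cross(rel, np.asarray(forces, dtype=float)).sum(axis=0)
    tau_local = local_frame.axes @ tau
    inertia = local_frame.principal_inertia
    return tau_local[keep] * 0.5 / np.sqrt(inertia[keep])


def ua_weighted_forces(
    forces: np.ndarray, topology: MolecularTopology, local_frame: LocalFrame
) -> np.ndarray:
    """Concatenated per-UA net forces in the molecule frame, NOT halved,
    each UA's 3 components divided by √(UA mass)."""
    out = np.empty(3 * topology.n_united_atoms)
    f = np.asarray(forces, dtype=float)
    for k, ua in enumerate(topology.united_atoms):
        net = f[list(ua.members)].sum(axis=0)
        out[3 * k : 3 * k + 3] = (local_frame.axes @ net) / np.sqrt(ua.mass)
    return out


def ua_weighted_torques(
    coordinates: np.ndarray, forces: np.ndarray, topology: MolecularTopology
) -> np.ndarray:
    """Concatenated halved, inertia-weighted per-UA torque components.

    Each UA's torque is taken about its own centre of mass in its own local
    frame: principal axes of its member atoms for a nonlinear UA (3
    components), the two axes perpendicular to the heavy-atom→hydrogen axis
    for a linear UA (2 components).  Point UAs contribute nothing.
    """
    coords = np.asarray(coordinates, dtype=float)
    f = np.asarray(forces, dtype=float)
    parts: list[np.ndarray] = []
    for ua in topology.united_atoms:
        if ua.rotation_class == ROTATION_POINT:
            continue
        members = list(ua.members)
        m = topology.masses[members]
        pts = coords[members]
        if ua.rotation_class == ROTATION_LINEAR:
            com = m @ pts / m.sum()
            axis = pts[1:].mean(axis=0) - pts[0]  # heavy -> hydrogens
            norm = np.linalg.norm(axis)
            if norm == 0:
                raise GeometryError("linear UA with coincident heavy atom and H")
            u = axis / norm
            v, w = _perpendicular_pair(u)
            rel = pts - com
            inertia = float(
                (m * ((rel**2).sum(axis=1) - (rel @ u) ** 2)).sum()
            )
            tau = np.cross(rel, f[members]).sum(axis=0)
            parts.append(
                np.array([tau @ v, tau @ w]) * 0.5 / np.sqrt(inertia)
            )
        else:
            lf = principal_frame(pts, m)
            rel = pts - lf.origin
            tau = lf.axes @ np.cross(rel, f[members]).sum(axis=0)
            keep = ~lf.zero_inertia
            parts.append(tau[keep] * 0.5 / np.sqrt(lf.principal_inertia[keep]))
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def _perpendicular_pair(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic orthonormal pair perpendicular to unit vector u."""
    e = np.eye(3)[int(np.argmin(np.abs(u)))]
    v = np.cross(u, e)
    v /= np.linalg.norm(v)
    return v, np.cross(u, v)


# ---------------------------------------------------------------------------
# streaming covariance
# ---------------------------------------------------------------------------

@dataclass
class CovarianceAccumulator:
    """Streaming raw second moment ⟨v vᵀ⟩ of weighted component vectors.

    The raw (non-mean-subtracted) second moment is used because mean
    forces and torques vanish at equilibrium; the accumulated mean is
    tracked and a warning is logged if |mean|/rms exceeds 0.1 on any
    component.
    """

    dimension: int
    level: str = "molecule"  # or "united-atom"
    channel: str = "force"  # or "torque"
    _sum: np.ndarray = field(init=False, repr=False)
    _outer: np.ndarray = field(init=False, repr=False)
    n_samples: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self._sum = np.zeros(self.dimension)
        self._outer = np.zeros((self.dimension, self.dimension))

    def add(self, v: np.ndarray) -> None:
        v = np.asarray(v, dtype=float).ravel()
        self._sum += v
        self._outer += np.outer(v, v)
        self.n_samples += 1

    def add_batch(self, vs: np.ndarray) -> None:
        """Add k samples at once; ``vs`` has shape (k, dimension)."""
        vs = np.asarray(vs, dtype=float)
        self._sum += vs.sum(axis=0)
        self._outer += vs.T @ vs
        self.n_samples += len(vs)

    def merge(self, other: "CovarianceAccumulator") -> None:
        self._sum += other._sum
        self._outer += other._outer
        self.n_samples += other.n_samples

    def finalize(self) -> np.ndarray:
        if self.n_samples < 2:
            raise InsufficientDataError(
                f"{self.level} {self.channel}: {self.n_samples} samples; need >= 2"
            )
        second = self._outer / self.n_samples
        second = 0.5 * (second + second.T)
        mean = self._sum / self.n_samples
        rms = np.sqrt(np.diag(second))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(rms > 0, np.abs(mean) / rms, 0.0)
        if np.any(ratio > 0.1):
            log.warning(
                "%s %s covariance: |mean|/rms up to %.3f exceeds 0.1; "
                "system may not be equilibrated",
                self.level,
                self.channel,
                float(ratio.max()),
            )
        return second


# ---------------------------------------------------------------------------
# eigenvalues -> frequencies -> entropy
# ---------------------------------------------------------------------------

@dataclass
class VibrationalSpectrum:
    """Retained covariance eigenvalues and their harmonic frequencies."""

    eigenvalues: np.ndarray  # retained, descending, internal units
    n_vib: int
    frequencies: np.ndarray = field(default_factory=lambda: np.empty(0))  # s^-1
    dihedral_softened: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    n_zero_excluded: int = 0


def select_modes(
    eigenvalues: np.ndarray,
    level: str,
    channel: str,
    topology: MolecularTopology,
    ua_rovib_removal: bool = False,
) -> VibrationalSpectrum:
    """Apply the degree-of-freedom bookkeeping to a sorted eigenvalue set.

    Molecule force: keep all 3.  Molecule torque: keep the molecule's
    rotational-dof count.  UA force: drop the largest 6 (nonlinear
    molecule) or 5 (linear) — these duplicate whole-molecule translation
    and rotation — then divide the N_dih smallest retained eigenvalues by
    4 (mean-field halving for soft dihedral modes).  UA torque: keep all
    per-UA rotational components (optionally apply the same 6/5 removal
    with ``ua_rovib_removal``).  Eigenvalues within the clamp tolerance of
    zero are excluded and counted in ``n_zero_excluded``.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    scale = lam[0] if len(lam) and lam[0] > 0 else 0.0
    softened = np.zeros(len(lam), dtype=bool)
    if level == "molecule":
        keep = 3 if channel == "force" else topology.rotational_dof
        if len(lam) < keep:
            raise MCCError(f"need {keep} eigenvalues, got {len(lam)}")
        lam = lam[:keep]
        softened = softened[:keep]
    elif level == "united-atom" and channel == "force":
        removed = 5 if topology.molecule_linear else 6
        if len(lam) < removed:
            raise MCCError(
                f"UA force spectrum has {len(lam)} eigenvalues; cannot remove {removed}"
            )
        lam = lam[removed:]
        softened = softened[removed:]
        ndih = min(topology.n_dihedrals, len(lam))
        if ndih > 0:
            lam = lam.copy()
            lam[-ndih:] = lam[-ndih:] / 4.0
            softened[-ndih:] = True
            lam_order = np.argsort(lam)[::-1]
            lam, softened = lam[lam_order], softened[lam_order]
    elif level == "united-atom" and channel == "torque":
        if ua_rovib_removal:
            removed = 5 if topology.molecule_linear else 6
            if len(lam) < removed:
                raise MCCError("UA torque spectrum too small for requested removal")
            lam = lam[removed:]
            softened = softened[removed:]
    else:
        raise MCCError(f"unknown level/channel {level!r}/{channel!r}")

    # clamp relative to the full spectrum's scale, not the retained subset
    positive = lam > EIGENVALUE_CLAMP * scale
    n_zero = int((~positive).sum())
    if n_zero:
        log.warning(
            "%s %s: %d eigenvalue(s) clamped to zero and excluded", level, channel, n_zero
        )
    return VibrationalSpectrum(
        eigenvalues=lam[positive],
        n_vib=int(positive.sum()),
        dihedral_softened=softened[positive],
        n_zero_excluded=n_zero,
    )


def frequencies_from_eigenvalues(
    eigenvalues: np.ndarray, temperature: float
) -> np.ndarray:
    """ν = (1/2π)·√(λ/kBT) with λ converted from internal units to SI, s⁻¹."""
    if temperature <= 0:
        raise ConfigError(f"temperature must be > 0 K, got {temperature}")
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0):
        raise MCCError("negative eigenvalue passed to frequency conversion")
    lam_si = lam * LAMBDA_INTERNAL_TO_SI
    return np.sqrt(lam_si / (KB * temperature)) / (2.0 * np.pi)


def qho_entropy(frequencies: np.ndarray, temperature: float) -> float:
    """Quantum-harmonic-oscillator entropy of a frequency set, J K⁻¹ mol⁻¹.

    Zero frequencies are excluded (their classical entropy diverges) with a
    logged warning.  The sum is additive over modes, non-negative and
    decreasing in each frequency.
    """
    if temperature <= 0:
        raise ConfigError(f"temperature must be > 0 K, got {temperature}")
    nu = np.asarray(frequencies, dtype=float)
    if np.any(nu < 0):
        raise MCCError("negative frequency in qho_entropy")
    zero = nu == 0
    if zero.any():
        log.warning("qho_entropy: excluding %d zero-frequency mode(s)", int(zero.sum()))
        nu = nu[~zero]
    if nu.size == 0:
        return 0.0
    x = H_PLANCK * nu / (KB * temperature)
    # x/(e^x - 1) underflows safely; cap x to avoid overflow in expm1
    xc = np.minimum(x, 700.0)
    term = np.where(x < 700.0, xc / np.expm1(xc), 0.0) - np.log1p(-np.exp(-xc))
    return float(R_GAS * term.sum())
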