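"""Topographical entropy: orientations at the molecule level, conformations
at the united-atom level.

The orientational term treats each molecule's rotational phase space as
discretised by its Nc nearest neighbours (relative-angular-distance, RAD,
coordination), with ~√Nc equally probable orientations per rotational axis
divided by the symmetry number σ:

    S_orient = R Σ_Nc p(Nc) ln max(1, √(Nc³ π)/σ)        (nonlinear)
    S_orient = R Σ_Nc p(Nc) ln max(1, Nc/σ)              (linear, 2 axes)

The conformational term discretises each united-atom dihedral into three
states (trans, gauche−, gauche+) and diagonalises a conformation
correlation matrix ρ whose eigenvalues act as conformer probabilities:

    ρ_ij = p_ij · r_ij / P_m(i),    S_conf = −R Σ_i λ_i ln λ_i

with p_ij the pair probability (each dihedral-pair 3×3 block normalised to
sum 1), r_ij the Pearson correlation of the conformation indicator
variables, and P_m one constant per dihedral making each dihedral's
3-row block of ρ sum to 1.  trace(ρ) runs from 1 (fully correlated) to
N_dih (independent dihedrals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import R_GAS
from .errors import ConfigError, GeometryError, InsufficientDataError

log = logging.getLogger(__name__)

CONFORMATION_LABELS = ("t", "g-", "g+")

#: |λ| below this is dropped from the conformational entropy sum
CONF_EIGENVALUE_CLAMP = 1e-12
#: negative eigenvalues beyond this trigger a warning (anticorrelation artefact)
CONF_NEGATIVE_WARN = -1e-6


# ---------------------------------------------------------------------------
# RAD coordination
# ---------------------------------------------------------------------------

def rad_coordination(
    positions: np.ndarray,
    center_index: int,
    box: np.ndarray,
    sorted_variant: bool = True,
) -> int:
    """Relative-angular-distance coordination number of one centre.

    Neighbours j are considered in increasing (minimum-image) distance
    from centre i and accepted unless blocked by a closer accepted
    neighbour k; j is blocked by k iff

        (1/r_ij)² < (1/r_ik)² · cos θ_jik

    with θ_jik the angle at i between j and k.  With
    ``sorted_variant=False`` every closer particle can block, accepted or
    not (the unsorted variant).
    """
    pos = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    d = pos - pos[center_index]
    d = (d + box / 2.0) % box - box / 2.0  # minimum image
    d = np.delete(d, center_index, axis=0)
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0):
        raise GeometryError("coincident molecular centres in RAD")
    order = np.argsort(r, kind="stable")
    d, r = d[order], r[order]
    inv_r2 = 1.0 / r**2
    accepted: list[int] = []
    for j in range(len(r)):
        if sorted_variant:
            blockers = accepted
        else:
            blockers = list(range(j))
        if blockers:
            k = np.array(blockers)
            cos_theta = (d[k] @ d[j]) / (r[k] * r[j])
            if np.any(inv_r2[j] < inv_r2[k] * cos_theta):
                continue
        accepted.append(j)
    return len(accepted)


@dataclass
class CoordinationHistogram:
    """Empirical distribution of integer coordination numbers."""

    counts: dict[int, int] = field(default_factory=dict)
    n_samples: int = 0

    def add(self, nc: int) -> None:
        self.counts[int(nc)] = self.counts.get(int(nc), 0) + 1
        self.n_samples += 1

    def add_many(self, ncs) -> None:
        for nc in ncs:
            self.add(nc)

    def probabilities(self) -> dict[int, float]:
        if self.n_samples == 0:
            raise InsufficientDataError("empty coordination histogram")
        return {nc: c / self.n_samples for nc, c in sorted(self.counts.items())}

    @classmethod
    def from_probabilities(cls, probs: dict[int, float], n_samples: int = 1):
        h = cls()
        total = sum(probs.values())
        if not np.isclose(total, 1.0):
            raise ConfigError(f"probabilities sum to {total}, expected 1")
        h.counts = {int(k): v for k, v in probs.items()}
        h.n_samples = 1  # counts hold probabilities directly
        return h


def orientational_entropy(
    histogram: CoordinationHistogram,
    symmetry_number: int,
    molecule_linear: bool,
) -> float:
    """Molecule-level orientational entropy from p(Nc), J K⁻¹ mol⁻¹."""
    if symmetry_number < 1:
        raise ConfigError(f"symmetry number must be >= 1, got {symmetry_number}")
    probs = histogram.probabilities()
    s = 0.0
    for nc, p in probs.items():
        if nc <= 0:
            continue
        if molecule_linear:
            orientations = nc / symmetry_number
        else:
            orientations = np.sqrt(nc**3 * np.pi) / symmetry_number
        s += p * np.log(max(1.0, orientations))
    return float(R_GAS * s)


# ---------------------------------------------------------------------------
# conformations
# ---------------------------------------------------------------------------

def assign_conformation(angle_deg: float) -> str:
    """Discrete conformation of a dihedral angle: 't', 'g-' or 'g+'.

    Boundaries at ±120° and 0°: g+ on (0, 120], g− on [−120, 0], trans
    otherwise.  Angles outside (−180, 180] are first normalised by ±360°.
    """
    return CONFORMATION_LABELS[assign_conformations(np.array([angle_deg]))[0]]


def assign_conformations(angles_deg: np.ndarray) -> np.ndarray:
    """Vectorised conformation assignment; returns ints 0=t, 1=g−, 2=g+."""
    a = np.asarray(angles_deg, dtype=float)
    a = a - 360.0 * np.ceil((a - 180.0) / 360.0)  # normalise to (-180, 180]
    out = np.zeros(a.shape, dtype=np.int8)  # trans by default
    out[(a >= -120.0) & (a <= 0.0)] = 1  # g-
    out[(a > 0.0) & (a <= 120.0)] = 2  # g+
    return out


@dataclass
class ConformationModel:
    """Conformation statistics and the correlation matrix ρ of one species."""

    n_dihedrals: int
    marginals: np.ndarray  # (n_dih, 3) conformation probabilities
    joint: np.ndarray  # (3n, 3n) pair probabilities (block-normalised)
    pearson: np.ndarray  # (3n, 3n) conformation correlation coefficients
    rho: np.ndarray  # (3n, 3n) correlation matrix, rows block-normalised
    eigenvalues: np.ndarray  # real eigenvalues of ρ, descending

    @property
    def trace(self) -> float:
        return float(np.trace(self.rho))


def build_conformation_matrix(labels: np.ndarray) -> ConformationModel:
    """Build the conformation correlation matrix from a label series.

    ``labels`` has shape (n_samples, n_dihedrals) with entries 0/1/2, all
    dihedrals observed over the same samples (frames × molecules).
    """
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[0] == 0:
        raise InsufficientDataError("label series must be (n_samples, n_dihedrals), n>=1")
    n_samples, ndih = labels.shape
    dim = 3 * ndih

    # one-hot indicators, (n_samples, ndih, 3)
    onehot = np.zeros((n_samples, ndih, 3))
    np.put_along_axis(onehot, labels[:, :, None].astype(int), 1.0, axis=2)
    flat = onehot.reshape(n_samples, dim)

    pi = flat.mean(axis=0)  # marginals, length 3*ndih
    joint = flat.T @ flat / n_samples  # pair probabilities; each 3x3 block sums to 1

    # same-dihedral blocks: p_ii = p_i on the diagonal, 0 off-diagonal
    for m in range(ndih):
        sl = slice(3 * m, 3 * m + 3)
        block = np.diag(pi[sl])
        joint[sl, sl] = block

    # Pearson correlation of conformation indicators; degenerate marginals
    # (p in {0,1}) have zero variance and contribute r = 0 off the diagonal
    var = pi - pi**2
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(np.outer(var, var))
        pearson = np.where(denom > 0, (joint - np.outer(pi, pi)) / denom, 0.0)
    np.fill_diagonal(pearson, 1.0)
    for m in range(ndih):
        sl = slice(3 * m, 3 * m + 3)
        block = np.zeros((3, 3))
        np.fill_diagonal(block, 1.0)
        pearson[sl, sl] = block

    weighted = joint * pearson
    # P_m(i): one normalisation constant per dihedral so each 3-row block sums to 1
    block_sums = weighted.reshape(ndih, 3, dim).sum(axis=(1, 2))
    if np.any(block_sums <= 0):
        raise InsufficientDataError("a dihedral has no observed conformations")
    pm = np.repeat(block_sums, 3)
    rho = weighted / pm[:, None]

    # rho = D^-1 A with A symmetric; eigenvalues are those of the similar
    # symmetric matrix D^-1/2 A D^-1/2
    d = 1.0 / np.sqrt(pm)
    sym = d[:, None] * weighted * d[None, :]
    evals = np.linalg.eigvalsh(sym)[::-1]

    return ConformationModel(
        n_dihedrals=ndih,
        marginals=pi.reshape(ndih, 3),
        joint=joint,
        pearson=pearson,
        rho=rho,
        eigenvalues=evals,
    )


def conformational_entropy(model: ConformationModel) -> float:
    """−R Σ λ ln λ over the eigenvalues of ρ, J K⁻¹ mol⁻¹.

    Eigenvalues below the clamp tolerance are dropped; negative values
    beyond −1e−6 (possible with strong anticorrelation) are logged.
    """
    lam = np.asarray(model.eigenvalues, dtype=float)
    bad = lam < CONF_NEGATIVE_WARN
    if bad.any():
        log.warning(
            "conformation matrix has %d negative eigenvalue(s), min %.3g; dropped",
            int(bad.sum()),
            float(lam.min()),
        )
    lam = lam[lam > CONF_EIGENVALUE_CLAMP]
    if lam.size == 0:
        return 0.0
    return float(-R_GAS * np.sum(lam * np.log(lam)))


def two_state_conformer_entropy(delta_e_kj_mol: float, temperature: float) -> float:
    """Mixing entropy of two conformers separated by ΔE, J K⁻¹ mol⁻¹.

    Boltzmann populations p₁ = 1/(1 + e^{−ΔE/RT}), p₂ = 1 − p₁ give
    S = −R (p₁ ln p₁ + p₂ ln p₂); ΔE = 0 yields R ln 2 ≈ 5.76.
    """
    if temperature <= 0:
        raise ConfigError(f"temperature must be > 0 K, got {temperature}")
    x = delta_e_kj_mol * 1000.0 / (R_GAS * temperature)
    p1 = 1.0 / (1.0 + np.exp(-x))
    p2 = 1.0 - p1
    s = 0.0
    for p in (p1, p2):
        if p > 0:
            s -= p * np.log(p)
    return float(R_GAS * s)


def dihedral_angles(positions: np.ndarray, quadruples: np.ndarray) -> np.ndarray:
    """Signed dihedral angles (degrees) for point quadruples.

    ``positions`` is (..., n_points, 3) and ``quadruples`` (n_dih, 4);
    broadcast over leading axes.  Sign follows the right-hand rule about
    the b2 (central) bond.
    """
    p = np.asarray(positions, dtype=float)
    q = np.asarray(quadruples, dtype=int)
    a, b, c, d = (p[..., q[:, k], :] for k in range(4))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    return np.degrees(np.arctan2(y, x))
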