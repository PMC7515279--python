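# Methods

## Model

The package computes the absolute entropy per molecule of a pure
molecular liquid from an equilibrium trajectory that carries forces, in
the multiscale cell correlation framework. Phase space is partitioned
into harmonic cells at two levels, molecule (M) and united atom (UA), and
each level contributes a vibrational part (cell stiffness, from
force/torque fluctuations) and a topographical part (cell occupancy, from
discrete orientation and conformation distributions). The six terms are
strictly additive; the translational topographical term at the molecule
level is identically zero for a pure liquid (identical molecules exchange
without change of state).

Assumptions inherited from the framework:

* the liquid is pure — every molecule in the box is an identical copy of
  the topology, and all copies pool into the same covariance estimators;
* the system is equilibrated, so mean forces and torques vanish; raw
  second moments ⟨v vᵀ⟩ are used instead of mean-subtracted covariances,
  and the accumulator warns when |mean|/rms exceeds 0.1 on any component;
* each vibrational mode is an independent quantum harmonic oscillator at
  the stiffness implied by its force (or torque) second moment;
* the mean-field cell approximation — halving of forces/torques — is
  valid only for weakly correlated degrees of freedom: molecule-level
  forces and torques and UA torques are halved, UA forces are not
  (bonded-atom force anti-correlation is carried explicitly by the UA
  force covariance matrix), and dihedral softness enters as a factor 1/4
  on the N_dih smallest retained UA force eigenvalues.

### Degree-of-freedom bookkeeping

Molecule translation always has 3 modes. Molecule rotation has 3 modes,
or 2 when the molecule is linear with respect to its united-atom centres
(collinearity tolerance 10⁻² Å maximum perpendicular deviation from the
best-fit axis on reference coordinates); a molecule of one united atom
rotates as that united atom does (nonlinear 3, linear 2, bare heavy atom
0), because at that size molecule and UA rotation coincide. UA
translation has 3N − 6 modes (3N − 5 for a UA-linear molecule), obtained
by dropping the largest 6 (or 5) eigenvalues of the 3N-dimensional UA
force covariance — those duplicate whole-molecule translation and
rotation. UA rotation keeps every per-UA torque component (3 for a
nonlinear UA, 2 for a linear one, 0 for a bare heavy atom): with that
convention the mode count closes exactly, e.g. a two-UA linear molecule
has 3 + 2 + 1 + 6 = 12 = 2 × 6 rigid-body dof. An optional
`ua_rovib_removal` switch applies the same 6/5 removal to the UA torque
spectrum for sensitivity studies; it is off by default because it would
break the closure above.

Single-UA molecules contribute nothing at the UA level. Whether such a
species (e.g. an ammonia-like pyramid, whose hydrogens break orientational
symmetry) still has orientational entropy cannot be decided from the
topology alone; it is exposed as the `single_ua_orientational` flag,
default off.

### Local frames

Molecule frames are the principal axes of inertia about the centre of
mass, ordered by descending inertia, with a deterministic sign convention
(largest-magnitude component of each of the first two axes positive,
right-handedness enforced by the third). Within degenerate inertia
subspaces (symmetric tops — relative splitting below 10⁻⁶) the
eigensolver's arbitrary basis is replaced by a canonical pair built from
the unique axis, so the frame is a deterministic function of the body
orientation; spherical tops fall back to the laboratory basis. Without
this, pooled covariances of symmetric molecules mix inconsistently
oriented bases and the spectrum loses its rotation invariance.

United-atom frames: nonlinear UAs use the principal axes of their member
atoms about the UA centre of mass; linear UAs (one hydrogen, or collinear
H–X–H) use the heavy-atom→hydrogen axis with a deterministic
perpendicular pair, contributing the two transverse torque components.

### Frequencies and entropy

Internal units are Å, kJ mol⁻¹, g mol⁻¹ and ps. A covariance eigenvalue
λ converts to SI by the single factor 10²⁹/N_A (identical for the force
and torque channels) inside ν = (1/2π)√(λ/k_B T); constants are the exact
SI values. Eigenvalues below 10⁻¹⁰ of the spectrum's largest are clamped
to zero and excluded from the mode count with a logged warning (their
classical entropy diverges); the exclusion count is reported. The QHO sum
caps x = hν/k_B T at 700 to avoid overflow — modes that stiff contribute
< 10⁻³⁰⁰ anyway.

### RAD coordination

The coordination number counts neighbours, taken in increasing
minimum-image distance, that are not angularly blocked by a closer
*accepted* neighbour: j is blocked by k when (1/r_ij)² < (1/r_ik)²·cos θ_jik.
This is the sorted, self-consistent shell definition; `rad_unsorted` lets
any closer particle block instead. Only orthorhombic boxes are supported.
Because p(N_c) converges within a handful of frames while the RAD pass is
the most expensive per-frame step, the histogram may be evaluated on every
k-th frame (`coordination_stride`, default 1 — every frame).

### Conformations

Dihedrals are all simple 4-paths of bonded united atoms; a path and its
reverse count once. Ring dihedrals are included by default (a
cyclohexane-like 6-ring has six fully correlated dihedrals); rigid rings
such as aromatics should be declared with `include_ring_dihedrals=False`,
since flexibility cannot be inferred from connectivity alone. States are
assigned as trans for |φ| > 120°, gauche− on [−120°, 0], gauche⁺ on
(0, 120°]; boundary membership is a documented convention, exact hits are
measure-zero. The correlation matrix uses pair probabilities (each
dihedral-pair 3×3 block sums to 1; same-dihedral blocks are diag(pᵢ)) and
Pearson correlations of the conformation indicators, with r ≡ 0 where a
marginal is degenerate (0 or 1 — no variance to correlate) and r_ii ≡ 1.
One normalisation constant per dihedral makes each 3-row block of ρ sum
to 1. ρ is diagonally scaled but similar to a symmetric matrix, so its
eigenvalues are computed from D^{-1/2} A D^{-1/2} with `eigvalsh`.
Eigenvalues below 10⁻¹² are dropped; negatives beyond −10⁻⁶ (possible
with strong anticorrelation) are logged and dropped.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `temperature` (K) | required | never inferred from the trajectory |
| `symmetry_number` σ | 1 (warned) | indistinguishable orientations of the UA skeleton; user input, no point-group perception |
| `single_ua_orientational` | False | grant a one-UA species orientational entropy |
| `rad_unsorted` | False | any-closer-particle RAD blocking variant |
| `ua_rovib_removal` | False | drop 6/5 largest UA torque eigenvalues |
| `coordination_stride` | 1 | RAD histogram every k-th frame |
| collinearity tolerance | 10⁻² Å | topology-level linearity decisions |
| eigenvalue clamp | 10⁻¹⁰ relative | zero-mode exclusion |

## Synthetic data

The generators produce inputs whose ground truth is known in closed form:
Gaussian net-force trajectories on static coordinates whose weighted
second moment equals a prescribed λ* (the generator inverts the
pipeline's halving convention, with a flag to disable it); a rigid
homonuclear diatomic with independent prescribed translational and
rotational frequencies (force couples perpendicular to the bond supply
the torque channel); categorical three-state dihedral series in which
each further dihedral copies the first with a prescribed probability;
and periodic point sets (seeded random with a separation floor, perfect
fcc lattices, an octahedral probe). Every generator takes an explicit
integer seed and owns its own random stream.

What the fixtures deliberately do not emulate: liquid structure beyond a
lattice of centres, coupling between translational and rotational forces,
anharmonicity, conformation-dependent force covariances, and broken
molecules across periodic boundaries under diffusion. Passing tests
therefore demonstrate that the estimators recover known stiffnesses,
coordinations and correlation structures — not that any force field
reproduces an experimental entropy.

Problem sizes: frequency-recovery and rigid-diatomic checks use 10⁵
samples (1000 frames × 100 molecules), at which prescribed frequencies
are recovered to well within 2% and decomposition terms to within 1% of
their closed forms; conformation statistics use 3·10³–6·10⁴ samples; RAD
cross-validation uses 200 seeded 50-centre configurations.

## Known limitations

* The conformational-entropy estimator −R Σ λ ln λ is exact in the
  independent, fully locked and single-dihedral limits, but at
  intermediate pair correlation with skewed marginals its value can
  *exceed* the sum of marginal entropies by up to a few J K⁻¹ mol⁻¹
  (verified with exact joint probabilities; the true joint entropy never
  does). For near-uniform or weakly correlated dihedrals — the regime the
  method was designed for — the expected small reduction is reproduced.
* trace(ρ) lies in [1, N_dih] exactly for population probabilities;
  finite samples perturb it by O(1/√n) through spurious negative Pearson
  cross terms, and bound checks use a 10/√n tolerance accordingly.
* The N_dih smallest retained UA force eigenvalues are *assumed* to be
  the dihedral modes; other soft modes (ring pucker) could be
  misidentified, and no eigenvector-projection test is attempted.
* Pure liquids only; no mixtures, no triclinic boxes, no velocities.
* UA-level rotational topographical entropy (hydrogen-bond arrangement
  counting) is not implemented — negligible for the liquids this method
  targets.
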