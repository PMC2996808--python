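# Methods

This note records the models implemented, the parameter choices that matter,
what the synthetic data does and does not emulate, and the numerical
decisions taken where the design was genuinely open.

## Elastic network model

All atoms are nodes. Every pair closer than the cutoff `C` carries an
identical Hookean spring minimised at the input geometry. Defaults:
`C = 10 Å` (large enough to damp the tip effect of peripheral atoms while
keeping the network local) and `k = 1` — the force constant is a single
global scale, so only mode shapes and eigenvalue ratios are meaningful and
no physical unit calibration is attempted. The Hessian is built in
mass-weighted coordinates with true atomic masses from a packaged
element→amu table (unknown elements fall back to carbon with a warning); a
uniform-mass variant exists for comparison.

Trivial (rigid-body) modes are identified by an eigenvalue threshold,
`|λ| < max(1e-8·λ_max, 1e-10)`, not by a fixed count; a warning fires when
the count differs from the 6 expected for a non-linear molecule (a diatomic
correctly yields 5). The absolute floor matters for the degenerate case of a
projected Hessian that is numerically zero throughout.

Mode conventions: mode 1 is the lowest non-trivial frequency; each
eigenvector's largest-magnitude component is made positive (reproducible
signs); *Cartesian* modes are the mass-weighted eigenvectors divided
componentwise by √m and renormalised to unit Euclidean norm, so a
coefficient β displaces the structure by a collective norm of β Å. Whether
an upstream mode calculator normalises before or after de-mass-weighting is
not externally standardised; this convention is a documented choice and is
used consistently by the fitting and docking layers.

### RTB

Each residue is a block contributing 3 mass-weighted rigid translations and
up to 3 rotations about its mass centre (degenerate rotations of single-atom
or collinear blocks are dropped by a singular-value threshold). Blocks have
disjoint support, so the projection matrix has orthonormal columns; the
block Hessian PᵀHP is diagonalised and eigenvectors are back-projected. As a
Rayleigh–Ritz projection, RTB eigenvalues upper-bound the exact spectrum
mode by mode — asserted in the tests.

Fidelity depends on the number of blocks: for helices of ≥ 10 residues the
RTB/exact mode-1 overlap exceeds 0.9, but for toys of ≤ 8 residues (≤ 8
blocks) the first RTB mode mixes nearby exact modes and the overlap can drop
to ~0.5–0.65. Tests of mode-shape fidelity therefore use helices of at
least 10 residues. The iterative refinement of RTB modes toward the exact
solution with per-block high-frequency corrections is out of scope.

## Overlap and least-squares fitting

Overlap is the absolute cosine between a mode and a transition vector,
restricted to the 3n′ coordinates of an atom subset. The maximum overlap
considers the first 20 modes by default (configurable, e.g. 500 for
wide-spectrum analyses). Transitions built from two crystal-like structures
in unrelated frames should be constructed with `superpose=True`, which
rigidly superposes the unbound coordinates onto the bound ones first;
without it, frame rotation dilutes the overlap (a 15° hinge rotation fixture
drops from ~0.8 to ~0.2). The hinge fixtures constructed *by displacement*
need no superposition and preserve exact overlap 1.

Least squares is solved with a rank-revealing factorisation
(`numpy.linalg.lstsq`), mathematically identical to the normal-equation
inverse at full rank and stable otherwise (least-norm solution plus a
warning when rank-deficient). The fitted deformation is applied to all
paired atoms; residuals and RMSDs are evaluated on the fitting subset. By
default the unbound structure is first superposed onto the bound one over
the fitting subset so no coefficients are spent absorbing rigid motion; a
flag disables this. Note that the 3n−6 internal modes span the orthogonal
complement of the *mass-weighted* rigid-body space: a "complete basis
reproduces the transition" statement holds exactly for equal-mass systems
after uniform-weight superposition, and to very good approximation
otherwise.

Percent RMSD reduction is reported per pair and then averaged, never
pooled. The mode of greatest influence is found by adding modes one at a
time in frequency order and recording the largest RMSD drop.

The Kolmogorov–Smirnov uniformity statistic for best-mode distributions is
evaluated on the discrete mode support (both CDFs jump only at integers).
Both the asymptotic 1% critical value `1.628/√n` and the exact
finite-sample value are reported; they differ by well under 5% at the sample
sizes of interest.

## Interaction energy

Intermolecular pairs only; no internal energy term. The pair term is
`q_i q_j/(ε r) + ε_ij[(Rmin_ij/r)¹² − 2(Rmin_ij/r)⁶]` with combination
rules `Rmin_ij = Rmin_i/2 + Rmin_j/2`, `ε_ij = √(ε_i ε_j)`, switched by
`sw(r) = (r_off−r)²(r_off+2r−3r_on)/(r_off−r_on)³` between `r_on = 7` and
`r_off = 9 Å` (applied to the combined term, not per component) and exactly
zero beyond. The Lennard-Jones minimum is −ε_ij at Rmin_ij; the attractive
term carries the standard factor 2, which that minimum condition requires.

The default dielectric is distance-dependent (ε = r), a common docking
choice that damps long-range electrostatics; a constant-ε mode is available
and the choice is prominent because it changes every energy. Parameters are
CHARMM19-style polar-hydrogen (united-atom aliphatic carbons) from a
packaged plain-text table. The table is an approximate reconstruction: van
der Waals classes follow the param19 atom types, while partial charges are
simplified but reproduce the integer net charge of every standard residue
(stated in the table's `NET` lines and asserted in tests). Missing
hydrogens are simply absent atoms — no reconstruction. Atoms not in the
table get a neutral carbon-like generic type with a warning, never a
failure.

Neighbour search: a uniform 9 Å grid cell list by default, a k-d tree
variant, and a dense double loop; the correctness contract is mutual
agreement to 1e-8 kcal/mol, which the tests assert. The docking hot loop
uses a compiled (numba) batch kernel over particle stacks that agrees with
the scalar path to round-off; a pure-numpy fallback exists. An optional
steric-relaxation hook rigidly backs a clashed ligand off along the line of
centres; it replaces nothing in the default pipeline and changes no internal
geometry.

## Swarm search

Search vector: translation (3), angle/axis orientation (1+3, converted to a
unit quaternion/rotation at decode time; the axis is renormalised after
every position update), N_r + N_l mode coefficients. The receptor stays at
the origin and deforms only along its modes; the ligand deforms in its own
frame, is rotated about its mass centre, then translated.

Parameters: population 350, ring neighbourhood k = 114 (split evenly either
side with wraparound), c1 = c2 = 2.05, r1, r2, r3 ~ U(0,1) drawn per
particle per iteration, p_rand uniform over the swarm excluding the particle
itself. Velocity clamps: 5 Å (translation), 0.2 rad (angle), 0.5 Å
(quaternion spatial terms), none for mode coefficients. Initialisation:
translations Gaussian (σ = 10 Å) around a start point, orientations uniform
on SO(3), coefficients Gaussian (σ = 3), zero velocities. Start points come
from a deterministic Fibonacci lattice on a sphere enclosing both partners
(quasi-uniform; n = 1 degenerates to the +z pole); local docking keeps the
n points nearest a reference site. Defaults of 120 points × 4 repeats
reflect the standard global protocol.

Choices where the published description is open, all configurable:

- **Inertial weight** w = 0.7298, the standard constriction-equivalent
  value for c1 = c2 = 2.05.
- **Iterations** default 300; optional stagnation stop, off by default.
- **Solis–Wets budget**: the swarm-best particle takes
  `local_search_steps` trials per iteration (default 1); the adaptive state
  persists across iterations and is re-initialised after its
  5-consecutive-contractions termination. Step sizes start at 0.5 Å
  (translation), 5° (angle), 0.25 (axis), 0.15 (mode coefficients); five
  straight successes double them, five straight failures halve them; the
  bias update is 0.6b ± 0.4d on success, b/2 on double failure. On a 2-D
  quadratic bowl a single descent reaches the minimum value to 1e-3 in
  ≥ 95% of seeds; with more search dimensions the early-termination rule
  bites sooner and restarts are advisable.
- **Final polish**: each run's best pose gets a few restarted Solis–Wets
  descents (default 3 × ≤ 3000 steps) before being returned — the
  package's stand-in for the external force-field minimisation some
  pipelines apply before clustering. Without it, energy ranking between
  near-native poses is noise-limited.
- **Mode-coefficient penalty**: an optional soft harmonic score term
  `w·Σ λ_j β_j²` approximating the internal elastic energy, off by default.
  With no internal energy at all, unbounded coefficients let the optimiser
  "wrap" soft structures around the partner for spurious contacts; the
  redocking tests therefore run with `mode_penalty_weight = 3`. Large
  weights (≳ 5 on the synthetic fixtures) are counterproductive: the
  penalty of the σ = 3 initial coefficients dominates the score and the
  swarm collapses onto the flat zero-energy region instead of searching.

Everything is a pure function of (inputs, config, seed): repeated runs are
bit-identical, and each run logs a per-iteration trace of best energy and
mean pairwise translation distance (swarm spread).

## Clustering and evaluation

Greedy, ascending energy: the lowest-energy pose seeds cluster 1; each
subsequent pose joins the first cluster whose *seed* it is within 2.5 Å of,
else it seeds a new cluster. The metric is plain ligand Cα RMSD without
superposition (the receptor frame is fixed during docking, so absolute
coordinates are comparable); ties keep input order. Representatives are the
seeds, hence strictly energy-ordered.

I RMSD follows the CAPRI convention: reference-complex interface residues
at a 5 Å any-atom contact cutoff (heavy-atom-only by flag), backbone atoms
of those residues pooled over both partners, optimal joint superposition,
then RMSD. A cluster whose representative is below 5 Å marks a correct
binding site; evaluation reports the rank of the first such cluster, the
best pose I RMSD, and both readings of "cluster size" (member counts and
number of correct clusters).

## Synthetic fixtures: what they are and are not

Chains are grown from ideal internal coordinates (NeRF), so bond geometry
is exact by construction; residues use standard names and atom sets
(backbone + amide H + Cβ), which keeps energy typing exact and every peptide
unit charge-neutral. Helices use φ = −57°, ψ = −47° (rise ≈ 1.55 Å/residue).

`make_hinge_pair` returns a two-domain helix–linker–helix chain whose bound
form is either displaced exactly along a chosen elastic mode (exact ground
truth for overlap/fitting) or rigidly rotated about the central linker.

`make_binding_pair` is a *designed* complex: a compact three-helix bundle
whose two groove walls each carry one full-side-chain aspartate aimed into
the groove — at different heights on the two walls — and a ligand helix
with two matching lysines. The two salt bridges give the native placement a
decisive electrostatic funnel and admit exactly one registration, pinning
the axial slide, spin and flip degeneracies that smooth Cβ-level helices
otherwise leave energetically degenerate. Bundle compactness keeps the
receptor's elastic network stiff (λ₁ ≈ 0.15 vs ~1e-4 for disconnected
walls), so low-frequency deformations cannot cheaply wrap the receptor
around the ligand. The bound reference is made self-consistent with the
search model: after a rigid grid placement (12 spins × 2 directions ×
translations) the complex is relaxed in the full flexible docking space
(5 + 5 RTB modes, soft coefficient penalty, weight 3 by default),
then settled with the same swarm search the pipeline uses, so the stored
bound state is the model's own optimum and carries a small induced-fit
deformation exactly representable by the docking coordinates. The unbound
ligand is the undeformed conformer rigidly displaced (equivalently: the
bound ligand with its mode-representable deformation removed, plus a random
rigid displacement). Generation verifies the bound energy is negative,
below 20 random rigid placements, and that the interface is non-empty,
retrying with perturbed geometry otherwise.

These are toys. They exercise the mathematics — Hessians, projections,
least squares, the search dynamics, clustering and scoring — but have no
packing cores, rotamers, solvation or crystallographic noise. A green test
establishes algorithmic correctness and internal consistency, not predictive
performance on real complexes; the published benchmark-scale numbers
(mean-overlap values, benchmark RMSD recoveries, cluster-size tables)
require the real benchmark structures and are outside the desk-scale test
surface.

## Known limitations

- No internal (bonded) energy; the optional harmonic coefficient penalty is
  a crude surrogate.
- CHARMM19 charge reconstruction is approximate (vdW classes faithful,
  charges simplified to correct residue net charges).
- The quaternion clamping units ("0.2 rad angle / 0.5 Å spatial") follow
  one reasonable interpretation of an under-specified convention; it is
  isolated in `SearchSpace` so alternatives can be swapped.
- Single-model PDB files only; no mmCIF, no protonation.
- The swarm's velocity rule uses the printed attractive random-particle
  term; a repulsion variant mentioned in prose elsewhere is not implemented.
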