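"""All-atom elastic network model: Hessian, exact and RTB normal modes.

The elastic network places identical Hookean springs between every pair of
atoms closer than a cutoff ``C`` (default 10 Å), with the input geometry taken
as the energy minimum:

    U_AB = 1/2 k (R_AB - R_e,AB)^2,   U = sum over pairs with R_AB < C.

The Hessian of this potential, in mass-weighted coordinates, yields normal
modes ordered by vibrational frequency. Two diagonalisation routes are
provided: exact dense diagonalisation, and the rotation-translation-of-blocks
(RTB) projection in which each residue moves as a rigid unit — a variational
approximation whose eigenvalues upper-bound the exact ones mode by mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree

from .structure import Structure


@dataclass(frozen=True)
class EnmParams:
    """Elastic network parameters.

    cutoff: spring cutoff C in Å. 10 Å is large enough to damp the tip
        effect of peripheral atoms while keeping the network sparse.
    force_constant: global spring constant k; only mode shapes and relative
        frequencies matter downstream, so k = 1 by default.
    mass_weighted: build the Hessian in mass-weighted coordinates (true
        atomic masses); a uniform-mass variant is available for comparison.
    """

    cutoff: float = 10.0
    force_constant: float = 1.0
    mass_weighted: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.force_constant <= 0:
            raise ValueError("cutoff and force constant must be positive")


@dataclass
class ModeSet:
    """Non-trivial normal modes, ascending in frequency.

    eigenvalues: mass-weighted eigenvalues (angular frequency squared, in
        units of k/amu).
    eigenvectors: (3n, m) orthonormal columns in the mass-weighted frame.
    cartesian_modes: eigenvectors divided componentwise by sqrt(mass) and
        renormalised to unit Euclidean norm — a coefficient of β Å applied to
        a column displaces the structure by a collective norm of β Å.
    method: ``exact`` or ``rtb``. Mode 1 is the lowest non-trivial mode.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    cartesian_modes: np.ndarray
    n_atoms: int
    method: str

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def mode(self, number: int) -> np.ndarray:
        """Cartesian mode vector by 1-based mode number."""
        if not 1 <= number <= self.n_modes:
            raise IndexError(f"mode {number} out of range 1..{self.n_modes}")
        return self.cartesian_modes[:, number - 1]


@dataclass
class RtbBlocks:
    """Rigid-block projection for RTB diagonalisation.

    block_assignment maps each atom to a block (default: one residue per
    block); projection is a (3n, K) matrix with orthonormal columns spanning
    the mass-weighted rigid translations/rotations of every block.
    """

    block_assignment: np.ndarray
    projection: np.ndarray


def build_hessian(s: Structure, params: EnmParams | None = None) -> np.ndarray:
    """Dense 3n x 3n elastic-network Hessian at the input geometry.

    The off-diagonal 3x3 super-element for a connected pair (A, B) is
    -k r̂ r̂ᵀ with r̂ the unit inter-atom vector; self blocks accumulate the
    negative sum over partners, which enforces translational invariance.
    Mass weighting divides element (A, B) by sqrt(m_A m_B).
    """
    params = params or EnmParams()
    n = s.n_atoms
    if n < 2:
        raise ValueError("elastic network needs at least 2 atoms")
    coords = s.coords
    H = np.zeros((3 * n, 3 * n))
    pairs = cKDTree(coords).query_pairs(params.cutoff, output_type="ndarray")
    k = params.force_constant
    for a, b in pairs:
        d = coords[a] - coords[b]
        r = np.linalg.norm(d)
        if r == 0.0:
            continue
        u = d / r
        block = k * np.outer(u, u)
        sa, sb = slice(3 * a, 3 * a + 3), slice(3 * b, 3 * b + 3)
        H[sa, sb] -= block
        H[sb, sa] -= block
        H[sa, sa] += block
        H[sb, sb] += block
    if params.mass_weighted:
        w = 1.0 / np.sqrt(np.repeat(s.masses, 3))
        H *= np.outer(w, w)
    return H


def _finish_modes(eigvals: np.ndarray, eigvecs: np.ndarray, masses: np.ndarray,
                  method: str, drop_trivial: bool,
                  expect_trivial: int = 6) -> ModeSet:
    order = np.argsort(eigvals)
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if drop_trivial:
        # relative threshold with an absolute floor (an all-rigid projected
        # Hessian is numerically zero throughout)
        tol = max(1e-8 * np.max(np.abs(eigvals), initial=0.0), 1e-10)
        trivial = np.abs(eigvals) < tol
        if trivial.sum() != expect_trivial:
            warnings.warn(
                f"{trivial.sum()} trivial modes found (expected {expect_trivial})")
        eigvals, eigvecs = eigvals[~trivial], eigvecs[:, ~trivial]
    # sign convention: largest-magnitude component positive
    eigvecs = eigvecs.copy()
    for j in range(eigvecs.shape[1]):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    cart = eigvecs / np.sqrt(np.repeat(masses, 3))[:, None]
    norms = np.linalg.norm(cart, axis=0)
    cart = cart / norms
    return ModeSet(eigenvalues=eigvals, eigenvectors=eigvecs,
                   cartesian_modes=cart, n_atoms=len(masses), method=method)


def diagonalize(H: np.ndarray, masses: np.ndarray,
                drop_trivial: bool = True) -> ModeSet:
    """Exact dense diagonalisation of a (mass-weighted) Hessian.

    Trivial rigid-body modes are identified by an eigenvalue threshold
    (|λ| < 1e-8 · max λ), not by a fixed count; a warning is emitted when the
    count differs from the 6 expected for a non-linear molecule.
    """
    H = np.asarray(H, float)
    if H.shape[0] != H.shape[1] or not np.allclose(H, H.T, atol=1e-10):
        raise ValueError("Hessian must be square and symmetric")
    try:
        eigvals, eigvecs = scipy.linalg.eigh(H)
    except scipy.linalg.LinAlgError as exc:
        raise RuntimeError(f"eigensolver failed: {exc}") from exc
    return _finish_modes(eigvals, eigvecs, np.asarray(masses, float),
                         "exact", drop_trivial)


def build_rtb(s: Structure, block_assignment: np.ndarray | None = None) -> RtbBlocks:
    """Rigid-block projection matrix (one residue per block by default).

    Each block contributes 3 mass-weighted translations plus up to 3
    rotations about its mass centre; degenerate rotations of single-atom or
    collinear blocks are dropped by a singular-value threshold. Columns of
    distinct blocks have disjoint support, so the projection is orthonormal.
    """
    if block_assignment is None:
        block_assignment = s.residue_index()
    block_assignment = np.asarray(block_assignment, dtype=int)
    if len(block_assignment) != s.n_atoms:
        raise ValueError("block assignment must cover every atom")
    n = s.n_atoms
    cols = []
    for b in np.unique(block_assignment):
        atoms = np.where(block_assignment == b)[0]
        if len(atoms) == 0:
            raise ValueError(f"block {b} is empty")
        m = s.masses[atoms]
        sq = np.sqrt(m)
        centre = np.average(s.coords[atoms], axis=0, weights=m)
        rel = s.coords[atoms] - centre
        local = np.zeros((3 * len(atoms), 6))
        for axis in range(3):
            local[axis::3, axis] = sq                      # translation
            e = np.zeros(3)
            e[axis] = 1.0
            rot = np.cross(e, rel) * sq[:, None]           # rotation
            local[:, 3 + axis] = rot.reshape(-1)
        U, sv, _ = np.linalg.svd(local, full_matrices=False)
        keep = sv > 1e-10 * sv[0]
        block_cols = np.zeros((3 * n, int(keep.sum())))
        rows = (3 * atoms[:, None] + np.arange(3)).reshape(-1)
        block_cols[rows, :] = U[:, keep]
        cols.append(block_cols)
    return RtbBlocks(block_assignment=block_assignment,
                     projection=np.hstack(cols))


def rtb_modes(H: np.ndarray, blocks: RtbBlocks, masses: np.ndarray,
              n_modes: int | None = None) -> ModeSet:
    """Diagonalise the block-projected Hessian PᵀHP and back-project.

    Returned all-atom vectors are P u (already unit norm since P has
    orthonormal columns); eigenvalues upper-bound the exact spectrum mode by
    mode (Rayleigh-Ritz).
    """
    P = blocks.projection
    Hp = P.T @ np.asarray(H, float) @ P
    Hp = 0.5 * (Hp + Hp.T)
    eigvals, eigvecs = scipy.linalg.eigh(Hp)
    modes = _finish_modes(eigvals, P @ eigvecs, np.asarray(masses, float),
                          "rtb", drop_trivial=True)
    if n_modes is not None:
        if n_modes > modes.n_modes:
            raise ValueError(
                f"requested {n_modes} modes but only {modes.n_modes} available")
        modes = ModeSet(eigenvalues=modes.eigenvalues[:n_modes],
                        eigenvectors=modes.eigenvectors[:, :n_modes],
                        cartesian_modes=modes.cartesian_modes[:, :n_modes],
                        n_atoms=modes.n_atoms, method="rtb")
    return modes


def compute_modes(s: Structure, params: EnmParams | None = None,
                  method: str = "exact", n_modes: int | None = None) -> ModeSet:
    """Convenience wrapper: Hessian + diagonalisation in one call."""
    params = params or EnmParams()
    H = build_hessian(s, params)
    masses = s.masses if params.mass_weighted else np.ones(s.n_atoms)
    if method == "exact":
        modes = diagonalize(H, masses)
        if n_modes is not None:
            if n_modes > modes.n_modes:
                raise ValueError("n_modes exceeds available modes")
            modes = ModeSet(eigenvalues=modes.eigenvalues[:n_modes],
                            eigenvectors=modes.eigenvectors[:, :n_modes],
                            cartesian_modes=modes.cartesian_modes[:, :n_modes],
                            n_atoms=modes.n_atoms, method="exact")
        return modes
    if method == "rtb":
        return rtb_modes(H, build_rtb(s), masses, n_modes=n_modes)
    raise ValueError(f"unknown method {method!r}")


def save_modes(modes: ModeSet, path) -> None:
    """Serialise a mode set to an NPZ container."""
    np.savez_compressed(path, eigenvalues=modes.eigenvalues,
                        eigenvectors=modes.eigenvectors,
                        cartesian_modes=modes.cartesian_modes,
                        n_atoms=modes.n_atoms, method=modes.method)


def load_modes(path) -> ModeSet:
    with np.load(path) as data:
        return ModeSet(eigenvalues=data["eigenvalues"],
                       eigenvectors=data["eigenvectors"],
                       cartesian_modes=data["cartesian_modes"],
                       n_atoms=int(data["n_atoms"]),
                       method=str(data["method"]))


def write_modes_text(modes: ModeSet, path) -> None:
    """Plain-text dump: one block per mode — eigenvalue line, then the 3n
    Cartesian components, one per line."""
    with open(path, "w") as fh:
        fh.write(f"# {modes.method} modes, {modes.n_atoms} atoms, "
                 f"{modes.n_modes} modes\n")
        for j in range(modes.n_modes):
            fh.write(f"MODE {j + 1} {modes.eigenvalues[j]:.12g}\n")
            for value in modes.cartesian_modes[:, j]:
                fh.write(f"{value:.9f}\n")


def rigid_body_vectors(s: Structure, mass_weighted: bool = True) -> np.ndarray:
    """Orthonormal basis of the six rigid-body motions of a structure."""
    blocks = build_rtb(s, np.zeros(s.n_atoms, dtype=int))
    if not mass_weighted:
        raise NotImplementedError("only the mass-weighted frame is provided")
    return blocks.projection
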