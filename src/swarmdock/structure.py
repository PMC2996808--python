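"""Protein structure container, PDB I/O, atom subsets and superposition.

The :class:`Structure` holds a flat, ordered list of atoms; all downstream
matrix constructions (Hessians, mode matrices, transition vectors) index into
this order, so it is never reshuffled after loading.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils import seq1

logger = logging.getLogger(__name__)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "TIP3", "SOL"})
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

#: Atomic masses in amu for common elements. Unknown elements fall back to
#: carbon with a warning (they still need a positive mass for mass weighting).
ELEMENT_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed or yields no atoms."""


@dataclass
class Structure:
    """Ordered collection of atoms with coordinates and masses.

    Atom order is stable: every matrix built from a structure addresses atoms
    by their position in these arrays.
    """

    serials: np.ndarray          # (n,) int
    names: np.ndarray            # (n,) str
    elements: np.ndarray         # (n,) str, upper-case
    res_names: np.ndarray        # (n,) str
    chain_ids: np.ndarray       # (n,) str
    res_seqnums: np.ndarray      # (n,) int
    icodes: np.ndarray           # (n,) str
    coords: np.ndarray           # (n, 3) float, Angstrom
    masses: np.ndarray           # (n,) float, amu
    is_hetero: np.ndarray        # (n,) bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residue_ids(self) -> list[tuple[str, int, str]]:
        """Per-atom residue identifiers (chain, seqnum, insertion code)."""
        return list(zip(self.chain_ids, self.res_seqnums.tolist(), self.icodes))

    def residue_index(self) -> np.ndarray:
        """Integer residue label per atom, increasing along the atom order."""
        rid = self.residue_ids()
        out = np.empty(self.n_atoms, dtype=int)
        seen: dict[tuple, int] = {}
        for i, r in enumerate(rid):
            if r not in seen:
                seen[r] = len(seen)
            out[i] = seen[r]
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        return replace(self, coords=np.array(coords, dtype=float))

    def subset(self, indices: np.ndarray) -> "Structure":
        """New structure containing only the given atoms (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return Structure(
            serials=self.serials[idx], names=self.names[idx],
            elements=self.elements[idx], res_names=self.res_names[idx],
            chain_ids=self.chain_ids[idx], res_seqnums=self.res_seqnums[idx],
            icodes=self.icodes[idx], coords=self.coords[idx],
            masses=self.masses[idx], is_hetero=self.is_hetero[idx],
        )

    def mass_center(self) -> np.ndarray:
        return np.average(self.coords, axis=0, weights=self.masses)

    def bounding_radius(self) -> float:
        """Largest distance of any atom from the mass centre."""
        return float(np.max(np.linalg.norm(self.coords - self.mass_center(), axis=1)))


@dataclass(frozen=True)
class AtomSubset:
    """Sorted atom indices into a structure, tagged by selection kind."""

    kind: str                    # all | backbone | calpha | interface | custom
    indices: np.ndarray          # sorted unique int positions

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Correspondence:
    """One-to-one atom pairing between an unbound and a bound structure."""

    pairs: np.ndarray            # (k, 2) [unbound_index, bound_index]
    aligned_residues: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        for col in (0, 1):
            if len(np.unique(self.pairs[:, col])) != len(self.pairs):
                raise ValueError("correspondence is not one-to-one")


def element_mass(element: str) -> float:
    el = element.strip().upper()
    if el in ELEMENT_MASSES:
        return ELEMENT_MASSES[el]
    warnings.warn(f"unknown element {element!r}: using carbon mass")
    return ELEMENT_MASSES["C"]


def _from_atom_array(arr: bst.AtomArray) -> Structure:
    elements = np.array([e.upper() for e in arr.element])
    masses = np.array([element_mass(e) for e in elements])
    serials = (arr.atom_id if "atom_id" in arr.get_annotation_categories()
               else np.arange(1, arr.array_length() + 1))
    return Structure(
        serials=np.asarray(serials, dtype=int),
        names=np.asarray(arr.atom_name, dtype="U6"),
        elements=elements,
        res_names=np.asarray(arr.res_name, dtype="U5"),
        chain_ids=np.asarray(arr.chain_id, dtype="U4"),
        res_seqnums=np.asarray(arr.res_id, dtype=int),
        icodes=np.asarray(arr.ins_code, dtype="U1"),
        coords=np.asarray(arr.coord, dtype=float),
        masses=masses,
        is_hetero=np.asarray(arr.hetero, dtype=bool),
    )


def read_structure(path, keep_hetero: bool = False) -> Structure:
    """Read the first model of a PDB file.

    Crystallographic waters are always removed; other hetero groups (small
    molecule ligands, ions) are kept only when ``keep_hetero`` is true.
    Alternate locations are resolved to the highest-occupancy conformer.
    """
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="occupancy",
                                extra_fields=["atom_id"])
    except Exception as exc:  # biotite reports the offending line
        raise PDBParseError(f"cannot parse PDB file {path}: {exc}") from exc
    keep = ~np.isin(arr.res_name, list(WATER_NAMES))
    if not keep_hetero:
        keep &= ~arr.hetero
    arr = arr[keep]
    if arr.array_length() == 0:
        raise PDBParseError(f"no atoms left after filtering in {path}")
    return _from_atom_array(arr)


def write_structure(s: Structure, path) -> None:
    """Write a structure as a single-model PDB file."""
    arr = bst.AtomArray(s.n_atoms)
    arr.coord = s.coords.astype(np.float32)
    arr.set_annotation("atom_name", s.names)
    arr.set_annotation("element", s.elements)
    arr.set_annotation("res_name", s.res_names)
    arr.set_annotation("chain_id", s.chain_ids)
    arr.set_annotation("res_id", s.res_seqnums)
    arr.set_annotation("ins_code", s.icodes)
    arr.set_annotation("hetero", s.is_hetero)
    arr.set_annotation("atom_id", s.serials)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def merge_structures(a: Structure, b: Structure,
                     chain_a: str | None = None,
                     chain_b: str | None = None) -> Structure:
    """Concatenate two structures into one (e.g. to form a complex)."""
    def _chains(s, c):
        return np.full(s.n_atoms, c, dtype="U4") if c else s.chain_ids
    return Structure(
        serials=np.concatenate([a.serials, b.serials + a.serials.max()]),
        names=np.concatenate([a.names, b.names]),
        elements=np.concatenate([a.elements, b.elements]),
        res_names=np.concatenate([a.res_names, b.res_names]),
        chain_ids=np.concatenate([_chains(a, chain_a), _chains(b, chain_b)]),
        res_seqnums=np.concatenate([a.res_seqnums, b.res_seqnums]),
        icodes=np.concatenate([a.icodes, b.icodes]),
        coords=np.vstack([a.coords, b.coords]),
        masses=np.concatenate([a.masses, b.masses]),
        is_hetero=np.concatenate([a.is_hetero, b.is_hetero]),
    )


def select_subset(s: Structure, kind: str) -> AtomSubset:
    """Select ``all`` (non-hetero), ``backbone`` or ``calpha`` atoms.

    Hetero atoms (small molecules) take part in the elastic network but are
    excluded from reported subsets; hydrogens are excluded from backbone and
    Cα selections by name.
    """
    not_het = ~s.is_hetero
    if kind == "all":
        mask = not_het
    elif kind == "backbone":
        mask = not_het & np.isin(s.names, list(BACKBONE_NAMES)) & (s.elements != "H")
    elif kind == "calpha":
        mask = not_het & (s.names == "CA") & (s.elements == "C")
    else:
        raise ValueError(f"unknown subset kind {kind!r}")
    return AtomSubset(kind=kind, indices=np.where(mask)[0])


def find_interface(receptor: Structure, ligand: Structure,
                   cutoff: float = 6.0) -> tuple[AtomSubset, AtomSubset]:
    """Interface residues: any residue with a heavy atom within ``cutoff``
    of a partner heavy atom. Returns all atoms of those residues on each side.
    """
    heavy_r = np.where(receptor.elements != "H")[0]
    heavy_l = np.where(ligand.elements != "H")[0]
    out = []
    if len(heavy_r) and len(heavy_l):
        tree_r = cKDTree(receptor.coords[heavy_r])
        tree_l = cKDTree(ligand.coords[heavy_l])
        pairs = tree_r.query_ball_tree(tree_l, r=cutoff)
        contact_r = np.array([i for i, hits in zip(heavy_r, pairs) if hits], dtype=int)
        contact_l = np.array(sorted({heavy_l[j] for hits in pairs for j in hits}), dtype=int)
    else:
        contact_r = contact_l = np.array([], dtype=int)
    for s, contacts in ((receptor, contact_r), (ligand, contact_l)):
        res = s.residue_index()
        touched = set(res[contacts].tolist())
        idx = np.where(np.isin(res, list(touched)))[0] if touched else np.array([], int)
        out.append(AtomSubset(kind="interface", indices=idx))
    return out[0], out[1]


_STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL MSE".split()
)


def _chain_residues(s: Structure, chain: str):
    """(residue_key, res_name, atom index list) for standard residues of a chain."""
    res_idx = s.residue_index()
    out: dict[int, list[int]] = {}
    for i in np.where(s.chain_ids == chain)[0]:
        if s.is_hetero[i] or s.res_names[i] not in _STANDARD_AA:
            continue
        out.setdefault(int(res_idx[i]), []).append(int(i))
    items = sorted(out.items())
    return [(s.res_names[idx[0]], idx) for _, idx in items]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # do not penalise terminal gaps: truncated constructs are common
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def map_correspondence(unbound: Structure, bound: Structure) -> Correspondence:
    """Pair atoms of the unbound and bound forms via per-chain sequence
    alignment.

    Non-matching residues are excluded from the pairing (the elastic network
    elsewhere still uses every unbound atom). For aligned residues of equal
    type, all atoms present on both sides are paired by name; for substituted
    residues only the backbone atoms are paired.
    """
    chains_u = list(dict.fromkeys(unbound.chain_ids.tolist()))
    chains_b = list(dict.fromkeys(bound.chain_ids.tolist()))
    shared = [c for c in chains_u if c in chains_b]
    chain_pairs = ([(c, c) for c in shared] if shared
                   else list(zip(chains_u, chains_b)))
    aligner = _make_aligner()
    pairs: list[tuple[int, int]] = []
    aligned_residues: list[tuple[tuple, tuple]] = []
    for cu, cb in chain_pairs:
        res_u = _chain_residues(unbound, cu)
        res_b = _chain_residues(bound, cb)
        if not res_u or not res_b:
            continue
        seq_u = "".join(seq1(name, undef_code="X") for name, _ in res_u)
        seq_b = "".join(seq1(name, undef_code="X") for name, _ in res_b)
        aln = aligner.align(seq_u, seq_b)[0]
        matched = 0
        n_aligned = 0
        for (us, ue), (bs, be) in zip(*aln.aligned):
            for off in range(ue - us):
                iu, ib = us + off, bs + off
                name_u, atoms_u = res_u[iu]
                name_b, atoms_b = res_b[ib]
                n_aligned += 1
                if name_u == name_b:
                    matched += 1
                    allowed = None
                else:
                    allowed = BACKBONE_NAMES
                by_name_b = {bound.names[j]: j for j in atoms_b}
                for i in atoms_u:
                    nm = unbound.names[i]
                    if allowed is not None and nm not in allowed:
                        continue
                    if nm in by_name_b:
                        pairs.append((i, by_name_b[nm]))
                ru = (cu, int(unbound.res_seqnums[atoms_u[0]]), unbound.icodes[atoms_u[0]])
                rb = (cb, int(bound.res_seqnums[atoms_b[0]]), bound.icodes[atoms_b[0]])
                aligned_residues.append((ru, rb))
        if n_aligned and matched / n_aligned < 0.30:
            logger.warning(
                "chain %s/%s alignment identity %.0f%% < 30%%",
                cu, cb, 100 * matched / n_aligned)
    return Correspondence(pairs=np.array(pairs, dtype=int).reshape(-1, 2),
                          aligned_residues=aligned_residues)


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t)`` with ``mobile @ R.T + t`` the superposed coordinates.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - cm @ R.T
    return R, t


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    R, t = kabsch(mobile, target)
    return mobile @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray, superpose_first: bool = False) -> float:
    """Root-mean-square deviation between two equal-length coordinate sets."""
    a = np.asarray(a, float).reshape(-1, 3)
    b = np.asarray(b, float).reshape(-1, 3)
    if a.shape != b.shape or len(a) == 0:
        raise ValueError("coordinate sets must have equal, nonzero atom counts")
    if superpose_first:
        a = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
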