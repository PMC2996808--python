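"""Clustering of docked poses, interface RMSD and run evaluation.

Poses are clustered greedily in ascending energy order: the lowest-energy
pose seeds the first cluster, every later pose joins the first cluster whose
*seed* it is within the RMSD threshold of (2.5 Å by default), otherwise it
seeds a new cluster. The seed, being the lowest-energy member, is the
cluster's representative, so representatives are strictly ordered by energy.

Pose quality against a reference complex uses interface RMSD (I RMSD), the
CAPRI convention: interface residues are those with any atom pair within 5 Å
of the partner in the reference complex; I RMSD is the minimum RMSD over the
backbone atoms of those residues after optimal joint superposition. A cluster
with representative I RMSD < 5 Å marks a correct binding site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import (BACKBONE_NAMES, AtomSubset, Structure, rmsd,
                        superpose)


@dataclass
class Cluster:
    representative_index: int     # index into the input pose list
    energy: float
    member_indices: list


@dataclass
class ClusterReport:
    clusters: list                # ordered by representative energy
    assignment: np.ndarray        # pose index -> cluster rank-1 index

    @property
    def ranked_energies(self) -> list:
        return [c.energy for c in self.clusters]


def cluster_poses(ligand_coords, energies, threshold: float = 2.5,
                  atom_indices=None) -> ClusterReport:
    """Greedy energy-ordered clustering of ligand poses.

    The metric is plain ligand RMSD (no superposition): the receptor frame is
    fixed during docking, so pose differences are meaningful in absolute
    coordinates. ``atom_indices`` restricts the RMSD to a subset (e.g. Cα).
    Ties in energy keep input order (stable sort).
    """
    coords = [np.asarray(c, float) for c in ligand_coords]
    energies = np.asarray(energies, float)
    if len(coords) == 0 or len(coords) != len(energies):
        raise ValueError("need one energy per pose, at least one pose")
    sel = (np.asarray(atom_indices, int) if atom_indices is not None
           else np.arange(coords[0].shape[0]))
    order = np.argsort(energies, kind="stable")
    seeds: list[int] = []
    clusters: list[Cluster] = []
    assignment = np.empty(len(coords), dtype=int)
    for pose in order:
        placed = False
        for ci, seed in enumerate(seeds):
            if rmsd(coords[pose][sel], coords[seed][sel]) <= threshold:
                clusters[ci].member_indices.append(int(pose))
                assignment[pose] = ci
                placed = True
                break
        if not placed:
            seeds.append(int(pose))
            clusters.append(Cluster(representative_index=int(pose),
                                    energy=float(energies[pose]),
                                    member_indices=[int(pose)]))
            assignment[pose] = len(seeds) - 1
    return ClusterReport(clusters=clusters, assignment=assignment)


def reference_interface(ref_receptor: Structure, ref_ligand: Structure,
                        cutoff: float = 5.0, heavy_only: bool = False):
    """Backbone atom indices of the reference complex's interface residues.

    Contacts use all atoms by default (hydrogens included when present);
    ``heavy_only`` restricts contact detection to non-hydrogen atoms.
    """
    sel_r = np.arange(ref_receptor.n_atoms)
    sel_l = np.arange(ref_ligand.n_atoms)
    if heavy_only:
        sel_r = sel_r[ref_receptor.elements != "H"]
        sel_l = sel_l[ref_ligand.elements != "H"]
    pairs = cKDTree(ref_receptor.coords[sel_r]).query_ball_tree(
        cKDTree(ref_ligand.coords[sel_l]), r=cutoff)
    contact_r = [sel_r[i] for i, hits in enumerate(pairs) if hits]
    contact_l = sorted({sel_l[j] for hits in pairs for j in hits})
    out = []
    for s, contacts in ((ref_receptor, contact_r), (ref_ligand, contact_l)):
        res = s.residue_index()
        touched = set(res[np.asarray(contacts, int)].tolist()) if contacts else set()
        bb = (np.isin(s.names, list(BACKBONE_NAMES)) & (s.elements != "H")
              & np.isin(res, list(touched)))
        out.append(np.where(bb)[0])
    if len(out[0]) == 0 and len(out[1]) == 0:
        raise ValueError("reference complex has no interface residues")
    return out[0], out[1]


def interface_rmsd(pred_receptor_coords, pred_ligand_coords,
                   ref_receptor: Structure, ref_ligand: Structure,
                   cutoff: float = 5.0, heavy_only: bool = False) -> float:
    """I RMSD of a predicted pose against the reference complex.

    Prediction coordinates must follow the reference atom order (the usual
    redocking situation). Receptor and ligand interface backbones are pooled
    and superposed jointly before the RMSD.
    """
    idx_r, idx_l = reference_interface(ref_receptor, ref_ligand,
                                       cutoff=cutoff, heavy_only=heavy_only)
    pred = np.vstack([np.asarray(pred_receptor_coords, float)[idx_r],
                      np.asarray(pred_ligand_coords, float)[idx_l]])
    ref = np.vstack([ref_receptor.coords[idx_r], ref_ligand.coords[idx_l]])
    return rmsd(superpose(pred, ref), ref)


@dataclass
class RunEvaluation:
    rank_first_correct: int | None      # 1-based cluster rank, None if no hit
    best_irmsd: float                   # minimum I RMSD over all poses
    correct_cluster_sizes: list         # member counts of correct clusters
    n_correct_clusters: int
    representative_irmsds: list


def evaluate_run(report: ClusterReport, poses,
                 ref_receptor: Structure, ref_ligand: Structure,
                 correct_threshold: float = 5.0) -> RunEvaluation:
    """Score a clustered docking run against the reference complex.

    ``poses`` is the list of (receptor coords, ligand coords) the report was
    built from. A cluster is *correct* when its representative's I RMSD is
    below ``correct_threshold``; both the member counts and the number of
    such clusters are reported (the two readings of "cluster size").
    """
    rep_irmsds = []
    for c in report.clusters:
        rec, lig = poses[c.representative_index]
        rep_irmsds.append(interface_rmsd(rec, lig, ref_receptor, ref_ligand))
    all_irmsds = [interface_rmsd(rec, lig, ref_receptor, ref_ligand)
                  for rec, lig in poses]
    correct = [i for i, v in enumerate(rep_irmsds) if v < correct_threshold]
    return RunEvaluation(
        rank_first_correct=(correct[0] + 1) if correct else None,
        best_irmsd=float(min(all_irmsds)),
        correct_cluster_sizes=[len(report.clusters[i].member_indices)
                               for i in correct],
        n_correct_clusters=len(correct),
        representative_irmsds=rep_irmsds,
    )
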