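"""Consensus analysis of experimental waters across aligned structures.

Waters deposited with several independent structures of the same protein
are superposed into a common frame, pooled within an aggregation shell
of the reference protomer, grouped by single-linkage clustering (two
waters are connected when strictly less than ``link_cutoff`` apart),
restricted to the first hydration shell, and classified as
high-consensus when seen in at least ``high_threshold`` distinct
structures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .model import (
    DegenerateGeometryError,
    SoluteStructure,
    ValidationError,
)
from .structure_io import StructureRecord, pdb_atom_line

__all__ = [
    "RigidTransform",
    "ConsensusCluster",
    "superpose",
    "aggregate_waters",
    "cluster_waters",
    "filter_first_shell",
    "classify_consensus",
    "write_clusters_csv",
    "write_clusters_pdb",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation mapping mobile coordinates into the
    reference frame: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation


@dataclass
class ConsensusCluster:
    """A cross-structure water cluster.

    ``n_structures`` counts *distinct* source structures (a single
    structure depositing two waters closer than the linkage cutoff still
    contributes one), which is what bounds cluster sizes by the number
    of input structures.
    """

    members: list[tuple[str, np.ndarray]]
    n_structures: int
    mean_position: np.ndarray
    consensus_class: str | None = None


def _pair_atoms(
    mobile: SoluteStructure,
    reference: SoluteStructure,
    atom_selection: str,
    mobile_chain: str | None,
    reference_chain: str | None,
) -> tuple[np.ndarray, np.ndarray]:
    if atom_selection == "all":
        if len(mobile) != len(reference):
            raise ValidationError(
                "atom_selection='all' needs equal atom counts "
                f"({len(mobile)} vs {len(reference)})"
            )
        return mobile.coords, reference.coords
    # default: Calpha atoms of one chain, paired by residue number
    mob = mobile.chain(mobile_chain or mobile.chains[0])
    ref = reference.chain(reference_chain or reference.chains[0])

    def ca_map(s: SoluteStructure) -> dict[int, np.ndarray]:
        return {
            s.residue_ids[i]: s.coords[i]
            for i in range(len(s))
            if s.atom_names[i].strip().upper() == atom_selection.upper()
        }

    mmap, rmap = ca_map(mob), ca_map(ref)
    common = sorted(set(mmap) & set(rmap))
    if len(common) < 3:
        raise ValidationError(
            f"need >=3 paired {atom_selection} atoms, found {len(common)}"
        )
    return (
        np.array([mmap[k] for k in common]),
        np.array([rmap[k] for k in common]),
    )


def superpose(
    mobile: SoluteStructure,
    reference: SoluteStructure,
    atom_selection: str = "CA",
    mobile_chain: str | None = None,
    reference_chain: str | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of *mobile* onto
    *reference*.

    Returns the transform and the post-fit RMSD over the paired atoms.
    ``atom_selection`` is an atom name (paired by residue number within
    one chain, default Calpha) or ``"all"`` (paired by index).
    """
    mob, ref = _pair_atoms(
        mobile, reference, atom_selection, mobile_chain, reference_chain
    )
    if len(mob) < 3:
        raise ValidationError("need >=3 paired atoms for superposition")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    p, q = mob - mc, ref - rc
    svals = np.linalg.svd(p.T @ q, compute_uv=False)
    if svals[1] <= 1e-8 * max(svals[0], 1.0):
        raise DegenerateGeometryError(
            "superposition selection is (near-)collinear; rotation is "
            "not determined"
        )
    rot, rssd = Rotation.align_vectors(q, p)
    R = rot.as_matrix()
    transform = RigidTransform(rotation=R, translation=rc - R @ mc)
    rmsd = float(rssd / np.sqrt(len(mob)))
    return transform, rmsd


def aggregate_waters(
    records: Sequence[StructureRecord],
    reference: StructureRecord,
    shell: float = 4.0,
    atom_selection: str = "CA",
    reference_chain: str | None = None,
) -> list[tuple[str, np.ndarray]]:
    """Pool waters from all *records*, superposed onto *reference*, and
    keep those within *shell* of any atom of the reference protomer.

    The protomer defaults to the first chain of the reference solute.
    Returns (structure id, position) pairs with provenance preserved.
    """
    chain_id = reference_chain or reference.solute.chains[0]
    protomer = reference.solute.chain(chain_id)
    tree = cKDTree(protomer.coords)
    out: list[tuple[str, np.ndarray]] = []
    for rec in records:
        if len(rec.waters) == 0:
            continue
        transform, _ = superpose(
            rec.solute,
            reference.solute,
            atom_selection=atom_selection,
            reference_chain=chain_id,
        )
        moved = transform.apply(rec.waters)
        dist, _ = tree.query(moved)
        for pos in moved[dist <= shell]:
            out.append((rec.id, pos))
    return out


def cluster_waters(
    waters: Sequence[tuple[str, np.ndarray]],
    link_cutoff: float = 1.0,
) -> list[ConsensusCluster]:
    """Single-linkage clustering: connected components of the graph that
    joins water pairs strictly closer than *link_cutoff*."""
    if not waters:
        return []
    ids = [sid for sid, _ in waters]
    coords = np.asarray([p for _, p in waters], dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("water coordinates must be finite")
    n = len(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=link_cutoff, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < link_cutoff]  # strict "less than"
    if len(pairs):
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        graph = coo_matrix((n, n))
    _, labels = connected_components(graph, directed=False)
    clusters: list[ConsensusCluster] = []
    for lab in range(labels.max() + 1):
        idx = np.flatnonzero(labels == lab)
        members = [(ids[i], coords[i]) for i in idx]
        clusters.append(
            ConsensusCluster(
                members=members,
                n_structures=len({ids[i] for i in idx}),
                mean_position=coords[idx].mean(axis=0),
            )
        )
    return clusters


def filter_first_shell(
    clusters: Sequence[ConsensusCluster],
    solute: SoluteStructure,
    cutoff: float = 3.25,
) -> list[ConsensusCluster]:
    """Keep clusters whose mean position lies within *cutoff* of any
    solute atom (inclusive); farther clusters are outside the first
    hydration shell and discarded."""
    if len(solute) == 0:
        raise ValidationError("solute must be non-empty for shell filtering")
    if not clusters:
        return []
    tree = cKDTree(solute.coords)
    means = np.asarray([c.mean_position for c in clusters])
    dist, _ = tree.query(means)
    return [c for c, d in zip(clusters, dist) if d <= cutoff]


def classify_consensus(
    clusters: Sequence[ConsensusCluster],
    high_threshold: int = 5,
) -> list[ConsensusCluster]:
    """Label clusters ``high`` when seen in >= *high_threshold* distinct
    structures, else ``lower``."""
    if high_threshold < 1:
        raise ValidationError("high_threshold must be >= 1")
    return [
        replace(
            c,
            consensus_class="high" if c.n_structures >= high_threshold else "lower",
        )
        for c in clusters
    ]


def write_clusters_csv(clusters: Sequence[ConsensusCluster], path) -> None:
    """CSV of cluster means, sizes, classes, and member provenance."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["cluster", "x", "y", "z", "n_structures", "n_members",
             "consensus_class", "members"]
        )
        for i, c in enumerate(clusters, start=1):
            writer.writerow(
                [
                    i,
                    f"{c.mean_position[0]:.4f}",
                    f"{c.mean_position[1]:.4f}",
                    f"{c.mean_position[2]:.4f}",
                    c.n_structures,
                    len(c.members),
                    c.consensus_class or "",
                    ";".join(sid for sid, _ in c.members),
                ]
            )


def write_clusters_pdb(clusters: Sequence[ConsensusCluster], path) -> None:
    """PDB of cluster mean positions, n_structures in the occupancy
    column (high-consensus clusters are easy to isolate by occupancy)."""
    lines = ["REMARK   6 HYDROSITE CONSENSUS CLUSTERS (OCCUPANCY = N_STRUCTURES)"]
    for i, c in enumerate(clusters, start=1):
        lines.append(
            pdb_atom_line(
                i, "O", "HOH", "W", i, c.mean_position,
                occupancy=float(c.n_structures), het=True, element="O",
            )
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
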