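"""Docking-pose post-processing: RMSD clustering, hit selection, compound
ranking, binding-pocket residue enumeration and grid-box definition.

Poses from one docking run share the receptor coordinate frame, so
pose–pose RMSD is computed directly on coordinates *without* rigid
superposition — two poses in different sub-sites must not be superposed
into agreement. Equivalent-atom permutations (molecular symmetry) are
ignored.

Compounds are ranked by their largest cluster first (maximum number of
conformations) and by best predicted binding energy second: a compound
whose poses pile into one big low-energy cluster outranks one with a
single lucky pose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptyInputError, PoseMismatchError
from .ranges import format_ranges
from .structio import Frame, Pose

__all__ = [
    "GridBox",
    "PoseCluster",
    "CompoundRanking",
    "cluster_poses",
    "select_hit",
    "rank_compounds",
    "pocket_residues",
    "pocket_residue_ranges",
    "make_grid_box",
    "DEFAULT_POSE_RMSD_CUTOFF_A",
    "DEFAULT_POCKET_CUTOFF_A",
]

#: pose-clustering RMSD cutoff (Å); docking-community convention
DEFAULT_POSE_RMSD_CUTOFF_A = 2.0
#: receptor-atom to pose-atom distance defining pocket membership (Å)
DEFAULT_POCKET_CUTOFF_A = 4.0


@dataclass(frozen=True)
class GridBox:
    """Axis-aligned docking search volume."""

    center: np.ndarray  # (3,) Å
    size: np.ndarray    # (3,) Å
    spacing_A: float = 1.0
    points: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "size", np.asarray(self.size, dtype=float))


@dataclass
class PoseCluster:
    """Spatially coherent family of poses of one compound."""

    member_poses: list[Pose]
    representative: Pose

    @property
    def size(self) -> int:
        return len(self.member_poses)

    @property
    def best_energy(self) -> float:
        return min(p.energy_kcal_mol for p in self.member_poses)


@dataclass
class CompoundRanking:
    """Ranked compounds: (compound_id, largest cluster size, best energy, rank)."""

    table: pd.DataFrame  # columns: compound_id, largest_cluster_size, best_energy, rank

    def order(self) -> list[str]:
        return list(self.table["compound_id"])


def _pose_rmsd(a: Pose, b: Pose) -> float:
    ca, cb = a.coords, b.coords
    if ca.shape != cb.shape:
        raise PoseMismatchError(
            f"poses {a.compound_id}/{a.model_index} and {b.compound_id}/"
            f"{b.model_index} have different atom counts"
        )
    d = ca - cb
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def cluster_poses(
    poses: Sequence[Pose],
    rmsd_cutoff_A: float = DEFAULT_POSE_RMSD_CUTOFF_A,
) -> list[PoseCluster]:
    """Greedy energy-ordered clustering of poses by coordinate RMSD.

    Poses are visited by ascending docking score; each joins the first
    cluster whose representative (its seed — necessarily that cluster's
    lowest-energy member) is within ``rmsd_cutoff_A``, otherwise it seeds
    a new cluster. Clusters are returned by descending size, ties broken
    by better (lower) best energy.
    """
    if not poses:
        raise EmptyInputError("no poses to cluster")
    if rmsd_cutoff_A <= 0:
        raise ValueError("rmsd_cutoff_A must be positive")
    n_atoms = len(poses[0].atoms)
    for p in poses:
        if len(p.atoms) != n_atoms:
            raise PoseMismatchError(
                f"pose {p.compound_id}/{p.model_index} has {len(p.atoms)} atoms, "
                f"expected {n_atoms}"
            )
    order = sorted(
        poses,
        key=lambda p: (p.energy_kcal_mol, p.compound_id, p.model_index),
    )
    clusters: list[PoseCluster] = []
    for pose in order:
        for cl in clusters:
            if _pose_rmsd(pose, cl.representative) <= rmsd_cutoff_A:
                cl.member_poses.append(pose)
                break
        else:
            clusters.append(PoseCluster(member_poses=[pose], representative=pose))
    clusters.sort(key=lambda c: (-c.size, c.best_energy,
                                 c.representative.compound_id,
                                 c.representative.model_index))
    return clusters


def select_hit(clusters: Sequence[PoseCluster]) -> Pose:
    """Representative (lowest-energy member) of the largest cluster.

    Size ties are broken by lower best energy, then lexicographically by
    the representative's compound and model identifiers.
    """
    if not clusters:
        raise EmptyInputError("no clusters to select from")
    best = min(
        clusters,
        key=lambda c: (-c.size, c.best_energy,
                       c.representative.compound_id,
                       c.representative.model_index),
    )
    return best.representative


def rank_compounds(
    per_compound: Mapping[str, Sequence[PoseCluster]],
) -> CompoundRanking:
    """Total order over compounds: largest cluster size desc, best energy
    asc, compound id asc; ranks 1..n."""
    if not per_compound:
        raise EmptyInputError("no compounds to rank")
    rows = []
    for cid, clusters in per_compound.items():
        if not clusters:
            raise EmptyInputError(f"compound {cid} has no clusters")
        largest = max(c.size for c in clusters)
        best = min(c.best_energy for c in clusters)
        rows.append((cid, largest, best))
    rows.sort(key=lambda r: (-r[1], r[2], r[0]))
    table = pd.DataFrame(rows, columns=["compound_id", "largest_cluster_size",
                                        "best_energy"])
    table["rank"] = np.arange(1, len(rows) + 1)
    return CompoundRanking(table=table)


def pocket_residues(
    receptor: Frame,
    poses: Sequence[Pose],
    cutoff_A: float = DEFAULT_POCKET_CUTOFF_A,
) -> dict[str, list[int]]:
    """Receptor residues with any atom within ``cutoff_A`` of any pose atom.

    Returns sorted residue numbers per chain. An empty pose list yields an
    empty footprint (not an error). Receptor and poses must share one
    coordinate frame.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff_A must be positive")
    if not poses:
        return {}
    pose_coords = np.vstack([p.coords for p in poses])
    tree = cKDTree(pose_coords)
    rec_coords = receptor.coords
    near = tree.query_ball_point(rec_coords, r=cutoff_A)
    out: dict[str, set[int]] = {}
    for atom, hits in zip(receptor.atoms, near):
        if hits:
            out.setdefault(atom.chain_id, set()).add(atom.residue_number)
    return {chain: sorted(nums) for chain, nums in sorted(out.items())}


def pocket_residue_ranges(
    receptor: Frame,
    poses: Sequence[Pose],
    cutoff_A: float = DEFAULT_POCKET_CUTOFF_A,
) -> dict[str, str]:
    """Pocket footprint formatted as per-chain residue ranges ("515–536")."""
    return {
        chain: format_ranges(nums)
        for chain, nums in pocket_residues(receptor, poses, cutoff_A).items()
    }


def make_grid_box(
    center: Sequence[float],
    size: Sequence[float],
    spacing_A: float = 1.0,
) -> GridBox:
    """Validated grid box; per-axis point count is floor(size/spacing)+1."""
    center = np.asarray(center, dtype=float)
    size = np.asarray(size, dtype=float)
    if center.shape != (3,) or size.shape != (3,):
        raise ValueError("center and size must be 3-vectors")
    if spacing_A <= 0:
        raise ValueError("spacing_A must be positive")
    if np.any(size <= 0):
        raise ValueError("grid box sizes must be positive")
    points = tuple(int(np.floor(s / spacing_A)) + 1 for s in size)
    return GridBox(center=center, size=size, spacing_A=spacing_A, points=points)
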