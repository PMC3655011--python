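"""Trajectory post-analysis: superposition, RMSD series, intermolecular
contact persistence, residue histograms and frame clustering.

The central operation is the persistent-contact screen: for every pair of
atoms on different chains, count the fraction of analysed frames in which
their distance is within a threshold (3 Å by default). Pairs whose
fraction strictly exceeds a persistence cutoff (0.90 by default — the
fraction must *exceed* the cutoff, so a pair present in exactly 90% of
frames is not persistent) are reported and aggregated into residue-level
histograms and per-chain interface residue lists.

Boundary semantics, tested explicitly:

* distance comparison is inclusive (d <= threshold counts as a contact);
* persistence comparison is strict (fraction > persistence).

By default every atom, including hydrogens, participates in the distance
search (the simulated systems are all-atom); ``heavy_atoms_only`` restricts
the search to non-hydrogen atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import EmptyInputError, GeometryError, UnknownChainError
from .structio import Frame, Trajectory

__all__ = [
    "ContactAtom",
    "ContactEvent",
    "PersistentContact",
    "ContactHistogram",
    "FrameClustering",
    "RigidTransform",
    "superpose",
    "rmsd_series",
    "find_contacts",
    "persistent_contacts",
    "residue_histogram",
    "interface_residues",
    "donor_acceptor_subset",
    "cluster_frames",
    "DEFAULT_CONTACT_THRESHOLD_A",
    "DEFAULT_PERSISTENCE",
    "DEFAULT_SKIP_FRACTION",
]

#: distance threshold (Å) below/at which two atoms are in contact
DEFAULT_CONTACT_THRESHOLD_A = 3.0
#: fraction of analysed frames a contact must exceed to count as persistent
DEFAULT_PERSISTENCE = 0.90
#: fraction of leading frames excluded from analysis (equilibration)
DEFAULT_SKIP_FRACTION = 0.30


@dataclass(frozen=True, order=True)
class ContactAtom:
    """Identity of one atom participating in a contact."""

    chain_id: str
    residue_number: int
    residue_name: str
    name: str
    element: str = ""

    def label(self) -> str:
        return (f"{self.chain_id}/{self.residue_name.capitalize()}"
                f"{self.residue_number}/{self.name}")


@dataclass(frozen=True)
class ContactEvent:
    """One atom pair within the distance threshold in one frame."""

    atom_i: ContactAtom
    atom_j: ContactAtom
    frame_index: int
    distance_A: float


@dataclass(frozen=True)
class PersistentContact:
    """An atom pair in contact in a (large) fraction of analysed frames."""

    atom_i: ContactAtom
    atom_j: ContactAtom
    n_frames_present: int
    n_frames_total: int
    persistence_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_frames_total <= 0:
            raise ValueError("n_frames_total must be positive")
        object.__setattr__(
            self, "persistence_fraction",
            self.n_frames_present / self.n_frames_total,
        )


@dataclass
class ContactHistogram:
    """Residue-pair contact fractions for one chain pair.

    ``bins`` maps (residue_i, residue_j) — each a (chain, number, name)
    triple — to the fraction of frames in which at least one atom pair of
    that residue pair was in contact. ``persistent`` flags bins whose
    fraction strictly exceeds the persistence cutoff.
    """

    chain_pair: tuple[str, str] | None
    n_frames: int
    bins: dict[tuple, float]
    persistent: dict[tuple, bool]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain_i": ri[0], "residue_number_i": ri[1], "residue_name_i": ri[2],
                "chain_j": rj[0], "residue_number_j": rj[1], "residue_name_j": rj[2],
                "fraction": frac, "persistent": self.persistent[(ri, rj)],
            }
            for (ri, rj), frac in sorted(self.bins.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["chain_i", "residue_number_i", "residue_name_i",
                     "chain_j", "residue_number_j", "residue_name_j",
                     "fraction", "persistent"],
        )


@dataclass
class FrameClustering:
    """Greedy-centroid clustering of trajectory frames."""

    assignments: dict[int, int]       # frame index -> cluster id
    centroids: dict[int, np.ndarray]  # cluster id -> (n_atoms, 3) coordinates
    dispersion_A: dict[int, float]    # cluster id -> mean member-centroid RMSD
    sizes: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


@dataclass(frozen=True)
class RigidTransform:
    """y = R x + t, with R a proper rotation (no reflection)."""

    rotation: np.ndarray     # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _check_nondegenerate(coords: np.ndarray, which: str) -> None:
    if coords.shape[0] < 3:
        raise GeometryError(f"{which}: need at least 3 atoms, got {coords.shape[0]}")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    if s[1] / scale < 1e-8:
        raise GeometryError(f"{which}: collinear (degenerate) atom selection")


def _coords_of(frame_or_coords) -> np.ndarray:
    if isinstance(frame_or_coords, Frame):
        return frame_or_coords.coords
    return np.asarray(frame_or_coords, dtype=float)


def superpose(
    mobile: Frame | np.ndarray,
    reference: Frame | np.ndarray,
    selection: Sequence[int] | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of mobile onto reference.

    Returns the proper-rotation rigid transform minimizing the coordinate
    RMSD over the selected atoms, and the post-fit RMSD in Å. Reflections
    are excluded; selections with fewer than three atoms or collinear
    geometry raise :class:`GeometryError`.
    """
    mob = _coords_of(mobile)
    ref = _coords_of(reference)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        mob, ref = mob[sel], ref[sel]
    if mob.shape != ref.shape:
        raise GeometryError(
            f"selection maps to unequal atom counts: {mob.shape[0]} vs {ref.shape[0]}"
        )
    _check_nondegenerate(mob, "mobile")
    _check_nondegenerate(ref, "reference")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    rmsd = float(rssd / np.sqrt(mob.shape[0]))
    return RigidTransform(rotation=R, translation=t), rmsd


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def rmsd_series(
    traj: Trajectory,
    reference_index: int = 0,
    groups: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Per-group RMSD versus frame, corrected for global rigid motion.

    Every frame is superposed onto the reference frame using *all* atoms;
    each named group's RMSD is then measured in that single global fit
    (no per-group re-fitting), so group traces report internal motion
    relative to the whole complex. With no groups, a single ``all`` column
    is returned.
    """
    n = len(traj)
    if not (-n <= reference_index < n):
        raise IndexError(f"reference_index {reference_index} out of range for "
                         f"{n}-frame trajectory")
    ref = traj.frames[reference_index].coords
    if groups is None:
        groups = {"all": np.arange(traj.n_atoms)}
    group_idx = {name: np.asarray(sel, dtype=int) for name, sel in groups.items()}
    rows = []
    for fr in traj.frames:
        tf, _ = superpose(fr.coords, ref)
        fitted = tf.apply(fr.coords)
        row = {"frame": fr.index}
        for name, sel in group_idx.items():
            row[name] = _rmsd(fitted[sel], ref[sel])
        rows.append(row)
    return pd.DataFrame(rows).set_index("frame")


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _contact_atom(a) -> ContactAtom:
    return ContactAtom(a.chain_id, a.residue_number, a.residue_name, a.name,
                       a.element)


def _chain_indices(frame: Frame, chain_id: str,
                   heavy_atoms_only: bool) -> np.ndarray:
    idx = [
        i for i, a in enumerate(frame.atoms)
        if a.chain_id == chain_id and not (heavy_atoms_only and a.element == "H")
    ]
    if not any(a.chain_id == chain_id for a in frame.atoms):
        raise UnknownChainError(f"chain {chain_id!r} not present in frame")
    return np.asarray(idx, dtype=int)


def find_contacts(
    frame: Frame,
    chain_pair: tuple[str, str],
    threshold_A: float = DEFAULT_CONTACT_THRESHOLD_A,
    heavy_atoms_only: bool = False,
) -> list[ContactEvent]:
    """All intermolecular atom pairs within the distance threshold.

    One atom is drawn from each chain of ``chain_pair``; intramolecular
    (same-chain) pairs are never reported. The comparison is inclusive:
    a pair at exactly the threshold distance is a contact.
    """
    if threshold_A <= 0:
        raise ValueError("threshold_A must be positive")
    ca, cb = chain_pair
    if ca == cb:
        raise ValueError("chain_pair must name two different chains")
    idx_a = _chain_indices(frame, ca, heavy_atoms_only)
    idx_b = _chain_indices(frame, cb, heavy_atoms_only)
    coords = frame.coords
    events: list[ContactEvent] = []
    if len(idx_a) == 0 or len(idx_b) == 0:
        return events
    tree_b = cKDTree(coords[idx_b])
    neighbours = tree_b.query_ball_point(coords[idx_a], r=threshold_A)
    for ia, nb in zip(idx_a, neighbours):
        for jb in sorted(nb):
            ib = idx_b[jb]
            d = float(np.linalg.norm(coords[ia] - coords[ib]))
            events.append(
                ContactEvent(
                    atom_i=_contact_atom(frame.atoms[ia]),
                    atom_j=_contact_atom(frame.atoms[ib]),
                    frame_index=frame.index,
                    distance_A=d,
                )
            )
    return events


def resolve_window(
    n_frames: int,
    window: tuple[int, int] | None,
    skip_fraction: float = DEFAULT_SKIP_FRACTION,
) -> range:
    """Frame positions analysed: an explicit [start, stop) window, or the
    trajectory with the leading ``skip_fraction`` (equilibration) dropped."""
    if window is None:
        start = int(np.ceil(skip_fraction * n_frames))
        stop = n_frames
    else:
        start, stop = window
        if start < 0 or stop > n_frames:
            raise ValueError(f"window {window} outside trajectory of {n_frames} frames")
    if stop <= start:
        raise EmptyInputError(f"analysis window [{start}, {stop}) is empty")
    return range(start, stop)


def persistent_contacts(
    traj: Trajectory,
    chain_pair: tuple[str, str],
    threshold_A: float = DEFAULT_CONTACT_THRESHOLD_A,
    persistence: float = DEFAULT_PERSISTENCE,
    window: tuple[int, int] | None = None,
    skip_fraction: float = DEFAULT_SKIP_FRACTION,
    heavy_atoms_only: bool = False,
) -> list[PersistentContact]:
    """Atom pairs in contact in more than ``persistence`` of analysed frames.

    For every atom pair ever observed in contact inside the analysis
    window, the fraction of window frames with distance <= ``threshold_A``
    is computed; pairs whose fraction strictly exceeds ``persistence`` are
    returned sorted by (chain, residue number, atom name).
    """
    if threshold_A <= 0:
        raise ValueError("threshold_A must be positive")
    win = resolve_window(len(traj), window, skip_fraction)
    first = traj.frames[0]
    idx_a = _chain_indices(first, chain_pair[0], heavy_atoms_only)
    idx_b = _chain_indices(first, chain_pair[1], heavy_atoms_only)
    counts: dict[tuple[int, int], int] = {}
    for pos in win:
        coords = traj.frames[pos].coords
        tree_b = cKDTree(coords[idx_b])
        neighbours = tree_b.query_ball_point(coords[idx_a], r=threshold_A)
        for ia, nb in zip(idx_a, neighbours):
            for jb in nb:
                key = (int(ia), int(idx_b[jb]))
                counts[key] = counts.get(key, 0) + 1
    n_total = len(win)
    out = [
        PersistentContact(
            atom_i=_contact_atom(first.atoms[ia]),
            atom_j=_contact_atom(first.atoms[ib]),
            n_frames_present=c, n_frames_total=n_total,
        )
        for (ia, ib), c in counts.items()
        if c / n_total > persistence
    ]
    out.sort(key=lambda pc: (pc.atom_i.chain_id, pc.atom_i.residue_number,
                             pc.atom_i.name, pc.atom_j.chain_id,
                             pc.atom_j.residue_number, pc.atom_j.name))
    return out


def residue_histogram(
    events: Iterable[ContactEvent],
    n_frames: int,
    persistence: float = DEFAULT_PERSISTENCE,
) -> ContactHistogram:
    """Aggregate atom-level contact events into residue-pair fractions.

    A residue pair is counted present in a frame when *any* of its atom
    pairs is in contact there, so the residue-level fraction is the
    fraction of frames covered by the union of its atom-pair events and is
    never below any single atom pair's fraction.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    frames_by_respair: dict[tuple, set[int]] = {}
    chain_pair: tuple[str, str] | None = None
    for ev in events:
        ri = (ev.atom_i.chain_id, ev.atom_i.residue_number, ev.atom_i.residue_name)
        rj = (ev.atom_j.chain_id, ev.atom_j.residue_number, ev.atom_j.residue_name)
        frames_by_respair.setdefault((ri, rj), set()).add(ev.frame_index)
        pair = (ev.atom_i.chain_id, ev.atom_j.chain_id)
        if chain_pair is None:
            chain_pair = pair
        elif chain_pair != pair:
            raise ValueError(
                f"events mix chain pairs {chain_pair} and {pair}; histogram one "
                "chain pair at a time"
            )
    bins = {k: len(v) / n_frames for k, v in frames_by_respair.items()}
    flags = {k: frac > persistence for k, frac in bins.items()}
    return ContactHistogram(chain_pair=chain_pair, n_frames=n_frames,
                            bins=bins, persistent=flags)


def interface_residues(
    contacts: Iterable[PersistentContact],
) -> dict[str, list[str]]:
    """Unique interface residues per chain, sorted by residue number.

    Residues are formatted the way interface descriptions are printed:
    capitalised three-letter code followed by the residue number
    (``Glu367``).
    """
    per_chain: dict[str, dict[int, str]] = {}
    for c in contacts:
        for a in (c.atom_i, c.atom_j):
            per_chain.setdefault(a.chain_id, {})[a.residue_number] = a.residue_name
    out: dict[str, list[str]] = {}
    for chain in sorted(per_chain):
        out[chain] = [
            f"{per_chain[chain][num].capitalize()}{num}"
            for num in sorted(per_chain[chain])
        ]
    return out


_POLAR = {"N", "O"}


def donor_acceptor_subset(
    contacts: Iterable[PersistentContact],
) -> list[PersistentContact]:
    """Restrict persistent contacts to hydrogen-bond-capable atom pairs.

    Keeps pairs where one atom is a polar heavy atom (N or O) and the
    other is N, O or H — a distance-only proxy for donor–acceptor pairs.
    A hydrogen-bond search adds angular criteria on top of distance, so
    its hits form a subset of the distance-based persistent contacts; this
    helper carves out the candidate pool that such a search would draw
    from.
    """
    out = []
    for c in contacts:
        ei, ej = c.atom_i.element.upper(), c.atom_j.element.upper()
        if (ei in _POLAR and ej in _POLAR | {"H"}) or (
                ej in _POLAR and ei in _POLAR | {"H"}):
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# Frame clustering
# ---------------------------------------------------------------------------

def cluster_frames(
    traj: Trajectory,
    window: tuple[int, int] | None = None,
    cutoff_A: float = 1.5,
    skip_fraction: float = 0.0,
) -> FrameClustering:
    """Greedy centroid clustering of frames under superposition RMSD.

    Frames are visited in trajectory order; each joins the first existing
    cluster whose centroid is within ``cutoff_A`` after rigid
    superposition, otherwise it seeds a new cluster. Centroids are the
    running mean of member coordinates in the cluster's own reference
    frame, and each cluster's dispersion is the mean member-to-centroid
    RMSD after the final centroid is fixed.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff_A must be positive")
    win = resolve_window(len(traj), window, skip_fraction)
    members_aligned: dict[int, list[np.ndarray]] = {}
    member_frames: dict[int, list[int]] = {}
    centroids: dict[int, np.ndarray] = {}
    assignments: dict[int, int] = {}
    for pos in win:
        fr = traj.frames[pos]
        placed = False
        for cid in sorted(centroids):
            tf, rmsd = superpose(fr.coords, centroids[cid])
            if rmsd <= cutoff_A:
                aligned = tf.apply(fr.coords)
                members_aligned[cid].append(aligned)
                member_frames[cid].append(fr.index)
                centroids[cid] = np.mean(members_aligned[cid], axis=0)
                assignments[fr.index] = cid
                placed = True
                break
        if not placed:
            cid = len(centroids)
            centroids[cid] = fr.coords
            members_aligned[cid] = [fr.coords]
            member_frames[cid] = [fr.index]
            assignments[fr.index] = cid
    dispersion = {}
    sizes = {}
    for cid, mem in members_aligned.items():
        # re-fit members to the final centroid before measuring spread
        rmsds = [superpose(m, centroids[cid])[1] for m in mem]
        dispersion[cid] = float(np.mean(rmsds))
        sizes[cid] = len(mem)
    return FrameClustering(assignments=assignments, centroids=centroids,
                           dispersion_A=dispersion, sizes=sizes)
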