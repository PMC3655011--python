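"""Synthetic inputs with machine-readable ground truth.

Every stage of the pipeline can be exercised without external data:

* two-chain trajectories with atom pairs planted in contact for controlled
  fractions of frames (frames chosen by seeded permutation, so persistence
  is insensitive to where an analysis window falls),
* docking pose sets with planted spatial clusters and energies,
* fragment property tables with a known number of records inside every
  filter range,
* DSF plates of Boltzmann melt curves sampled on the standard
  20 → 89.9 °C, 0.3 °C scan (233 readings) with Gaussian noise and an
  optional post-peak linear decay.

All generators are deterministic given (spec, seed) and return ground
truth sufficient to score the downstream stage without re-derivation.
Synthetic chains use minimal three-atom residues to keep all-pairs test
oracles cheap; none of this emulates force-field physics or real
chemistry — it plants geometry and parameters with known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GeneratorSpecError
from .fragments import DEFAULT_FILTER, FilterSpec, FragmentRecord
from .structio import AtomRecord, Frame, Pose, Trajectory
from .thermofluor import boltzmann

__all__ = [
    "ChainSpec",
    "PlantedContact",
    "TrajectorySpec",
    "ConditionSpec",
    "PlateSpec",
    "gen_trajectory",
    "gen_pose_set",
    "gen_property_table",
    "gen_plate",
    "scan_temperatures",
]

#: separation (Å) a planted pair keeps in its out-of-contact frames
_APART_DISTANCE_A = 8.0
_MIN_APART_A = 6.0

# backbone-ish atom names/elements for 3-atom synthetic residues
_RESIDUE_ATOMS = (("N", "N"), ("CA", "C"), ("O", "O"))
_RESIDUE_NAMES = ("ALA", "GLY", "SER", "VAL", "LEU")


@dataclass(frozen=True)
class ChainSpec:
    chain_id: str
    n_residues: int = 4
    atoms_per_residue: int = 3


@dataclass(frozen=True)
class PlantedContact:
    """An atom pair to hold in contact in a target fraction of frames."""

    fraction: float
    contact_distance_A: float = 2.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise GeneratorSpecError(f"fraction {self.fraction} outside [0, 1]")
        if self.contact_distance_A <= 0:
            raise GeneratorSpecError("contact distance must be positive")
        if self.contact_distance_A >= _MIN_APART_A:
            raise GeneratorSpecError(
                f"contact distance {self.contact_distance_A} Å is not clearly "
                f"below the {_MIN_APART_A} Å out-of-contact separation"
            )


@dataclass(frozen=True)
class TrajectorySpec:
    n_frames: int
    chains: tuple[ChainSpec, ChainSpec] = (ChainSpec("B"), ChainSpec("D"))
    planted_contacts: tuple[PlantedContact, ...] = ()
    jitter_sigma_A: float = 0.0
    global_motion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise GeneratorSpecError("n_frames must be >= 1")
        if len(self.chains) != 2 or self.chains[0].chain_id == self.chains[1].chain_id:
            raise GeneratorSpecError("need two chains with distinct identifiers")
        n_contacts = len(self.planted_contacts)
        for ch in self.chains:
            if ch.n_residues < max(n_contacts, 1):
                raise GeneratorSpecError(
                    f"chain {ch.chain_id}: {ch.n_residues} residues cannot host "
                    f"{n_contacts} planted contacts (one per residue)"
                )


@dataclass
class TrajectoryGroundTruth:
    """Planted contacts with realized per-frame status."""

    contacts: pd.DataFrame      # one row per planted contact
    status: np.ndarray          # bool, (n_contacts, n_frames)


def _base_chain_atoms(spec: ChainSpec, z_offset: float,
                      serial_start: int) -> tuple[list[AtomRecord], np.ndarray]:
    atoms: list[AtomRecord] = []
    coords = []
    serial = serial_start
    for r in range(spec.n_residues):
        resname = _RESIDUE_NAMES[r % len(_RESIDUE_NAMES)]
        for a in range(spec.atoms_per_residue):
            name, element = _RESIDUE_ATOMS[a % len(_RESIDUE_ATOMS)]
            if a >= len(_RESIDUE_ATOMS):
                name = f"{name}{a}"
            pos = np.array([8.0 * r, 2.0 * a, z_offset])
            atoms.append(AtomRecord(
                serial=serial, name=name, element=element,
                residue_name=resname, residue_number=r + 1,
                chain_id=spec.chain_id, position=pos,
            ))
            coords.append(pos)
            serial += 1
    return atoms, np.array(coords)


def gen_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, TrajectoryGroundTruth]:
    """Build a two-chain trajectory with planted persistent contacts.

    Each planted contact occupies a dedicated, spatially isolated pair of
    atoms (residue k, atom 1 of each chain) and is within its contact
    distance in exactly ``round(fraction * n_frames)`` frames, chosen by a
    seeded permutation; in all other frames the pair sits 8 Å apart. Bulk
    atoms receive optional Gaussian jitter, and an optional global rigid
    motion (rotation + translation per frame) exercises superposition
    correction without changing any interatomic distance.
    """
    rng = np.random.default_rng(spec.seed)
    ch_a, ch_b = spec.chains
    atoms_a, base_a = _base_chain_atoms(ch_a, z_offset=0.0, serial_start=1)
    atoms_b, base_b = _base_chain_atoms(ch_b, z_offset=120.0,
                                        serial_start=len(atoms_a) + 1)
    template_atoms = tuple(atoms_a + atoms_b)
    base = np.vstack([base_a, base_b])
    n_atoms = len(template_atoms)
    n_contacts = len(spec.planted_contacts)

    # planted pair k: chain-A residue k atom 0 paired with chain-B residue k
    # atom 0, relocated to an isolated site on the x axis
    site_idx_a = [ch_a.atoms_per_residue * k for k in range(n_contacts)]
    site_idx_b = [len(atoms_a) + ch_b.atoms_per_residue * k
                  for k in range(n_contacts)]
    planted_atoms = set(site_idx_a) | set(site_idx_b)
    sites = np.array([[300.0 + 40.0 * k, 0.0, 60.0] for k in range(n_contacts)])

    n = spec.n_frames
    status = np.zeros((n_contacts, n), dtype=bool)
    for k, pc in enumerate(spec.planted_contacts):
        n_in = int(round(pc.fraction * n))
        chosen = rng.permutation(n)[:n_in]
        status[k, chosen] = True

    frames: list[Frame] = []
    for t in range(n):
        coords = base.copy()
        if spec.jitter_sigma_A > 0:
            jitter = rng.normal(0.0, spec.jitter_sigma_A, size=(n_atoms, 3))
            jitter[list(planted_atoms)] = 0.0
            coords += jitter
        for k, pc in enumerate(spec.planted_contacts):
            d = pc.contact_distance_A if status[k, t] else _APART_DISTANCE_A
            coords[site_idx_a[k]] = sites[k]
            coords[site_idx_b[k]] = sites[k] + np.array([d, 0.0, 0.0])
        if spec.global_motion:
            angle = math.radians(2.0 * t)
            c, s = math.cos(angle), math.sin(angle)
            R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            coords = coords @ R.T + np.array([0.1 * t, -0.05 * t, 0.02 * t])
        fr = Frame(index=t, atoms=template_atoms, time_ps=5.0 * t)
        frames.append(fr.with_coords(coords))

    rows = []
    for k, pc in enumerate(spec.planted_contacts):
        ai = template_atoms[site_idx_a[k]]
        bj = template_atoms[site_idx_b[k]]
        rows.append({
            "contact_id": k,
            "chain_i": ai.chain_id, "residue_number_i": ai.residue_number,
            "residue_name_i": ai.residue_name, "atom_i": ai.name,
            "chain_j": bj.chain_id, "residue_number_j": bj.residue_number,
            "residue_name_j": bj.residue_name, "atom_j": bj.name,
            "target_fraction": pc.fraction,
            "contact_distance_A": pc.contact_distance_A,
            "n_frames_in_contact": int(status[k].sum()),
            "realized_fraction": float(status[k].sum()) / n,
        })
    truth = TrajectoryGroundTruth(
        contacts=pd.DataFrame(rows, columns=[
            "contact_id", "chain_i", "residue_number_i", "residue_name_i",
            "atom_i", "chain_j", "residue_number_j", "residue_name_j",
            "atom_j", "target_fraction", "contact_distance_A",
            "n_frames_in_contact", "realized_fraction"]),
        status=status,
    )
    return Trajectory(frames=frames), truth


# ---------------------------------------------------------------------------
# Pose sets
# ---------------------------------------------------------------------------

_LIGAND_TEMPLATE = np.array([
    [0.0, 0.0, 0.0],
    [1.4, 0.0, 0.0],
    [0.0, 1.4, 0.0],
    [0.0, 0.0, 1.4],
    [-1.0, -1.0, 0.0],
])
_LIGAND_ELEMENTS = ("C", "C", "N", "O", "C")


@dataclass
class PoseSetGroundTruth:
    assignments: list[int]          # cluster index per pose (model order)
    sizes: tuple[int, ...]
    best_model_index: int           # lowest-energy pose of the largest cluster
    best_energy: float


def gen_pose_set(
    sizes: Sequence[int],
    base_energies: Sequence[float],
    separation_A: float = 15.0,
    jitter_A: float = 0.5,
    seed: int = 0,
    compound_id: str = "FRAG1",
    min_cutoff_A: float = 2.0,
) -> tuple[list[Pose], PoseSetGroundTruth]:
    """Pose set with planted spatial families.

    Family ``c`` sits at x = c * separation; its poses are rigid copies of
    a 5-atom ligand displaced by a uniform translation within ±``jitter_A``
    per axis, so intra-family coordinate RMSD stays below 2·√3·jitter
    while inter-family RMSD is ~separation. Energies within a family are
    ``base_energies[c] + 0.05 * j``. Poses are emitted in ascending-energy
    (Vina file) order with model indices 1..n.
    """
    if len(sizes) != len(base_energies):
        raise GeneratorSpecError("sizes and base_energies must have equal length")
    if any(s < 1 for s in sizes):
        raise GeneratorSpecError("every family size must be >= 1")
    if separation_A <= 2.0 * math.sqrt(3.0) * jitter_A + min_cutoff_A:
        raise GeneratorSpecError(
            f"separation {separation_A} Å cannot guarantee distinct families "
            f"for jitter {jitter_A} Å and clustering cutoff {min_cutoff_A} Å"
        )
    rng = np.random.default_rng(seed)
    raw: list[tuple[float, int, np.ndarray]] = []  # (energy, family, coords)
    for c, (size, e0) in enumerate(zip(sizes, base_energies)):
        center = np.array([separation_A * c, 0.0, 0.0])
        for j in range(size):
            shift = rng.uniform(-jitter_A, jitter_A, size=3)
            coords = _LIGAND_TEMPLATE + center + shift
            raw.append((e0 + 0.05 * j, c, coords))
    raw.sort(key=lambda r: r[0])
    poses: list[Pose] = []
    assignments: list[int] = []
    for m, (energy, fam, coords) in enumerate(raw, start=1):
        atoms = tuple(
            AtomRecord(serial=i + 1, name=f"{el}{i + 1}", element=el,
                       residue_name="LIG", residue_number=1, chain_id="L",
                       position=pos)
            for i, (el, pos) in enumerate(zip(_LIGAND_ELEMENTS, coords))
        )
        poses.append(Pose(compound_id=compound_id, model_index=m,
                          energy_kcal_mol=float(energy), atoms=atoms))
        assignments.append(fam)
    largest = max(range(len(sizes)), key=lambda c: (sizes[c],))
    in_largest = [p for p, fam in zip(poses, assignments) if fam == largest]
    best = min(in_largest, key=lambda p: p.energy_kcal_mol)
    truth = PoseSetGroundTruth(
        assignments=assignments, sizes=tuple(sizes),
        best_model_index=best.model_index, best_energy=best.energy_kcal_mol,
    )
    return poses, truth


# ---------------------------------------------------------------------------
# Property tables
# ---------------------------------------------------------------------------

# finite sampling intervals for properties whose filter range is one-sided
_SAMPLING_BOUNDS = {"PSA": (20.0, 200.0)}
_INT_PROPERTIES = {"n_atoms", "HAC", "nHA", "NR", "HD", "HA"}


def _sample_inside(rng: np.random.Generator, prop: str,
                   lo: float, hi: float) -> float:
    if not math.isfinite(lo) or not math.isfinite(hi):
        lo, hi = _SAMPLING_BOUNDS.get(prop, (0.0, 100.0))
    if prop in _INT_PROPERTIES:
        return int(rng.integers(int(math.ceil(lo)), int(math.floor(hi)) + 1))
    return float(rng.uniform(lo, hi))


def _sample_outside(rng: np.random.Generator, prop: str,
                    lo: float, hi: float) -> float:
    sides = []
    if math.isfinite(lo):
        sides.append("below")
    if math.isfinite(hi):
        sides.append("above")
    side = sides[int(rng.integers(len(sides)))]
    if prop in _INT_PROPERTIES:
        if side == "below":
            return int(rng.integers(max(0, int(lo) - 15), int(lo)))
        return int(rng.integers(int(hi) + 1, int(hi) + 16))
    span = (hi - lo) if (math.isfinite(lo) and math.isfinite(hi)) else 100.0
    if side == "below":
        return float(rng.uniform(lo - 0.5 * span, lo - 1e-6 * max(span, 1.0)))
    return float(rng.uniform(hi + 1e-6 * max(span, 1.0), hi + 0.5 * span))


def gen_property_table(
    n: int,
    in_range_count: int,
    spec: FilterSpec = DEFAULT_FILTER,
    seed: int = 0,
) -> tuple[list[FragmentRecord], pd.DataFrame]:
    """Property table with exactly ``in_range_count`` all-inside records.

    Every other record violates at least one filter range (the violated
    properties are recorded in the ground-truth table). Records are
    shuffled so passing and failing compounds interleave. Unfiltered
    descriptors (logS, HAC, nHA, NR, HD, HA when absent from the spec)
    are drawn around typical fragment-library values.
    """
    if in_range_count > n or in_range_count < 0:
        raise GeneratorSpecError("need 0 <= in_range_count <= n")
    rng = np.random.default_rng(seed)
    plan = np.array([True] * in_range_count + [False] * (n - in_range_count))
    rng.shuffle(plan)
    records: list[FragmentRecord] = []
    truth_rows = []
    filtered_props = list(spec.ranges)
    for i, inside in enumerate(plan):
        values: dict[str, float] = {}
        violated: list[str] = []
        if inside:
            for prop in filtered_props:
                lo, hi = spec.ranges[prop]
                values[prop] = _sample_inside(rng, prop, lo, hi)
        else:
            n_viol = 1 + int(rng.integers(0, 2))  # violate 1 or 2 ranges
            viol = list(rng.choice(len(filtered_props),
                                   size=min(n_viol, len(filtered_props)),
                                   replace=False))
            for j, prop in enumerate(filtered_props):
                lo, hi = spec.ranges[prop]
                if j in viol:
                    values[prop] = _sample_outside(rng, prop, lo, hi)
                    violated.append(prop)
                else:
                    values[prop] = _sample_inside(rng, prop, lo, hi)
        # descriptors outside the filter: typical library distributions
        defaults = {
            "MW": float(rng.uniform(200, 500)),
            "logP": float(rng.normal(1.0, 1.0)),
            "logS": float(rng.normal(-3.0, 1.0)),
            "MR": float(rng.uniform(40, 130)),
            "n_atoms": int(rng.integers(20, 71)),
            "HAC": int(rng.integers(10, 36)),
            "nHA": int(rng.integers(2, 13)),
            "NR": int(rng.integers(0, 5)),
            "HD": int(rng.integers(0, 6)),
            "HA": int(rng.integers(1, 11)),
            "PSA": float(rng.uniform(20, 200)),
        }
        for prop, dv in defaults.items():
            values.setdefault(prop, dv)
        cid = f"SYN{i:05d}"
        records.append(FragmentRecord(
            compound_id=cid, MW=values["MW"], logP=values["logP"],
            logS=values["logS"], MR=values["MR"],
            n_atoms=int(values["n_atoms"]), HAC=int(values["HAC"]),
            nHA=int(values["nHA"]), NR=int(values["NR"]),
            HD=int(values["HD"]), HA=int(values["HA"]), PSA=values["PSA"],
        ))
        truth_rows.append({"compound_id": cid, "in_range": bool(inside),
                           "violated": ";".join(violated)})
    truth = pd.DataFrame(truth_rows, columns=["compound_id", "in_range",
                                              "violated"])
    return records, truth


# ---------------------------------------------------------------------------
# DSF plates
# ---------------------------------------------------------------------------

def scan_temperatures(start_C: float = 20.0, end_C: float = 89.9,
                      step_C: float = 0.3) -> np.ndarray:
    """Temperature grid of the standard scan: start-inclusive readings
    every ``step_C`` up to (but not including) ``end_C`` — 233 points for
    the 20 → 89.9 °C, 0.3 °C default."""
    n = int(round((end_C - start_C) / step_C))
    return start_C + step_C * np.arange(n)


@dataclass(frozen=True)
class ConditionSpec:
    """One screen condition: planted melt parameters and replication."""

    name: str
    tm_C: float
    slope_a_C: float = 2.0
    f_min_AU: float = 1000.0
    f_max_AU: float = 10000.0
    n_replicates: int = 3


@dataclass(frozen=True)
class PlateSpec:
    conditions: tuple[ConditionSpec, ...]
    noise_sigma_AU: float = 0.0
    scan: tuple[float, float, float] = (20.0, 89.9, 0.3)
    decay_rate_AU_per_C: float = 0.0   # post-peak linear decay; 0 = off
    decay_onset_a_units: float = 8.0   # decay starts at Tm + onset * a
    seed: int = 0

    def __post_init__(self) -> None:
        start, end, _ = self.scan
        for cond in self.conditions:
            if not (start < cond.tm_C < end):
                raise GeneratorSpecError(
                    f"condition {cond.name!r}: planted Tm {cond.tm_C} °C outside "
                    f"the {start}–{end} °C scan"
                )


def gen_plate(spec: PlateSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format plate (well, condition, temperature_C, fluorescence_AU)
    plus a ground-truth table of planted parameters per well.

    Each replicate well holds a Boltzmann curve with the condition's
    planted parameters, an optional linear decay beyond Tm + 8·a (to
    exercise the fit-window truncation), and i.i.d. Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    T = scan_temperatures(*spec.scan)
    plate_rows = []
    truth_rows = []
    well_no = 0
    for cond in spec.conditions:
        for rep in range(cond.n_replicates):
            well = f"{chr(ord('A') + well_no // 12)}{well_no % 12 + 1:02d}"
            well_no += 1
            F = boltzmann(T, cond.f_min_AU, cond.f_max_AU, cond.tm_C,
                          cond.slope_a_C)
            if spec.decay_rate_AU_per_C > 0:
                onset = cond.tm_C + spec.decay_onset_a_units * cond.slope_a_C
                F = F - spec.decay_rate_AU_per_C * np.clip(T - onset, 0.0, None)
            if spec.noise_sigma_AU > 0:
                F = F + rng.normal(0.0, spec.noise_sigma_AU, size=T.shape)
            for t, f in zip(T, F):
                plate_rows.append((well, cond.name, round(float(t), 4),
                                   float(f)))
            truth_rows.append({
                "well": well, "condition": cond.name, "replicate": rep,
                "tm_C": cond.tm_C, "slope_a_C": cond.slope_a_C,
                "f_min_AU": cond.f_min_AU, "f_max_AU": cond.f_max_AU,
            })
    plate = pd.DataFrame(plate_rows, columns=["well", "condition",
                                              "temperature_C",
                                              "fluorescence_AU"])
    truth = pd.DataFrame(truth_rows)
    return plate, truth
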