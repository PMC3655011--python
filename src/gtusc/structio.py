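"""Structure and pose file I/O.

Reads and writes the formats the pipeline consumes:

* multi-model PDB trajectories (one MODEL per frame) via Bio.PDB,
* concatenated XYZ frame stacks (coordinates only; atom identity must be
  supplied by a template frame because XYZ carries no chain/residue data),
* multi-model PDBQT docking-pose files with per-model ``VINA RESULT``
  energy remarks,
* tab-separated persistent-contact reports.

Atom identity (serial, name, residue, chain) is validated to be constant
across the frames of one trajectory; files that violate this are rejected
with an error naming the offending frame.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    PoseParseError,
    StructuralInconsistencyError,
)

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "Pose",
    "read_trajectory",
    "write_trajectory",
    "read_pose_file",
    "write_pose_file",
    "write_contact_report",
    "read_contact_report",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure frame.

    Residue numbering is kept exactly as in the input file (1-based,
    e.g. Ser623); no renumbering is applied on input or output.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.chain_id or not self.chain_id.strip():
            raise ValueError(f"atom {self.serial}: empty chain identifier")
        if self.serial < 1:
            raise ValueError(f"atom serial must be positive, got {self.serial}")

    @property
    def identity(self) -> tuple:
        """Identity key used to check frame-to-frame consistency."""
        return (
            self.serial,
            self.name,
            self.element,
            self.residue_name,
            self.residue_number,
            self.chain_id,
        )


@dataclass(frozen=True)
class Frame:
    """An ordered snapshot of atoms at one trajectory frame."""

    index: int
    atoms: tuple[AtomRecord, ...]
    time_ps: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Frame":
        """Copy of this frame with replaced coordinates (identity preserved)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = tuple(
            AtomRecord(a.serial, a.name, a.element, a.residue_name,
                       a.residue_number, a.chain_id, c)
            for a, c in zip(self.atoms, coords)
        )
        return Frame(self.index, atoms, self.time_ps)

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return np.array([a.chain_id == chain_id for a in self.atoms], dtype=bool)


@dataclass
class Trajectory:
    """An ordered stack of frames sharing one atom identity list."""

    frames: list[Frame]
    chain_ids: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyInputError("trajectory has no frames")
        ref = [a.identity for a in self.frames[0].atoms]
        for fr in self.frames[1:]:
            ids = [a.identity for a in fr.atoms]
            if len(ids) != len(ref):
                raise StructuralInconsistencyError(
                    f"frame {fr.index}: atom count {len(ids)} != {len(ref)} in frame "
                    f"{self.frames[0].index}"
                )
            if ids != ref:
                raise StructuralInconsistencyError(
                    f"frame {fr.index}: atom identity differs from frame "
                    f"{self.frames[0].index}"
                )
        self.chain_ids = frozenset(a.chain_id for a in self.frames[0].atoms)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0].atoms)

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate stack."""
        return np.array([fr.coords for fr in self.frames])


@dataclass(frozen=True)
class Pose:
    """One docked conformation with its docking score."""

    compound_id: str
    model_index: int
    energy_kcal_mol: float
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("pose has no atoms")
        if not math.isfinite(self.energy_kcal_mol):
            raise ValueError("pose energy must be finite")
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


# ---------------------------------------------------------------------------
# PDB trajectories
# ---------------------------------------------------------------------------

def _frames_from_biopdb(path: Path) -> Iterator[Frame]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    for model in structure:
        atoms: list[AtomRecord] = []
        for chain in model:
            cid = str(chain.id)
            if not cid.strip():
                raise StructuralInconsistencyError(
                    f"{path}: model {model.id}: blank chain identifier "
                    "(chain-less files are rejected, not guessed)"
                )
            for res in chain:
                resnum = res.id[1]
                for atom in res:
                    atoms.append(
                        AtomRecord(
                            serial=int(atom.serial_number),
                            name=atom.get_name(),
                            element=(atom.element or "X").strip() or "X",
                            residue_name=res.get_resname().strip(),
                            residue_number=int(resnum),
                            chain_id=cid,
                            position=atom.coord.astype(float),
                        )
                    )
        yield Frame(index=int(model.id), atoms=tuple(atoms))


def _read_xyz_frames(path: Path, template: Frame) -> list[Frame]:
    frames: list[Frame] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + natoms]
        if len(block) < natoms:
            raise StructuralInconsistencyError(
                f"{path}: truncated XYZ frame {len(frames)}"
            )
        if natoms != len(template.atoms):
            raise StructuralInconsistencyError(
                f"{path}: frame {len(frames)} has {natoms} atoms, template has "
                f"{len(template.atoms)}"
            )
        coords = np.empty((natoms, 3))
        for j, line in enumerate(block):
            parts = line.split()
            el = parts[0]
            if el.upper() != template.atoms[j].element.upper():
                raise StructuralInconsistencyError(
                    f"{path}: frame {len(frames)} atom {j}: element {el} does not "
                    f"match template element {template.atoms[j].element}"
                )
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        fr = template.with_coords(coords)
        frames.append(Frame(index=len(frames), atoms=fr.atoms))
        i += 2 + natoms
    return frames


def read_trajectory(
    path: str | Path,
    format: Literal["pdb_multimodel", "xyz_frames"] = "pdb_multimodel",
    template: Frame | None = None,
) -> Trajectory:
    """Read a multi-frame trajectory from disk.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``pdb_multimodel`` — one MODEL record per frame; ``xyz_frames`` —
        concatenated XYZ blocks. XYZ files carry no chain or residue
        identity, so a ``template`` frame supplying the atom identity is
        mandatory for that dialect.

    Raises
    ------
    EmptyInputError
        The file contains no frames.
    StructuralInconsistencyError
        Atom count or identity differs between frames, or the XYZ elements
        do not match the template.
    """
    path = Path(path)
    if format == "pdb_multimodel":
        if path.stat().st_size == 0:
            raise EmptyInputError(f"{path}: empty file")
        frames = list(_frames_from_biopdb(path))
    elif format == "xyz_frames":
        if template is None:
            raise ValueError(
                "xyz_frames carries no chain/residue identity; a template "
                "Frame is required"
            )
        frames = _read_xyz_frames(path, template)
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown trajectory format {format!r}")
    if not frames:
        raise EmptyInputError(f"{path}: no frames found")
    return Trajectory(frames=frames)


def _pdb_atom_name(name: str, element: str) -> str:
    """PDB columns 13-16: one-letter elements start at column 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _format_atom_line(a: AtomRecord, record: str = "ATOM") -> str:
    x, y, z = a.position
    return (
        f"{record:<6s}{a.serial:>5d} {_pdb_atom_name(a.name, a.element)} "
        f"{a.residue_name:>3s} {a.chain_id:1s}{a.residue_number:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (3-decimal coordinates)."""
    path = Path(path)
    with path.open("w") as fh:
        for n, fr in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {n:>4d}\n")
            for a in fr.atoms:
                fh.write(_format_atom_line(a) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# PDBQT poses
# ---------------------------------------------------------------------------

def _parse_pdbqt_atom(line: str, serial_fallback: int) -> AtomRecord:
    # PDBQT shares the PDB fixed columns for the first 66 characters;
    # partial charge and AutoDock atom type follow.
    name = line[12:16].strip()
    resname = line[17:20].strip() or "LIG"
    chain = line[21].strip() or "L"  # ligand poses often leave the chain blank
    try:
        resnum = int(line[22:26])
    except ValueError:
        resnum = 1
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = serial_fallback
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    adtype = line[77:79].strip() if len(line) > 77 else ""
    element = adtype[:1].upper() if adtype else (name[:1] or "C")
    return AtomRecord(
        serial=serial,
        name=name or "X",
        element=element,
        residue_name=resname,
        residue_number=max(resnum, 1),
        chain_id=chain,
        position=np.array([x, y, z]),
    )


def read_pose_file(path: str | Path, compound_id: str | None = None) -> list[Pose]:
    """Parse a multi-model PDBQT pose file.

    One :class:`Pose` is returned per ``MODEL`` block, in file order. The
    docking score is taken from the per-model ``REMARK VINA RESULT`` line
    (first numeric field); a model without one is a parse error. A file
    holding bare ATOM records (no MODEL) is treated as a single model.
    """
    path = Path(path)
    if compound_id is None:
        compound_id = path.stem
    text = path.read_text()
    poses: list[Pose] = []
    model_index: int | None = None
    energy: float | None = None
    atoms: list[AtomRecord] = []
    saw_model = False

    def flush(idx: int) -> None:
        nonlocal energy, atoms
        if not atoms:
            return
        if energy is None:
            raise PoseParseError(
                f"{path}: model {idx} has no 'REMARK VINA RESULT' energy remark"
            )
        poses.append(
            Pose(compound_id=compound_id, model_index=idx,
                 energy_kcal_mol=energy, atoms=tuple(atoms))
        )
        energy = None
        atoms = []

    for line in io.StringIO(text):
        rec = line[:6].strip()
        if line.startswith("MODEL"):
            saw_model = True
            model_index = int(line.split()[1]) if len(line.split()) > 1 else (
                (poses[-1].model_index + 1) if poses else 1
            )
        elif line.startswith("REMARK VINA RESULT"):
            fields = line.split(":", 1)[1].split() if ":" in line else line.split()[3:]
            if not fields:
                raise PoseParseError(f"{path}: malformed VINA RESULT remark")
            energy = float(fields[0])
        elif rec in ("ATOM", "HETATM"):
            atoms.append(_parse_pdbqt_atom(line.rstrip("\n"), len(atoms) + 1))
        elif line.startswith("ENDMDL"):
            flush(model_index if model_index is not None else len(poses) + 1)
            model_index = None
    if atoms:  # single-model file without MODEL/ENDMDL bracketing
        flush(model_index if model_index is not None else 1)
    if not poses:
        if saw_model:
            raise EmptyInputError(f"{path}: MODEL blocks contain no atoms")
        raise EmptyInputError(f"{path}: no poses found")
    return poses


def write_pose_file(poses: Sequence[Pose], path: str | Path) -> None:
    """Write poses as a multi-model PDBQT with VINA RESULT remarks."""
    if not poses:
        raise EmptyInputError("no poses to write")
    path = Path(path)
    with path.open("w") as fh:
        for pose in poses:
            fh.write(f"MODEL {pose.model_index}\n")
            fh.write(
                f"REMARK VINA RESULT:    {pose.energy_kcal_mol:8.3f}"
                f"      0.000      0.000\n"
            )
            fh.write("ROOT\n")
            for a in pose.atoms:
                base = _format_atom_line(a, record="HETATM")[:66]
                # charge column + AutoDock type
                fh.write(f"{base}    {0.0:6.3f} {a.element:<2s}\n")
            fh.write("ENDROOT\nTORSDOF 0\nENDMDL\n")


# ---------------------------------------------------------------------------
# Contact reports
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "chain_i", "residue_number_i", "residue_name_i", "atom_i",
    "chain_j", "residue_number_j", "residue_name_j", "atom_j",
    "n_frames_present", "n_frames_total", "persistence_fraction",
]


def write_contact_report(contacts: Iterable, path: str | Path) -> None:
    """Write persistent contacts as a TSV report.

    Rows are sorted by (chain, residue number, atom name) of the first atom
    and then of the second, so the report is deterministic regardless of
    the input ordering.
    """
    rows = []
    for c in contacts:
        rows.append((
            c.atom_i.chain_id, c.atom_i.residue_number, c.atom_i.residue_name,
            c.atom_i.name,
            c.atom_j.chain_id, c.atom_j.residue_number, c.atom_j.residue_name,
            c.atom_j.name,
            c.n_frames_present, c.n_frames_total, c.persistence_fraction,
        ))
    rows.sort(key=lambda r: (r[0], r[1], r[3], r[4], r[5], r[7]))
    with Path(path).open("w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(str(v) for v in r[:10]) + f"\t{r[10]:.6f}\n"
            )


def read_contact_report(path: str | Path) -> list:
    """Read back a TSV contact report written by :func:`write_contact_report`."""
    from .contacts import ContactAtom, PersistentContact

    out = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _REPORT_COLUMNS:
            raise PoseParseError(f"{path}: unexpected contact-report header")
        for line in fh:
            v = line.rstrip("\n").split("\t")
            out.append(
                PersistentContact(
                    atom_i=ContactAtom(v[0], int(v[1]), v[2], v[3]),
                    atom_j=ContactAtom(v[4], int(v[5]), v[6], v[7]),
                    n_frames_present=int(v[8]),
                    n_frames_total=int(v[9]),
                )
            )
    return out
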