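"""Topology/trajectory containers and PDB/DCD readers and writers.

Coordinates are stored in single precision (the DCD native dtype); every
derived statistic in this package accumulates in double precision.  Only
orthorhombic boxes are supported: the systems this package targets are
simulated with the x-y plane restrained to a constant ratio, and a triclinic
DCD unit cell is rejected with a clear error rather than silently mangled.

PDB support covers fixed-column ATOM/HETATM records, MODEL/ENDMDL multi-frame
files and the CRYST1 box record.  DCD support covers the CHARMM/NAMD dialect:
4-byte Fortran record markers, the 84-byte control block, an optional
per-frame unit-cell record of six doubles.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    FormatError,
    InsufficientDataError,
    SelectionError,
    StructureError,
)

__all__ = [
    "Topology",
    "Trajectory",
    "DisplacementSeries",
    "read_pdb",
    "write_pdb",
    "read_dcd",
    "write_dcd",
    "select",
    "unwrapped_dz",
]

#: residue names recognised as water by default, oxygen-atom position proxy
WATER_RESIDUE_NAMES = ("TIP3", "HOH", "SOL", "WAT")
WATER_OXYGEN_NAMES = ("OH2", "OW", "O")


@dataclass
class Topology:
    """Per-atom metadata in file order; atom indices are 0-based and contiguous."""

    atom_name: np.ndarray
    residue_name: np.ndarray
    residue_number: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.residue_number = np.asarray(self.residue_number, dtype=np.int64)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        if self.element is not None:
            self.element = np.asarray(self.element, dtype=object)
        n = len(self.atom_name)
        for arr, nm in (
            (self.residue_name, "residue_name"),
            (self.residue_number, "residue_number"),
            (self.chain_id, "chain_id"),
        ):
            if len(arr) != n:
                raise StructureError(f"topology field {nm} has length {len(arr)} != {n}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates (Å) with per-frame orthorhombic box lengths.

    ``coords`` has shape (n_frames, n_atoms, 3) in float32; ``box`` is
    (n_frames, 3) giving (Lx, Ly, Lz) in Å, or ``None`` when no box is known.
    ``dt_frame`` is the time between stored frames in ps and is supplied by
    the caller (trajectory-file time headers are not trusted).
    """

    coords: np.ndarray
    box: np.ndarray | None = None
    dt_frame: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float32)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError(
                f"coords must have shape (n_frames, n_atoms, 3); got {self.coords.shape}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64)
            if self.box.ndim == 1:
                self.box = np.tile(self.box, (self.n_frames, 1))
            if self.box.shape != (self.n_frames, 3):
                raise StructureError(
                    f"box must have shape ({self.n_frames}, 3); got {self.box.shape}"
                )
            if np.any(self.box <= 0):
                raise StructureError("all box lengths must be positive")
        if self.dt_frame <= 0:
            raise StructureError("dt_frame must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def time_ps(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=np.float64) * self.dt_frame


@dataclass
class DisplacementSeries:
    """Per-interval, minimum-image-unwrapped z-displacements (Å).

    ``dz`` has shape (n_frames - 1, n_atoms_selected); row k is the
    displacement from frame k to frame k+1.
    """

    atom_ids: np.ndarray
    dz: np.ndarray


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

def _parse_pdb_float(line: str, lo: int, hi: int, lineno: int, what: str) -> float:
    try:
        return float(line[lo:hi])
    except ValueError as exc:
        raise FormatError(
            f"line {lineno}: cannot parse {what} from columns {lo + 1}-{hi}: {line[lo:hi]!r}"
        ) from exc


def read_pdb(path: str | Path) -> tuple[Topology, Trajectory]:
    """Read a (possibly multi-MODEL) PDB file.

    Fixed PDB column positions are used throughout.  MODEL/ENDMDL records
    delimit frames; a file without them yields a single frame.  A CRYST1
    record, if present, populates the box (replicated to every frame).
    """
    path = Path(path)
    names: list[str] = []
    resnames: list[str] = []
    resnums: list[int] = []
    chains: list[str] = []
    elements: list[str] = []
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] | None = None
    box: tuple[float, float, float] | None = None
    saw_model = False
    first_frame_atoms = 0

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                box = (
                    _parse_pdb_float(line, 6, 15, lineno, "box a"),
                    _parse_pdb_float(line, 15, 24, lineno, "box b"),
                    _parse_pdb_float(line, 24, 33, lineno, "box c"),
                )
            elif rec.startswith("MODEL"):
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                if current is None:
                    raise FormatError(f"line {lineno}: ENDMDL without MODEL")
                frames.append(current)
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    if saw_model:
                        raise FormatError(
                            f"line {lineno}: ATOM record outside MODEL/ENDMDL"
                        )
                    current = []
                x = _parse_pdb_float(line, 30, 38, lineno, "x")
                y = _parse_pdb_float(line, 38, 46, lineno, "y")
                z = _parse_pdb_float(line, 46, 54, lineno, "z")
                current.append((x, y, z))
                if not frames:  # metadata from first frame only
                    names.append(line[12:16].strip())
                    resnames.append(line[17:21].strip())
                    chains.append(line[21].strip())
                    try:
                        resnums.append(int(line[22:26]))
                    except ValueError as exc:
                        raise FormatError(
                            f"line {lineno}: cannot parse residue number: {line[22:26]!r}"
                        ) from exc
                    elements.append(line[76:78].strip() if len(line) >= 78 else "")

    if current is not None:
        # single-model file (no MODEL/ENDMDL) or unterminated last MODEL
        frames.append(current)
    if not frames or not frames[0]:
        raise FormatError(f"{path}: no ATOM/HETATM records found")

    first_frame_atoms = len(frames[0])
    for i, fr in enumerate(frames):
        if len(fr) != first_frame_atoms:
            raise StructureError(
                f"{path}: MODEL {i + 1} has {len(fr)} atoms, expected {first_frame_atoms}"
            )

    topo = Topology(
        atom_name=names,
        residue_name=resnames,
        residue_number=resnums,
        chain_id=chains,
        element=elements,
    )
    coords = np.asarray(frames, dtype=np.float32)
    traj = Trajectory(coords=coords, box=np.asarray(box) if box is not None else None)
    return topo, traj


def _pdb_atom_name(name: str) -> str:
    # names shorter than 4 characters start in column 14 by convention
    return f"{name:>4s}" if len(name) >= 4 else f" {name:<3s}"


def write_pdb(topology: Topology, trajectory: Trajectory, path: str | Path) -> None:
    """Write a fixed-column PDB; multi-frame trajectories use MODEL/ENDMDL.

    The CRYST1 record is taken from frame 0 (the PDB format has a single
    global cell).
    """
    if topology.n_atoms != trajectory.n_atoms:
        raise StructureError(
            f"topology has {topology.n_atoms} atoms but trajectory has {trajectory.n_atoms}"
        )
    path = Path(path)
    multi = trajectory.n_frames > 1
    with path.open("w") as fh:
        if trajectory.box is not None:
            a, b, c = trajectory.box[0]
            fh.write(
                f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        for f in range(trajectory.n_frames):
            if multi:
                fh.write(f"MODEL     {f + 1:4d}\n")
            for i in range(topology.n_atoms):
                serial = (i + 1) % 100000
                elem = topology.element[i] if topology.element is not None else ""
                x, y, z = trajectory.coords[f, i]
                fh.write(
                    f"ATOM  {serial:5d} {_pdb_atom_name(topology.atom_name[i])} "
                    f"{topology.residue_name[i]:<4s}"
                    f"{(topology.chain_id[i] or 'A')[:1]}"
                    f"{int(topology.residue_number[i]) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# DCD (CHARMM/NAMD dialect)
# --------------------------------------------------------------------------

def _write_record(fh, payload: bytes) -> None:
    fh.write(struct.pack("<i", len(payload)))
    fh.write(payload)
    fh.write(struct.pack("<i", len(payload)))


def _read_record(fh, *, what: str) -> bytes:
    head = fh.read(4)
    if len(head) < 4:
        raise EOFError(what)
    (n,) = struct.unpack("<i", head)
    if n < 0:
        raise FormatError(f"negative Fortran record length while reading {what}")
    payload = fh.read(n)
    tail = fh.read(4)
    if len(payload) < n or len(tail) < 4:
        raise EOFError(what)
    (n2,) = struct.unpack("<i", tail)
    if n2 != n:
        raise FormatError(f"mismatched Fortran record markers while reading {what}")
    return payload


def write_dcd(trajectory: Trajectory, path: str | Path) -> None:
    """Write a CHARMM-dialect DCD; the unit-cell block is emitted when a box
    is present (angle slots carry cosines, 0.0 for orthorhombic)."""
    path = Path(path)
    has_box = trajectory.box is not None
    icntrl = [0] * 20
    icntrl[0] = trajectory.n_frames  # NSET
    icntrl[1] = 0  # ISTART
    icntrl[2] = 1  # NSAVC
    icntrl[3] = trajectory.n_frames
    icntrl[9] = struct.unpack("<i", struct.pack("<f", float(trajectory.dt_frame)))[0]
    icntrl[10] = 1 if has_box else 0
    icntrl[19] = 24  # CHARMM version flag
    with path.open("wb") as fh:
        _write_record(fh, b"CORD" + struct.pack("<20i", *icntrl))
        title = b"Created by aqpflux".ljust(80)
        _write_record(fh, struct.pack("<i", 1) + title)
        _write_record(fh, struct.pack("<i", trajectory.n_atoms))
        for f in range(trajectory.n_frames):
            if has_box:
                lx, ly, lz = trajectory.box[f]
                cell = struct.pack("<6d", lx, 0.0, ly, 0.0, 0.0, lz)
                _write_record(fh, cell)
            frame = np.ascontiguousarray(trajectory.coords[f], dtype=np.float32)
            for axis in range(3):
                _write_record(fh, frame[:, axis].tobytes())


def _cell_is_orthorhombic(u: np.ndarray) -> bool:
    # CHARMM stores either angles (90 deg) or their cosines (0.0) in slots 1,3,4
    ang = u[[1, 3, 4]]
    return bool(np.all(np.abs(ang) < 1e-6) or np.all(np.abs(ang - 90.0) < 1e-6))


def read_dcd(path: str | Path, topology: Topology) -> Trajectory:
    """Read a CHARMM/NAMD DCD file against a topology.

    Returns as many complete frames as the file contains; if fewer than the
    header's NSET a warning is issued.  Triclinic unit cells are rejected.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file is not a DCD")
    with path.open("rb") as fh:
        try:
            header = _read_record(fh, what="header")
        except EOFError as exc:
            raise FormatError(f"{path}: truncated DCD header") from exc
        if len(header) != 84 or header[:4] != b"CORD":
            raise FormatError(f"{path}: DCD magic string is not 'CORD'")
        icntrl = struct.unpack("<20i", header[4:])
        nset, has_cell = icntrl[0], icntrl[10]
        try:
            _read_record(fh, what="title")
            natoms_rec = _read_record(fh, what="natoms")
        except EOFError as exc:
            raise FormatError(f"{path}: truncated DCD preamble") from exc
        (natoms,) = struct.unpack("<i", natoms_rec[:4])
        if natoms != topology.n_atoms:
            raise StructureError(
                f"{path}: DCD has {natoms} atoms but topology has {topology.n_atoms}"
            )
        frames: list[np.ndarray] = []
        boxes: list[np.ndarray] = []
        while True:
            try:
                if has_cell:
                    cell = np.frombuffer(
                        _read_record(fh, what="unit cell"), dtype="<f8"
                    )
                    if not _cell_is_orthorhombic(cell):
                        raise FormatError(
                            f"{path}: triclinic unit cell not supported "
                            "(only orthorhombic boxes)"
                        )
                    boxes.append(cell[[0, 2, 5]])
                xyz = np.empty((natoms, 3), dtype=np.float32)
                for axis in range(3):
                    rec = _read_record(fh, what="coordinates")
                    if len(rec) != 4 * natoms:
                        raise FormatError(
                            f"{path}: coordinate record has wrong size"
                        )
                    xyz[:, axis] = np.frombuffer(rec, dtype="<f4")
                frames.append(xyz)
            except EOFError:
                break
    if not frames:
        raise FormatError(f"{path}: DCD contains no complete frames")
    if nset and len(frames) != nset:
        warnings.warn(
            f"{path}: header declares {nset} frames but {len(frames)} were read",
            stacklevel=2,
        )
    coords = np.stack(frames)
    box = np.stack(boxes) if boxes else None
    return Trajectory(coords=coords, box=box)


# --------------------------------------------------------------------------
# selections and displacements
# --------------------------------------------------------------------------

_SELECT_FIELDS = ("atom_name", "residue_name", "residue_number", "chain_id")


def select(topology: Topology, criteria: Mapping[str, object]) -> np.ndarray:
    """Select atoms by a conjunction of field criteria.

    ``criteria`` maps field names (atom_name, residue_name, residue_number,
    chain_id) to a scalar or an iterable of allowed values.  Indices are
    returned in file order; an empty selection is a legal result.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    for key, value in criteria.items():
        if key not in _SELECT_FIELDS:
            raise SelectionError(
                f"unknown selection field {key!r}; allowed: {_SELECT_FIELDS}"
            )
        column = getattr(topology, key)
        if isinstance(value, (str, int, np.integer)):
            allowed = {value}
        else:
            allowed = set(value)  # type: ignore[arg-type]
        if key == "residue_number":
            allowed = {int(v) for v in allowed}
            mask &= np.isin(column, list(allowed))
        else:
            mask &= np.fromiter(
                (str(v) in {str(a) for a in allowed} for v in column),
                dtype=bool,
                count=topology.n_atoms,
            )
    return np.nonzero(mask)[0]


def select_water_oxygens(
    topology: Topology,
    residue_names: Sequence[str] = WATER_RESIDUE_NAMES,
    atom_names: Sequence[str] = WATER_OXYGEN_NAMES,
) -> np.ndarray:
    """Water molecules identified by residue name with the oxygen as proxy."""
    return select(
        topology, {"residue_name": residue_names, "atom_name": atom_names}
    )


def unwrapped_dz(trajectory: Trajectory, atom_ids: Iterable[int]) -> DisplacementSeries:
    """Per-interval z-displacements, minimum-image corrected along z.

    Each interval uses the box height of its starting frame:
    dz ← dz − Lz·round(dz/Lz).  After the correction |dz| < Lz/2.
    """
    atom_ids = np.asarray(list(atom_ids), dtype=np.int64)
    if trajectory.n_frames < 2:
        raise InsufficientDataError("at least two frames required for displacements")
    if trajectory.box is None:
        raise InsufficientDataError("per-frame box heights required to unwrap z")
    z = trajectory.coords[:, atom_ids, 2].astype(np.float64)
    dz = np.diff(z, axis=0)
    lz = trajectory.box[:-1, 2][:, None]
    dz -= lz * np.round(dz / lz)
    return DisplacementSeries(atom_ids=atom_ids, dz=dz)
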