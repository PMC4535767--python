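"""Structures, ensembles and backbone dihedrals.

The interchange format is plain PDB text: single-model files for topologies
and reference structures, MODEL/ENDMDL multi-model files for conformational
ensembles (one model per fixed time interval, 1 ns by default).  Only the
ATOM/HETATM/MODEL/ENDMDL records are interpreted; altloc and insertion-code
dialects are out of scope.  Coordinates are written with the standard %8.3f
fields, so a write/read round trip is exact to 3 decimals (Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConsistencyError, FormatError, InputError, SelectionError
from .geometry import dihedral_angle

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "DihedralSeries",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
    "backbone_dihedrals",
]

#: residue names flagged as ligand when present as HETATM records
DEFAULT_LIGAND_RESNAMES: tuple[str, ...] = ("LIG",)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, PDB conventions (1-based residue numbers)."""

    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain: str
    element: str
    position: tuple[float, float, float]
    hetero: bool = False

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise InputError(f"atom serial must be positive, got {self.serial}")
        if self.residue_number < 1:
            raise InputError(f"residue_number must be >= 1, got {self.residue_number}")
        if not self.element:
            raise InputError("element symbol must be non-empty")
        if not all(np.isfinite(self.position)):
            raise InputError(f"non-finite position for atom {self.serial}")


class Structure:
    """An ordered atom list with an optional per-atom ligand flag.

    The atom order is the canonical frame order: every coordinate array in a
    :class:`Trajectory` indexes atoms exactly as they appear here.
    """

    def __init__(self, atoms: Sequence[AtomRecord], ligand_flags: Sequence[bool] | None = None):
        self.atoms: list[AtomRecord] = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise InputError("atom serials must be unique")
        if ligand_flags is None:
            ligand_flags = [a.hetero and a.residue_name in DEFAULT_LIGAND_RESNAMES for a in self.atoms]
        self.ligand_flags = np.asarray(ligand_flags, dtype=bool)
        if self.ligand_flags.shape != (len(self.atoms),):
            raise InputError("ligand_flags length must equal atom count")
        self.positions = np.array([a.position for a in self.atoms], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def with_positions(self, positions: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (same atom metadata)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_atoms, 3):
            raise InputError(f"positions shape {positions.shape} != ({self.n_atoms}, 3)")
        atoms = [
            AtomRecord(
                a.serial, a.name, a.residue_name, a.residue_number, a.chain,
                a.element, tuple(positions[i]), a.hetero,
            )
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, self.ligand_flags.copy())

    def residue_numbers(self) -> np.ndarray:
        return np.array([a.residue_number for a in self.atoms], dtype=int)

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.element.upper() != "H" for a in self.atoms], dtype=bool)


@dataclass
class Trajectory:
    """A conformational ensemble: topology plus per-frame coordinates.

    ``frame_interval`` is the simulated duration represented by one frame, in
    nanoseconds (snapshots taken every nanosecond by default).
    """

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InputError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ConsistencyError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.frame_interval <= 0:
            raise InputError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration_ns(self) -> float:
        """Total simulated time covered by the ensemble, ns."""
        return self.n_frames * self.frame_interval


@dataclass
class DihedralSeries:
    """Backbone (φ, ψ) pairs of one frame, degrees in (-180, +180].

    Undefined angles (chain termini, residues missing a backbone atom) are
    NaN and additionally flagged in ``defined``; they are never zero-filled.
    """

    frame_index: int
    angles: np.ndarray  # (n_residues, 2): [:, 0] = φ, [:, 1] = ψ
    residue_numbers: np.ndarray
    defined: np.ndarray  # (n_residues, 2) bool


# --- PDB text I/O -----------------------------------------------------------


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21] if len(line) > 21 and line[21].strip() else "A"
        resnum = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"line {lineno}: unparsable ATOM/HETATM record: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the leading letter of the atom name
        element = next((ch for ch in name if ch.isalpha()), "X")
    return AtomRecord(
        serial=serial,
        name=name,
        residue_name=resname,
        residue_number=resnum,
        chain=chain,
        element=element,
        position=(x, y, z),
        hetero=line.startswith("HETATM"),
    )


def read_structure(path: str | Path, ligand_resnames: Iterable[str] = DEFAULT_LIGAND_RESNAMES) -> Structure:
    """Read a single-model PDB file.

    HETATM records whose residue name is in ``ligand_resnames`` get
    ``ligand_flags`` set; everything else is protein/solute.  Coordinates are
    parsed at full file precision.
    """
    path = Path(path)
    ligand_resnames = set(ligand_resnames)
    atoms: list[AtomRecord] = []
    flags: list[bool] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            rec = _parse_atom_line(line, lineno)
            atoms.append(rec)
            flags.append(rec.hetero and rec.residue_name in ligand_resnames)
        elif line.startswith("ENDMDL"):
            break  # single-model read stops at the first model boundary
    if not atoms:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms, flags)


def _format_atom_line(atom: AtomRecord, position: np.ndarray) -> str:
    record = "HETATM" if atom.hetero else "ATOM  "
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    return (
        f"{record}{atom.serial:>5d} {name:<4s} {atom.residue_name:>3s} "
        f"{atom.chain}{atom.residue_number:>4d}    "
        f"{position[0]:8.3f}{position[1]:8.3f}{position[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file (%8.3f coordinate fields)."""
    lines = [
        _format_atom_line(a, structure.positions[i]) for i, a in enumerate(structure.atoms)
    ]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(
    path: str | Path,
    topology: Structure,
    frame_interval: float = 1.0,
) -> Trajectory:
    """Read a multi-model PDB ensemble against a known topology.

    Every MODEL block must carry exactly the topology's atom count; a mismatch
    raises a consistency error naming the offending model.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] | None = None
    model_number = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("MODEL"):
            model_number += 1
            current = []
        elif line.startswith(("ATOM  ", "HETATM")):
            if current is None:  # tolerate headerless single-model content
                model_number = 1
                current = []
            rec = _parse_atom_line(line, lineno)
            current.append(rec.position)
        elif line.startswith("ENDMDL"):
            if current is None:
                raise FormatError(f"line {lineno}: ENDMDL without MODEL")
            if len(current) != topology.n_atoms:
                raise ConsistencyError(
                    f"model {model_number}: {len(current)} atoms, expected {topology.n_atoms}"
                )
            frames.append(np.asarray(current, dtype=float))
            current = None
    if current:  # trailing model without ENDMDL
        if len(current) != topology.n_atoms:
            raise ConsistencyError(
                f"model {model_number}: {len(current)} atoms, expected {topology.n_atoms}"
            )
        frames.append(np.asarray(current, dtype=float))
    if not frames:
        raise FormatError(f"{path}: no models found")
    return Trajectory(topology, np.stack(frames), frame_interval)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB ensemble."""
    out: list[str] = []
    for m in range(trajectory.n_frames):
        out.append(f"MODEL     {m + 1:>4d}")
        frame = trajectory.frames[m]
        out.extend(
            _format_atom_line(a, frame[i]) for i, a in enumerate(trajectory.topology.atoms)
        )
        out.append("ENDMDL")
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


# --- selections -------------------------------------------------------------


def select_atoms(structure: Structure, selector: str) -> np.ndarray:
    """Resolve a selection expression to a strictly increasing index array.

    Three selector forms are supported:

    - ``"name CA"`` — atom-name match (case-insensitive);
    - ``"resid 175-185"`` or ``"resid 42"`` — 1-based inclusive residue range;
    - ``"ligand"`` — atoms with the ligand flag set.

    An empty result is valid (e.g. ``"ligand"`` on an apo structure).
    """
    tokens = selector.split()
    if not tokens:
        raise SelectionError("empty selector")
    kind = tokens[0].lower()
    if kind == "name" and len(tokens) == 2:
        want = tokens[1].upper()
        mask = np.array([a.name.upper() == want for a in structure.atoms])
    elif kind == "resid" and len(tokens) == 2:
        spec = tokens[1]
        try:
            if "-" in spec:
                lo_s, hi_s = spec.split("-", 1)
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(spec)
        except ValueError as exc:
            raise SelectionError(f"malformed residue range {spec!r}") from exc
        if lo > hi:
            raise SelectionError(f"reversed residue range {spec!r}")
        nums = structure.residue_numbers()
        mask = (nums >= lo) & (nums <= hi)
    elif kind == "ligand" and len(tokens) == 1:
        mask = structure.ligand_flags
    else:
        raise SelectionError(f"malformed selector {selector!r}")
    return np.flatnonzero(mask)


# --- backbone dihedrals -----------------------------------------------------


def _backbone_index(structure: Structure) -> tuple[list[tuple[str, int]], dict[tuple[str, int, str], int]]:
    """Residue order and (chain, resnum, atom-name) -> atom-index lookup."""
    residues: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    lookup: dict[tuple[str, int, str], int] = {}
    for i, a in enumerate(structure.atoms):
        if structure.ligand_flags[i]:
            continue
        key = (a.chain, a.residue_number)
        if key not in seen:
            seen.add(key)
            residues.append(key)
        lookup.setdefault((a.chain, a.residue_number, a.name.upper()), i)
    return residues, lookup


def backbone_dihedrals(trajectory: Trajectory) -> list[DihedralSeries]:
    """Per-frame backbone (φ, ψ) series for every protein residue.

    φ(i) = C(i-1)–N(i)–CA(i)–C(i); ψ(i) = N(i)–CA(i)–C(i)–N(i+1), both in
    degrees with the IUPAC sign convention.  Chain termini and residues
    missing a backbone atom are flagged undefined in every frame.
    """
    topo = trajectory.topology
    residues, lookup = _backbone_index(topo)
    if not residues:
        raise InputError("no protein residues in topology")
    n_res = len(residues)

    # quadruple atom indices per residue; -1 marks an undefined angle
    phi_idx = np.full((n_res, 4), -1, dtype=int)
    psi_idx = np.full((n_res, 4), -1, dtype=int)
    for r, (chain, num) in enumerate(residues):
        n_i = lookup.get((chain, num, "N"), -1)
        ca_i = lookup.get((chain, num, "CA"), -1)
        c_i = lookup.get((chain, num, "C"), -1)
        if r > 0 and residues[r - 1][0] == chain:
            c_prev = lookup.get((residues[r - 1][0], residues[r - 1][1], "C"), -1)
        else:
            c_prev = -1
        if r < n_res - 1 and residues[r + 1][0] == chain:
            n_next = lookup.get((residues[r + 1][0], residues[r + 1][1], "N"), -1)
        else:
            n_next = -1
        if min(c_prev, n_i, ca_i, c_i) >= 0:
            phi_idx[r] = (c_prev, n_i, ca_i, c_i)
        if min(n_i, ca_i, c_i, n_next) >= 0:
            psi_idx[r] = (n_i, ca_i, c_i, n_next)

    phi_ok = phi_idx[:, 0] >= 0
    psi_ok = psi_idx[:, 0] >= 0
    if not (phi_ok.any() or psi_ok.any()):
        raise InputError("no defined backbone dihedral in any residue")
    resnums = np.array([num for _, num in residues], dtype=int)
    defined = np.column_stack([phi_ok, psi_ok])

    out: list[DihedralSeries] = []
    for f in range(trajectory.n_frames):
        xyz = trajectory.frames[f]
        angles = np.full((n_res, 2), np.nan)
        if phi_ok.any():
            q = phi_idx[phi_ok]
            angles[phi_ok, 0] = dihedral_angle(xyz[q[:, 0]], xyz[q[:, 1]], xyz[q[:, 2]], xyz[q[:, 3]])
        if psi_ok.any():
            q = psi_idx[psi_ok]
            angles[psi_ok, 1] = dihedral_angle(xyz[q[:, 0]], xyz[q[:, 1]], xyz[q[:, 2]], xyz[q[:, 3]])
        out.append(DihedralSeries(f, angles, resnums, defined))
    return out
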