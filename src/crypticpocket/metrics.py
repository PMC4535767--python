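"""Per-frame scalar series characterizing conformational events.

Three series cover the phenomenology of a gated transient site: the
flap-to-anchor gap (minimum Cα–Cα distance between two residue ranges,
capturing open/closed flap motion), the helicity fraction of a residue range
(capturing repeated helix unwinding/rewinding), and the ligand pose RMSD
under protein-frame superposition (capturing pose stability vs. excursions).
A hysteresis threshold detector turns any of these series into discrete
rising/falling transition events.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, SelectionError
from .geometry import apply_transform, kabsch
from .pdbio import DihedralSeries, Structure, Trajectory, select_atoms

__all__ = [
    "ResidueRange",
    "SeriesMetric",
    "TransitionEvent",
    "HELICAL_PHI_RANGE",
    "HELICAL_PSI_RANGE",
    "loop_gap_series",
    "helicity_series",
    "ligand_rmsd_series",
    "detect_state_transitions",
    "series_to_csv",
    "events_to_csv",
]

#: broad α-helical region of the Ramachandran map used for the helicity fraction
HELICAL_PHI_RANGE: tuple[float, float] = (-100.0, -30.0)
HELICAL_PSI_RANGE: tuple[float, float] = (-80.0, -5.0)


@dataclass(frozen=True)
class ResidueRange:
    """1-based inclusive residue range."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParameterError(f"reversed residue range {self.start}-{self.end}")

    def contains(self, resnum: np.ndarray) -> np.ndarray:
        return (np.asarray(resnum) >= self.start) & (np.asarray(resnum) <= self.end)

    def overlaps(self, other: "ResidueRange") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class SeriesMetric:
    """A named per-frame scalar series with its units and parameters."""

    name: str
    values: np.ndarray
    units: str
    params: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class TransitionEvent:
    frame: int
    direction: str  # "rising" | "falling"


def _ca_for_range(structure: Structure, rng: ResidueRange) -> np.ndarray:
    ca = select_atoms(structure, "name CA")
    resnums = structure.residue_numbers()[ca]
    idx = ca[rng.contains(resnums)]
    if idx.size == 0:
        raise InputError(f"no Cα atoms in residue range {rng.start}-{rng.end}")
    return idx


def loop_gap_series(trajectory: Trajectory, range_a: ResidueRange, range_b: ResidueRange) -> SeriesMetric:
    """Per-frame minimum Cα–Cα distance between two disjoint residue ranges (Å).

    The minimum over all cross pairs is robust to internal rearrangement of
    either range, so the series reads directly as flap open/closed gap.
    """
    if range_a.overlaps(range_b):
        raise ParameterError(f"ranges {range_a} and {range_b} overlap")
    ia = _ca_for_range(trajectory.topology, range_a)
    ib = _ca_for_range(trajectory.topology, range_b)
    a = trajectory.frames[:, ia, :]
    b = trajectory.frames[:, ib, :]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)
    values = d.reshape(trajectory.n_frames, -1).min(axis=1)
    return SeriesMetric(
        "loop_gap", values, "A",
        {"range_a": (range_a.start, range_a.end), "range_b": (range_b.start, range_b.end)},
    )


def helicity_series(dihedrals: list[DihedralSeries], rng: ResidueRange) -> SeriesMetric:
    """Fraction of the range's residues in the α-helical (φ, ψ) window, per frame.

    Residues with an undefined φ or ψ are excluded from the denominator.
    """
    if not dihedrals:
        raise InputError("empty dihedral series")
    resnums = dihedrals[0].residue_numbers
    in_range = rng.contains(resnums)
    both_defined = dihedrals[0].defined.all(axis=1)
    usable = in_range & both_defined
    if not usable.any():
        raise InputError(f"residue range {rng.start}-{rng.end} has no defined dihedrals")
    values = np.empty(len(dihedrals))
    for i, s in enumerate(dihedrals):
        phi = s.angles[usable, 0]
        psi = s.angles[usable, 1]
        helical = (
            (phi >= HELICAL_PHI_RANGE[0]) & (phi <= HELICAL_PHI_RANGE[1])
            & (psi >= HELICAL_PSI_RANGE[0]) & (psi <= HELICAL_PSI_RANGE[1])
        )
        values[i] = helical.mean()
    return SeriesMetric("helicity", values, "fraction", {"range": (rng.start, rng.end)})


def ligand_rmsd_series(trajectory: Trajectory, ligand: np.ndarray, protein_ref: np.ndarray) -> SeriesMetric:
    """Ligand pose RMSD from frame 1 under protein-frame superposition (Å).

    Each frame is superposed onto the first frame over ``protein_ref``; the
    value is then the RMSD of the ligand atoms with no separate ligand refit,
    so ligand excursions inside a stable protein frame register directly.
    """
    ligand = np.asarray(ligand, dtype=int)
    protein_ref = np.asarray(protein_ref, dtype=int)
    if ligand.size == 0 or protein_ref.size == 0:
        raise SelectionError("ligand and protein selections must be non-empty")
    if np.intersect1d(ligand, protein_ref).size:
        raise SelectionError("ligand and protein selections must be disjoint")
    ref = trajectory.frames[0]
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        rot, trans, _ = kabsch(trajectory.frames[f][protein_ref], ref[protein_ref])
        moved = apply_transform(trajectory.frames[f][ligand], rot, trans)
        values[f] = float(np.sqrt(((moved - ref[ligand]) ** 2).sum(axis=1).mean()))
    return SeriesMetric(
        "ligand_rmsd", values, "A",
        {"n_ligand_atoms": int(ligand.size), "n_protein_ref": int(protein_ref.size)},
    )


def detect_state_transitions(
    series: SeriesMetric, threshold: float, hysteresis: float = 0.0, min_dwell: int = 1
) -> list[TransitionEvent]:
    """Hysteresis (Schmitt-trigger) event detection with a dwell requirement.

    A falling event fires at the first frame of a run that stays below
    ``threshold - hysteresis`` for at least ``min_dwell`` frames; rising
    events are symmetric about ``threshold + hysteresis``.  Events alternate
    by construction.
    """
    if min_dwell < 1:
        raise ParameterError("min_dwell must be >= 1")
    if hysteresis < 0:
        raise ParameterError("hysteresis must be >= 0")
    v = series.values
    lo = threshold - hysteresis
    hi = threshold + hysteresis
    state = "high" if v[0] > threshold else "low"
    events: list[TransitionEvent] = []
    t = 0
    n = len(v)
    while t < n:
        if state == "high" and v[t] < lo:
            end = t
            while end + 1 < n and v[end + 1] < lo:
                end += 1
            if end - t + 1 >= min_dwell:
                events.append(TransitionEvent(t, "falling"))
                state = "low"
            t = end + 1
        elif state == "low" and v[t] > hi:
            end = t
            while end + 1 < n and v[end + 1] > hi:
                end += 1
            if end - t + 1 >= min_dwell:
                events.append(TransitionEvent(t, "rising"))
                state = "high"
            t = end + 1
        else:
            t += 1
    return events


def series_to_csv(series: SeriesMetric, path: str | Path, frame_interval: float = 1.0) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(series.values)),
            "time_ns": np.arange(len(series.values)) * frame_interval,
            "value": series.values,
        }
    )
    buf = io.StringIO()
    buf.write(f"# {series.name} [{series.units}]; params={series.params}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def events_to_csv(events: list[TransitionEvent], path: str | Path) -> None:
    df = pd.DataFrame([{"frame": e.frame, "direction": e.direction} for e in events])
    Path(path).write_text(df.to_csv(index=False))
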