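"""Synthetic conformational ensembles with planted ground truth.

The real system this package targets — a multi-microsecond simulation of a
~230-residue nuclear-receptor ligand-binding domain — is not distributable,
so every analysis stage is exercised on generated data that reproduces the
statistical structure the analyses assume:

* a compact helix-bundle pseudo-protein with ideal backbone geometry,
* a small library of well-separated conformational states whose differences
  are concentrated in backbone torsions (so that both Cartesian clustering
  and dihedral-state segmentation can recover them),
* a piecewise-constant state schedule with essentially irreversible
  transitions plus isotropic Gaussian coordinate noise per frame, and
* a transient cavity of prescribed volume that exists only in designated
  "open" states, gated by a flap of consecutive residues.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .errors import GenerationError, SpecError
from .geometry import kabsch, nerf_place
from .pdbio import AtomRecord, Structure, Trajectory

__all__ = [
    "ToyProteinSpec",
    "StateLibrary",
    "StateSchedule",
    "CavitySpec",
    "build_toy_protein",
    "make_state_library",
    "generate_trajectory",
    "plant_transient_cavity",
]

# canonical backbone internal coordinates (Å / degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_CA_C_O = 120.8
_OMEGA = 180.0

#: ideal α-helix torsions used for helical segments
HELIX_PHI = -60.0
HELIX_PSI = -45.0

_LOOP_LEN = 4  # residues per inter-helix connector


@dataclass(frozen=True)
class ToyProteinSpec:
    """Specification of a helix-bundle pseudo-protein.

    ``helix_radius`` is the distance of each helix axis from the bundle axis;
    smaller radii pack the bundle more tightly and shrink the central channel.
    """

    n_residues: int = 64
    n_helices: int = 4
    helix_radius: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 20:
            raise SpecError(f"n_residues must be >= 20, got {self.n_residues}")
        if self.n_helices < 2:
            raise SpecError(f"n_helices must be >= 2, got {self.n_helices}")

    def segment_layout(self) -> list[tuple[str, int, int]]:
        """(kind, first_resnum, last_resnum) for alternating helix/loop segments."""
        n_loop = (self.n_helices - 1) * _LOOP_LEN
        n_helix_res = self.n_residues - n_loop
        per = n_helix_res // self.n_helices
        if per < 6:
            raise SpecError(
                f"{self.n_residues} residues cannot form {self.n_helices} helices "
                f"of >= 6 residues with {_LOOP_LEN}-residue connectors"
            )
        lengths = [per] * self.n_helices
        for i in range(n_helix_res - per * self.n_helices):
            lengths[i] += 1
        layout: list[tuple[str, int, int]] = []
        pos = 1
        for h, L in enumerate(lengths):
            layout.append(("helix", pos, pos + L - 1))
            pos += L
            if h < self.n_helices - 1:
                layout.append(("loop", pos, pos + _LOOP_LEN - 1))
                pos += _LOOP_LEN
        return layout


@dataclass
class StateLibrary:
    """Discrete conformational states sharing one topology.

    ``min_separation`` is the realized lower bound δ on pairwise superposed
    Cα-RMSD between conformers (``None`` for a single-state library).
    """

    base: Structure
    conformers: np.ndarray  # (K, n_atoms, 3)
    labels: list[str]
    min_separation: float | None = None
    cavity: "CavitySpec | None" = None

    @property
    def n_states(self) -> int:
        return int(self.conformers.shape[0])

    def coords_for(self, label: str) -> np.ndarray:
        return self.conformers[self.labels.index(label)]


@dataclass(frozen=True)
class StateSchedule:
    """Contiguous, non-overlapping (label, start_ns, end_ns) occupation entries."""

    entries: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise SpecError("schedule must have at least one entry")
        prev_end = None
        for label, start, end in self.entries:
            if end <= start:
                raise SpecError(f"entry {label!r}: end {end} <= start {start}")
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise SpecError(f"entry {label!r}: schedule not contiguous at {start} ns")
            prev_end = end
        if abs(self.entries[0][1]) > 1e-9:
            raise SpecError("schedule must start at 0 ns")

    @property
    def duration_ns(self) -> float:
        return self.entries[-1][2]

    def state_at(self, t_ns: float) -> str:
        for label, start, end in self.entries:
            if start <= t_ns < end:
                return label
        return self.entries[-1][0]


@dataclass(frozen=True)
class CavitySpec:
    """A transient cavity gated by a flap of consecutive residues.

    In ``open_states`` the gate residues are displaced outward onto a shell
    that encloses a void of ``target_volume`` around ``cavity_center``; in
    every other state the structure is left untouched, so the site is just
    ordinary protein surface there.  ``clearance`` is the probe exclusion
    radius used when measuring the enclosed void (matching the pocket
    detector's default exclusion radius).
    """

    gate_range: tuple[int, int]
    cavity_center: tuple[float, float, float]
    open_states: tuple[str, ...]
    target_volume: float = 150.0
    cavity_radius: float | None = None  # realized shell radius, filled at planting
    clearance: float = 2.5
    mouth_fraction: float = 0.0  # fraction of shell solid angle left open

    def __post_init__(self) -> None:
        if self.target_volume <= 0:
            raise SpecError("target_volume must be positive")
        if self.gate_range[0] > self.gate_range[1]:
            raise SpecError(f"reversed gate_range {self.gate_range}")


# --- toy protein ------------------------------------------------------------


def _extend_backbone(chain: list[np.ndarray], phi: float, psi_prev: float) -> None:
    """Append N, CA, C of the next residue given ψ of the previous one."""
    a, b, c = chain[-3], chain[-2], chain[-1]  # N, CA, C of previous residue
    n = nerf_place(a, b, c, _BOND_C_N, _ANG_CA_C_N, psi_prev)
    ca = nerf_place(b, c, n, _BOND_N_CA, _ANG_C_N_CA, _OMEGA)
    cc = nerf_place(c, n, ca, _BOND_CA_C, _ANG_N_CA_C, phi)
    chain.extend([n, ca, cc])


def _build_chain(torsions: np.ndarray) -> np.ndarray:
    """Backbone N/CA/C chain from per-residue (φ, ψ); first φ and last ψ unused."""
    n_res = len(torsions)
    chain = [
        np.array([0.0, 0.0, 0.0]),
        np.array([_BOND_N_CA, 0.0, 0.0]),
    ]
    # first C placed in the xy-plane at the ideal N-CA-C angle
    ang = np.radians(180.0 - _ANG_N_CA_C)
    chain.append(chain[1] + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0]))
    for r in range(1, n_res):
        _extend_backbone(chain, torsions[r, 0], torsions[r - 1, 1])
    return np.asarray(chain).reshape(n_res, 3, 3)


def _add_oxygens(ncac: np.ndarray, torsions: np.ndarray) -> np.ndarray:
    """(n_res, 4, 3) backbone with carbonyl O placed anti to ψ."""
    n_res = ncac.shape[0]
    out = np.zeros((n_res, 4, 3))
    out[:, :3] = ncac
    for r in range(n_res):
        psi = torsions[r, 1] if r < n_res - 1 else HELIX_PSI
        out[r, 3] = nerf_place(
            ncac[r, 0], ncac[r, 1], ncac[r, 2], _BOND_C_O, _ANG_CA_C_O, psi + 180.0
        )
    return out


def _extend_segment(triad: Sequence[np.ndarray], psis_prev: np.ndarray, phis: np.ndarray) -> np.ndarray:
    """NeRF-extend a chain from the previous residue's (N, CA, C) triad.

    ``psis_prev[j]`` is ψ of the residue preceding extension residue ``j``;
    ``phis[j]`` is φ of extension residue ``j``.
    """
    chain = [np.asarray(p, dtype=float) for p in triad]
    for psi_prev, phi in zip(psis_prev, phis):
        _extend_backbone(chain, phi, psi_prev)
    return np.asarray(chain[3:]).reshape(-1, 3, 3)


def _helix_template(n_res: int) -> np.ndarray:
    t = np.tile([HELIX_PHI, HELIX_PSI], (n_res, 1))
    return _build_chain(t)


def _target_frames(spec: ToyProteinSpec) -> list[np.ndarray]:
    """Rigidly placed ideal helices: (n_res_k, 3, 3) target N/CA/C coordinates.

    Helices run antiparallel (alternating ±z) on a circle of ``helix_radius``
    about the bundle axis.
    """
    layout = [seg for seg in spec.segment_layout() if seg[0] == "helix"]
    targets = []
    for k, (_, lo, hi) in enumerate(layout):
        L = hi - lo + 1
        tmpl = _helix_template(L).reshape(-1, 3)
        # orient the template's principal axis along z
        ctr = tmpl.mean(axis=0)
        u, s, vt = np.linalg.svd(tmpl - ctr)
        axis = vt[0] if vt[0, 2] >= 0 else -vt[0]
        # rotation taking `axis` to ±z
        direction = 1.0 if k % 2 == 0 else -1.0
        zhat = np.array([0.0, 0.0, direction])
        v = np.cross(axis, zhat)
        c = float(np.dot(axis, zhat))
        if np.linalg.norm(v) < 1e-12:
            rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
        placed = (tmpl - ctr) @ rot.T
        theta = 2.0 * np.pi * k / spec.n_helices
        offset = spec.helix_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        targets.append((placed + offset).reshape(L, 3, 3))
    return targets


def build_toy_protein(spec: ToyProteinSpec) -> Structure:
    """Deterministic helix-bundle pseudo-protein with ideal backbone geometry.

    The chain is grown residue-by-residue from canonical internal coordinates
    (so every bond length and angle is exact); helical segments use ideal α
    torsions and each connector's torsions are solved by least squares so the
    following helix lands on its target position in the bundle.
    """
    from .geometry import apply_transform  # local import to avoid cycle noise

    layout = spec.segment_layout()
    n_res = spec.n_residues
    h_ranges = [(lo - 1, hi) for kind, lo, hi in layout if kind == "helix"]  # 0-based [lo, hi)
    l_ranges = [(lo - 1, hi) for kind, lo, hi in layout if kind == "loop"]

    torsions = np.tile([HELIX_PHI, HELIX_PSI], (n_res, 1))
    targets = _target_frames(spec)

    for g, (llo, lhi) in enumerate(l_ranges):
        n_loop = lhi - llo
        prefix = _build_chain(torsions[:llo])
        triad = prefix[-1]
        # re-anchor the plan to the as-built previous helix so each closure is
        # the same local problem and placement error cannot accumulate
        hlo_prev, hhi_prev = h_ranges[g]
        rot, trans, _ = kabsch(
            targets[g].reshape(-1, 3), prefix[hlo_prev:hhi_prev].reshape(-1, 3)
        )
        target = apply_transform(targets[g + 1][0], rot, trans)

        # every backbone atom built so far; clash pairs are exempted by chain
        # distance (<= 3 atom steps covers bonds and 1-3/1-4 neighbours)
        bulk = prefix.reshape(-1, 3)
        n_bulk = len(bulk)
        n_ext = (n_loop + 1) * 3
        ext_flat = n_bulk + np.arange(n_ext)
        step = ext_flat[:, None] - np.arange(n_bulk)[None, :]
        cross_ok = step > 3
        ii, jj = np.triu_indices(n_ext, k=4)
        clash_cut = 3.2

        def extension(x: np.ndarray) -> np.ndarray:
            psis_prev = np.concatenate([[HELIX_PSI], x[1::2]])
            phis = np.concatenate([x[0::2], [HELIX_PHI]])
            return _extend_segment(triad, psis_prev, phis)

        def residual(x: np.ndarray) -> np.ndarray:
            ext = extension(x)
            closure = (ext[-1] - target).ravel()
            pts = ext.reshape(-1, 3)
            d = np.linalg.norm(pts[:, None, :] - bulk[None, :, :], axis=-1)
            d = np.where(cross_ok, d, np.inf)
            pen = np.maximum(0.0, clash_cut - d.min(axis=1))
            d_self = np.linalg.norm(pts[ii] - pts[jj], axis=-1)
            pen_self = np.maximum(0.0, clash_cut - d_self)
            return np.concatenate([closure, 2.0 * pen, 2.0 * pen_self])

        starts = [
            np.tile([-70.0, 140.0], n_loop),
            np.tile([-100.0, 20.0], n_loop),
            np.tile([60.0, 40.0], n_loop),
            np.tile([-140.0, 150.0], n_loop),
            np.tile([-60.0, -45.0], n_loop),
        ]
        rng = np.random.default_rng(spec.seed * 7919 + g)
        starts += [rng.uniform(-170.0, 170.0, 2 * n_loop) for _ in range(12)]
        best: tuple[float, np.ndarray] | None = None
        for x0 in starts:
            sol = least_squares(residual, np.asarray(x0, dtype=float), method="trf", max_nfev=4000)
            fun = residual(sol.x)
            closure_err = float(np.linalg.norm(fun[:9]))
            clash_err = float(np.linalg.norm(fun[9:]))
            score = closure_err + 10.0 * clash_err
            if best is None or score < best[0]:
                best = (score, sol.x)
            if closure_err < 1e-6 and clash_err == 0.0:
                break
        torsions[llo:lhi, 0] = best[1][0::2]
        torsions[llo:lhi, 1] = best[1][1::2]

    coords = _build_chain(torsions)
    full = _add_oxygens(coords, torsions)
    # pseudo side chain: a CB filler atom keeps the bundle core packed the
    # way real side chains would, so the only sizeable cavities are planted
    cb = np.array(
        [
            nerf_place(coords[r, 2], coords[r, 0], coords[r, 1], 1.53, 110.5, 122.6)
            for r in range(n_res)
        ]
    )
    atoms: list[AtomRecord] = []
    serial = 1
    # CB sits between CA and C in the atom order: a φ rotation (about N-CA)
    # then carries it with the C side, while a ψ rotation (about CA-C) leaves
    # it in the N-CA frame — both preserve its bonded geometry
    names = ("N", "CA", "CB", "C", "O")
    elements = ("N", "C", "C", "C", "O")
    for r in range(n_res):
        pos = (full[r, 0], full[r, 1], cb[r], full[r, 2], full[r, 3])
        for j in range(5):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=names[j],
                    residue_name="ALA",
                    residue_number=r + 1,
                    chain="A",
                    element=elements[j],
                    position=tuple(pos[j]),
                )
            )
            serial += 1
    return Structure(atoms)


# --- state library ----------------------------------------------------------


def _rotate_about_axis(points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    ang = np.radians(angle_deg)
    k = axis
    p = points - origin
    rot = (
        p * np.cos(ang)
        + np.cross(k, p) * np.sin(ang)
        + np.outer(p @ k, k) * (1.0 - np.cos(ang))
    )
    return rot + origin


def _apply_torsion_change(
    coords: np.ndarray, structure: Structure, residue: int, which: str, delta_deg: float
) -> np.ndarray:
    """Rotate all atoms downstream of a backbone torsion of ``residue`` (1-based)."""
    resnums = structure.residue_numbers()
    names = np.array([a.name.upper() for a in structure.atoms])
    sel = resnums == residue
    if which == "phi":
        a_idx = np.flatnonzero(sel & (names == "N"))[0]
        b_idx = np.flatnonzero(sel & (names == "CA"))[0]
    else:
        a_idx = np.flatnonzero(sel & (names == "CA"))[0]
        b_idx = np.flatnonzero(sel & (names == "C"))[0]
    out = coords.copy()
    downstream = np.arange(len(coords)) > b_idx
    out[downstream] = _rotate_about_axis(
        coords[downstream], coords[a_idx], coords[b_idx] - coords[a_idx], delta_deg
    )
    return out


def _ca_indices(structure: Structure) -> np.ndarray:
    return np.flatnonzero(np.array([a.name.upper() == "CA" for a in structure.atoms]))


def _gray_codes(n_codes: int, n_bits: int) -> list[int]:
    """First ``n_codes`` nonzero reflected-Gray-code values (consecutive codes
    differ in exactly one bit, and the first differs from zero in one bit)."""
    codes = [i ^ (i >> 1) for i in range(1, 2**n_bits)]
    if n_codes > len(codes):
        raise SpecError(f"cannot encode {n_codes} states with {n_bits} blocks")
    return codes[:n_codes]


def make_state_library(
    structure: Structure,
    K: int,
    displacement: float,
    seed: int,
    min_separation: float | None = None,
    tail_fraction: float = 0.55,
    max_retries: int = 6,
) -> StateLibrary:
    """Build K conformers separated by at least ``min_separation`` Cα-RMSD.

    Conformer 1 is the base structure.  The C-terminal ``tail_fraction`` of
    the chain is partitioned into blocks, one near-antipodal torsion flip
    (140-180°) is drawn once per tail torsion, and each further conformer
    applies the flips of a Gray-coded block subset.  This design gives the
    states three properties the downstream analyses rely on:

    * the N-terminal core — and hence a gated cavity site there — is
      identical across states, so pockets map consistently between them;
    * every backbone dihedral takes at most two well-separated values across
      the whole library, so dihedral-state discretization stays clean under
      heavy thermal noise; and
    * consecutive states differ in a full block of residues, giving both a
      large Cα displacement and a large dihedral-string change at every
      scheduled transition.

    If the realized pairwise separation δ falls short of ``min_separation``
    (reported in the returned library), generation retries with a wider tail
    and fresh flip draws before giving up.
    """
    if K < 1:
        raise SpecError(f"K must be >= 1, got {K}")
    base = structure.positions.copy()
    if K == 1:
        return StateLibrary(structure, base[None], ["S1"], None)
    if min_separation is None:
        min_separation = displacement

    ca = _ca_indices(structure)
    n_res = int(structure.residue_numbers().max())
    n_bits = max(2, int(np.ceil(np.log2(K))))
    codes = _gray_codes(K - 1, n_bits)
    rng = np.random.default_rng(seed)

    for attempt in range(max_retries):
        frac = min(tail_fraction + 0.05 * attempt, 0.75)
        tail_start = n_res - int(round(n_res * frac)) + 1
        tail = np.arange(tail_start, n_res + 1)
        block_edges = np.linspace(0, len(tail), n_bits + 1).astype(int)
        blocks = [tail[block_edges[b] : block_edges[b + 1]] for b in range(n_bits)]
        flips = {
            (int(r), which): float(rng.uniform(140.0, 180.0) * rng.choice([-1.0, 1.0]))
            for r in tail
            for which in ("phi", "psi")
        }
        conformers = [base]
        for code in codes:
            coords = base.copy()
            for b in range(n_bits):
                if not code & (1 << b):
                    continue
                for r in blocks[b]:
                    for which in ("phi", "psi"):
                        coords = _apply_torsion_change(
                            coords, structure, int(r), which, flips[(int(r), which)]
                        )
            conformers.append(coords)
        stack = np.stack(conformers)
        sep = np.inf
        for i in range(K):
            for j in range(i + 1, K):
                _, _, r = kabsch(stack[i][ca], stack[j][ca])
                sep = min(sep, r)
        if sep >= min_separation:
            labels = [f"S{i + 1}" for i in range(K)]
            return StateLibrary(structure, stack, labels, float(sep))
    raise GenerationError(
        f"could not separate {K} conformers by {min_separation} Å after {max_retries} attempts"
    )


# --- trajectory -------------------------------------------------------------


def generate_trajectory(
    library: StateLibrary,
    schedule: StateSchedule,
    noise_sd: float,
    seed: int,
    frame_interval: float = 1.0,
) -> tuple[Trajectory, np.ndarray]:
    """Render a schedule into a noisy trajectory plus ground-truth labels.

    Frame ``t`` takes the scheduled state's coordinates plus iid isotropic
    Gaussian displacement (standard deviation ``noise_sd`` per coordinate
    component, Å).  Returns the trajectory and the per-frame state labels.
    """
    for label, _, _ in schedule.entries:
        if label not in library.labels:
            raise SpecError(f"schedule references unknown state {label!r}")
    if noise_sd < 0:
        raise SpecError("noise_sd must be >= 0")
    n_frames = int(round(schedule.duration_ns / frame_interval))
    rng = np.random.default_rng(seed)
    labels = np.empty(n_frames, dtype=object)
    frames = np.empty((n_frames, library.base.n_atoms, 3))
    for t in range(n_frames):
        lab = schedule.state_at((t + 0.5) * frame_interval)
        labels[t] = lab
        frames[t] = library.coords_for(lab)
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    return Trajectory(library.base, frames, frame_interval), labels


# --- transient cavity -------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral construction)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    th = golden * k
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def _void_volume(atoms: np.ndarray, center: np.ndarray, radius: float, clearance: float, grid: float = 0.3) -> float:
    """Fine-grid integral of the void (points > clearance from every atom)
    inside the ball of ``radius`` about ``center``."""
    ax = np.arange(-radius, radius + grid, grid)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius] + center
    d, _ = cKDTree(atoms).query(pts, workers=-1)
    return float((d > clearance).sum() * grid**3)


def plant_transient_cavity(library: StateLibrary, cavity: CavitySpec) -> StateLibrary:
    """Open a gated cavity of the prescribed volume in the designated states.

    In each open state the gate residues' atoms are displaced outward onto a
    quasi-uniform shell around ``cavity_center``; the shell radius is solved
    by bisection so that the enclosed void (measured by fine-grid integration
    with the spec's probe clearance) matches ``target_volume``.  Closed
    states are returned untouched; non-gate atoms are never moved.
    """
    unknown = set(cavity.open_states) - set(library.labels)
    if unknown:
        raise SpecError(f"open_states not in library: {sorted(unknown)}")
    if not cavity.open_states:
        return library

    structure = library.base
    resnums = structure.residue_numbers()
    lo, hi = cavity.gate_range
    gate_mask = (resnums >= lo) & (resnums <= hi)
    if not gate_mask.any():
        raise SpecError(f"gate_range {cavity.gate_range} selects no atoms")
    gate_idx = np.flatnonzero(gate_mask)
    other_idx = np.flatnonzero(~gate_mask)
    center = np.asarray(cavity.cavity_center, dtype=float)

    conformers = library.conformers.copy()
    realized_radius = None
    for label in cavity.open_states:
        k = library.labels.index(label)
        coords = conformers[k]
        # the cavity must not be pre-occluded by atoms the gate cannot move
        d_other = np.linalg.norm(coords[other_idx] - center, axis=1)
        if (d_other < 1.7).any():
            bad = other_idx[int(np.argmin(d_other))]
            raise SpecError(
                f"cavity_center lies inside non-gate atom {structure.atoms[bad].serial} "
                f"in state {label!r}"
            )
        shell_dirs = _fibonacci_sphere(len(gate_idx))
        if cavity.mouth_fraction > 0:
            keep = shell_dirs[:, 2] < (1.0 - 2.0 * cavity.mouth_fraction)
            shell_dirs = shell_dirs[keep]

        def volume_at(radius: float) -> float:
            trial = coords.copy()
            n_shell = len(shell_dirs)
            trial[gate_idx[:n_shell]] = center + radius * shell_dirs
            # leftover gate atoms (if mouth trimming shrank the shell) stack on the shell
            for extra, gi in enumerate(gate_idx[n_shell:]):
                trial[gi] = center + radius * shell_dirs[extra % n_shell] * 1.05
            return _void_volume(trial, center, radius, cavity.clearance)

        r_cav = (3.0 * cavity.target_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        lo_r, hi_r = r_cav + cavity.clearance * 0.5, r_cav + cavity.clearance + 2.5
        if volume_at(hi_r) < cavity.target_volume:
            raise SpecError(
                f"cannot enclose {cavity.target_volume} Å³ at {tuple(center)} in state {label!r}"
            )
        for _ in range(24):
            mid = 0.5 * (lo_r + hi_r)
            if volume_at(mid) < cavity.target_volume:
                lo_r = mid
            else:
                hi_r = mid
        radius = hi_r
        realized_radius = radius
        n_shell = len(shell_dirs)
        coords = coords.copy()
        coords[gate_idx[:n_shell]] = center + radius * shell_dirs
        for extra, gi in enumerate(gate_idx[n_shell:]):
            coords[gi] = center + radius * shell_dirs[extra % n_shell] * 1.05
        conformers[k] = coords

    planted = replace(cavity, cavity_radius=float(realized_radius))
    return StateLibrary(library.base, conformers, list(library.labels), library.min_separation, planted)
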