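"""Grid-based buriedness pocket detection on a single structure.

A cubic lattice is laid over the protein; lattice points outside the protein
(farther than the exclusion radius from every heavy atom) are scanned with a
fixed fan of quasi-uniform ray directions, and a point is buried when enough
rays encounter protein within the ray length.  Buried points are grouped into
26-connected components; components at or above the minimum volume are the
reported pockets, numbered by volume in ascending order.  Hydrogens are
ignored throughout.

For speed, atom distances are evaluated once on a half-spacing sub-lattice
and ray samples (taken every half spacing, as the scan prescribes) look up
the nearest sub-lattice node; candidate points coincide with sub-lattice
nodes, so the exclusion test is exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InputError, ParameterError
from .pdbio import AtomRecord, Structure

__all__ = [
    "Grid",
    "DetectorParams",
    "Pocket",
    "BuriednessMap",
    "build_grid",
    "buriedness_map",
    "detect_pockets",
    "flanking_residues",
    "ray_directions",
    "pockets_to_csv",
    "pocket_points_to_pdb",
]


@dataclass(frozen=True)
class Grid:
    """Axis-aligned cubic lattice; cell i spans [origin + i*spacing, origin + (i+1)*spacing)."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ParameterError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ParameterError(f"grid dims must be positive, got {self.dims}")

    def point_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Cartesian coordinates of lattice nodes given integer (i, j, k) triples."""
        return np.asarray(self.origin) + np.asarray(ijk, dtype=float) * self.spacing

    def quantize(self, coords: np.ndarray) -> np.ndarray:
        """Nearest lattice node for each Cartesian point."""
        return np.rint((np.asarray(coords, dtype=float) - np.asarray(self.origin)) / self.spacing).astype(int)


@dataclass(frozen=True)
class DetectorParams:
    """Buriedness-scan parameters.

    ``buriedness_min`` of the ``n_rays`` fixed directions must encounter a
    heavy atom (pass within ``hit_radius``) along ``ray_length`` for a point
    to count as buried; ``min_volume`` (Å³) filters the reported pockets.
    """

    spacing: float = 1.0
    n_rays: int = 30
    ray_length: float = 10.0
    hit_radius: float = 2.5
    buriedness_min: int = 26
    exclusion_radius: float = 2.5
    min_volume: float = 100.0
    grid_margin: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.buriedness_min <= self.n_rays):
            raise ParameterError("need 0 < buriedness_min <= n_rays")
        if self.min_volume <= 0:
            raise ParameterError("min_volume must be positive")


@dataclass
class Pocket:
    """One connected component of buried lattice points."""

    id: int
    snapshot_label: str
    points: np.ndarray  # (m, 3) integer lattice indices
    volume: float  # Å³ = m * spacing³
    centroid: np.ndarray  # (3,) Å
    flanking: list[int]  # residue numbers within the contact cutoff
    grid: Grid


@dataclass
class BuriednessMap:
    """Ray-hit counts for every candidate (outside-protein) lattice point."""

    grid: Grid
    candidate_ijk: np.ndarray  # (n_candidates, 3)
    counts: np.ndarray  # (n_candidates,)


def ray_directions(n: int) -> np.ndarray:
    """The fixed fan of ``n`` quasi-uniform unit vectors (golden-spiral set)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    th = np.pi * (3.0 - np.sqrt(5.0)) * k
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def _heavy_coords(structure: Structure, coords: np.ndarray | None) -> np.ndarray:
    xyz = structure.positions if coords is None else np.asarray(coords, dtype=float)
    heavy = structure.heavy_mask()
    out = xyz[heavy]
    if len(out) == 0:
        raise InputError("structure has no heavy atoms")
    return out


def build_grid(structure: Structure, margin: float, spacing: float, coords: np.ndarray | None = None) -> Grid:
    """Bounding box of the heavy atoms expanded by ``margin``, discretized at ``spacing``."""
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    xyz = _heavy_coords(structure, coords)
    lo = xyz.min(axis=0) - margin
    hi = xyz.max(axis=0) + margin
    dims = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    return Grid(tuple(lo), spacing, dims)


def _sublattice_distances(grid: Grid, atoms: np.ndarray) -> tuple[np.ndarray, float]:
    """Distance to the nearest heavy atom at every half-spacing sub-lattice node."""
    sub = grid.spacing / 2.0
    sub_dims = tuple(2 * (d - 1) + 1 for d in grid.dims)
    axes = [np.asarray(grid.origin)[d] + sub * np.arange(sub_dims[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d, _ = cKDTree(atoms).query(nodes, workers=-1)
    return d.reshape(sub_dims), sub


def buriedness_map(
    grid: Grid,
    structure: Structure,
    params: DetectorParams,
    coords: np.ndarray | None = None,
) -> BuriednessMap:
    """Ray-hit counts for all lattice points outside the protein.

    A candidate point is farther than ``exclusion_radius`` from every heavy
    atom.  Each of the ``n_rays`` fixed directions is sampled every half
    spacing out to ``ray_length``; the direction scores a hit when any sample
    lies within ``hit_radius`` of a heavy atom.  Samples leaving the grid box
    count as misses (no atoms live outside the box by construction).
    """
    atoms = _heavy_coords(structure, coords)
    dist_sub, sub = _sublattice_distances(grid, atoms)
    sub_dims = np.array(dist_sub.shape)

    # candidates sit on even sub-lattice nodes, where the distance is exact
    cand_mask = dist_sub[::2, ::2, ::2] > params.exclusion_radius
    cand_ijk = np.argwhere(cand_mask)
    if len(cand_ijk) == 0:
        return BuriednessMap(grid, cand_ijk, np.zeros(0, dtype=int))
    cand_pos = grid.point_coords(cand_ijk)

    # skip candidates no ray could ever reach from
    d_cand = dist_sub[::2, ::2, ::2][tuple(cand_ijk.T)]
    reachable = d_cand <= params.ray_length + params.hit_radius
    counts = np.zeros(len(cand_ijk), dtype=int)

    steps = np.arange(sub, params.ray_length + sub / 2.0, sub)
    origin = np.asarray(grid.origin)
    pos = cand_pos[reachable]
    hit_counts = np.zeros(len(pos), dtype=int)
    for direction in ray_directions(params.n_rays):
        samples = pos[:, None, :] + steps[:, None] * direction  # (nc, ns, 3)
        idx = np.rint((samples - origin) / sub).astype(int)
        inside = np.all((idx >= 0) & (idx < sub_dims), axis=-1)
        idx_clipped = np.clip(idx, 0, sub_dims - 1)
        d = dist_sub[idx_clipped[..., 0], idx_clipped[..., 1], idx_clipped[..., 2]]
        hit = inside & (d <= params.hit_radius)
        hit_counts += hit.any(axis=1)
    counts[reachable] = hit_counts
    return BuriednessMap(grid, cand_ijk, counts)


def detect_pockets(
    structure: Structure,
    params: DetectorParams | None = None,
    coords: np.ndarray | None = None,
    snapshot_label: str = "0",
    contact_cutoff: float = 4.5,
) -> list[Pocket]:
    """Detect pockets: buried candidate points grouped into 26-connected components.

    Components whose volume (point count x spacing³) reaches ``min_volume``
    are returned, numbered by volume ascending (centroid lexicographic order
    breaks ties), each annotated with its flanking residues.
    """
    if params is None:
        params = DetectorParams()
    grid = build_grid(structure, params.grid_margin, params.spacing, coords)
    bmap = buriedness_map(grid, structure, params, coords)
    buried = bmap.candidate_ijk[bmap.counts >= params.buriedness_min]

    occupancy = np.zeros(grid.dims, dtype=bool)
    if len(buried):
        occupancy[tuple(buried.T)] = True
    labeled, n_comp = ndimage.label(occupancy, structure=np.ones((3, 3, 3), dtype=int))

    raw: list[tuple[float, tuple[float, float, float], np.ndarray]] = []
    for comp in range(1, n_comp + 1):
        pts = np.argwhere(labeled == comp)
        volume = len(pts) * params.spacing**3
        if volume >= params.min_volume:
            centroid = grid.point_coords(pts).mean(axis=0)
            raw.append((volume, tuple(centroid), pts))
    raw.sort(key=lambda r: (r[0], r[1]))

    pockets = []
    for pid, (volume, centroid, pts) in enumerate(raw, start=1):
        p = Pocket(pid, snapshot_label, pts, volume, np.asarray(centroid), [], grid)
        p.flanking = flanking_residues(p, structure, contact_cutoff, coords)
        pockets.append(p)
    return pockets


def flanking_residues(
    pocket: Pocket,
    structure: Structure,
    contact_cutoff: float = 4.5,
    coords: np.ndarray | None = None,
) -> list[int]:
    """Residues with a heavy atom within ``contact_cutoff`` of any pocket point."""
    if contact_cutoff <= 0:
        return []
    xyz = structure.positions if coords is None else np.asarray(coords, dtype=float)
    heavy = np.flatnonzero(structure.heavy_mask())
    tree = cKDTree(pocket.grid.point_coords(pocket.points))
    d, _ = tree.query(xyz[heavy], workers=-1)
    resnums = structure.residue_numbers()[heavy]
    return sorted(set(resnums[d <= contact_cutoff].tolist()))


# --- exports ---------------------------------------------------------------


def pockets_to_csv(pockets: list[Pocket], path: str | Path, params: DetectorParams) -> None:
    rows = [
        {
            "snapshot_label": p.snapshot_label,
            "pocket_id": p.id,
            "volume_A3": p.volume,
            "centroid_x": p.centroid[0],
            "centroid_y": p.centroid[1],
            "centroid_z": p.centroid[2],
            "flanking_residues": ";".join(map(str, p.flanking)),
        }
        for p in pockets
    ]
    buf = io.StringIO()
    buf.write(f"# pocket table; {params}\n")
    pd.DataFrame(rows).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def pocket_points_to_pdb(pocket: Pocket, path: str | Path) -> None:
    """Write pocket lattice points as pseudo-atoms for sphere rendering."""
    from .pdbio import Structure, write_structure

    coords = pocket.grid.point_coords(pocket.points)
    atoms = [
        AtomRecord(
            serial=i + 1, name="PKT", residue_name="PKT", residue_number=max(pocket.id, 1),
            chain="Z", element="X", position=tuple(c), hetero=True,
        )
        for i, c in enumerate(coords)
    ]
    write_structure(Structure(atoms), path)
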