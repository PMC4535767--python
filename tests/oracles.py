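"""Independent reference implementations used to check the package's results.

Each oracle deliberately takes a different computational route from the code
it verifies: the superposition RMSD comes from the quaternion
characteristic-polynomial method instead of SVD; dihedrals from an explicit
plane-normal construction; void volumes from Monte-Carlo integration inside
the largest fully-blocked shell instead of lattice component analysis.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD via the largest eigenvalue of the 4x4 key matrix."""
    x = np.asarray(mobile, float)
    y = np.asarray(reference, float)
    n = len(x)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    r = xc.T @ yc
    key = np.array(
        [
            [r[0, 0] + r[1, 1] + r[2, 2], r[1, 2] - r[2, 1], r[2, 0] - r[0, 2], r[0, 1] - r[1, 0]],
            [r[1, 2] - r[2, 1], r[0, 0] - r[1, 1] - r[2, 2], r[0, 1] + r[1, 0], r[0, 2] + r[2, 0]],
            [r[2, 0] - r[0, 2], r[0, 1] + r[1, 0], -r[0, 0] + r[1, 1] - r[2, 2], r[1, 2] + r[2, 1]],
            [r[0, 1] - r[1, 0], r[0, 2] + r[2, 0], r[1, 2] + r[2, 1], -r[0, 0] - r[1, 1] + r[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    msd = max(((xc**2).sum() + (yc**2).sum() - 2.0 * lam), 0.0) / n
    return float(np.sqrt(msd))


def four_point_dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle (degrees) from explicit plane normals with a sign test."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def mc_void_volume(
    atoms: np.ndarray,
    center: np.ndarray,
    clearance: float = 2.5,
    r_max: float = 9.0,
    n_samples: int = 200_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo volume of the enclosed void around ``center``.

    The enclosing radius is found by scanning spherical shells outward for
    the first shell whose directions are all blocked (every sample within
    ``clearance`` of an atom); the void is then the fraction of uniform
    samples in that ball lying farther than ``clearance`` from every atom.
    Returns 0.0 if the centre region is not enclosed within ``r_max``.
    """
    rng = np.random.default_rng(seed)
    tree = cKDTree(np.asarray(atoms, float))
    center = np.asarray(center, float)

    r_blocked = None
    for r in np.arange(1.0, r_max + 1e-9, 0.25):
        v = rng.normal(size=(600, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        d, _ = tree.query(center + r * v)
        if np.all(d <= clearance):
            r_blocked = r
            break
    if r_blocked is None:
        return 0.0

    pts = rng.uniform(-r_blocked, r_blocked, size=(n_samples, 3))
    pts = pts[np.linalg.norm(pts, axis=1) <= r_blocked] + center
    d, _ = tree.query(pts, workers=-1)
    frac = float((d > clearance).mean())
    return frac * (4.0 / 3.0) * np.pi * r_blocked**3


def brute_force_overlap_edges(
    mapped: list, min_overlap: float
) -> set[frozenset]:
    """All-pairs overlap edge set by plain set arithmetic (no graph library)."""
    edges: set[frozenset] = set()
    for i in range(len(mapped)):
        for j in range(i + 1, len(mapped)):
            a, b = mapped[i], mapped[j]
            if a.vertex.snapshot_label == b.vertex.snapshot_label:
                continue
            inter = len(a.points & b.points)
            if inter / max(len(a.points), len(b.points)) >= min_overlap:
                edges.add(frozenset({a.vertex.key, b.vertex.key}))
    return edges
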