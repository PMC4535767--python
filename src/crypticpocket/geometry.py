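"""Rigid-body superposition and torsion geometry.

The Kabsch solver here is the single superposition primitive used by every
downstream stage (pairwise trajectory RMSD, pocket mapping onto the reference
lattice, ligand pose RMSD).  Rotations are proper (det = +1); reflections are
never returned, so enantiomeric point sets superpose with a residual instead
of silently inverting chirality.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

__all__ = ["kabsch", "trimmed_kabsch", "apply_transform", "rmsd", "dihedral_angle", "nerf_place"]

_DEGENERACY_TOL = 1e-9


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference:
        ``(n, 3)`` coordinate arrays with matched point correspondence,
        ``n >= 3`` and not all collinear.

    Returns
    -------
    rotation : (3, 3) ndarray
        Proper rotation matrix ``R`` (``det R = +1``).
    translation : (3,) ndarray
        Translation ``t`` such that ``mobile @ R.T + t`` best fits
        ``reference`` in the least-squares sense.
    rmsd : float
        Root-mean-square deviation at the optimum, in the input units.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise InputError(
            f"point count mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InputError(f"expected (n, 3) coordinates, got {mobile.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise InputError(f"superposition needs >= 3 points, got {n}")

    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)

    # collinear (rank < 2) point sets leave the rotation under-determined
    for label, pts in (("mobile", mob_c), ("reference", ref_c)):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] <= _DEGENERACY_TOL * max(sv[0], 1.0):
            raise InputError(f"{label} points are degenerate (collinear or coincident)")

    cov = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T

    translation = reference.mean(axis=0) - mobile.mean(axis=0) @ rotation.T
    # evaluate the residual explicitly: the singular-value identity loses
    # precision to cancellation exactly where it matters (rmsd near zero)
    resid = mob_c @ rotation.T - ref_c
    return rotation, translation, float(np.sqrt((resid**2).sum() / n))


def trimmed_kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    window: int = 12,
    stride: int = 4,
    inlier_tol: float = 2.0,
    n_refine: int = 3,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Robust core superposition seeded from contiguous sequence windows.

    When a structure combines a rigid core with large local rearrangements
    (a swinging loop, an unfolding helix), a global least-squares fit splits
    the difference and matches nothing.  Here every contiguous window of
    ``window`` points seeds a candidate fit; each candidate is refined on
    its inliers (points within ``inlier_tol`` after superposition) and the
    fit with the most inliers wins — a deterministic consensus search that
    locks onto the invariant core.  Returns (rotation, translation, rmsd
    over the winning inlier set).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    n = len(mobile)
    if n < 3:
        raise InputError(f"superposition needs >= 3 points, got {n}")
    window = min(window, n)
    starts = list(range(0, max(n - window, 0) + 1, stride))
    best: tuple[int, float, np.ndarray, np.ndarray] | None = None
    for s in starts:
        sel = slice(s, s + window)
        try:
            rot, trans, _ = kabsch(mobile[sel], reference[sel])
        except InputError:
            continue  # degenerate window
        for _ in range(n_refine):
            resid = np.linalg.norm(mobile @ rot.T + trans - reference, axis=1)
            inliers = np.flatnonzero(resid < inlier_tol)
            if len(inliers) < 3:
                break
            rot, trans, r = kabsch(mobile[inliers], reference[inliers])
        resid = np.linalg.norm(mobile @ rot.T + trans - reference, axis=1)
        inliers = np.flatnonzero(resid < inlier_tol)
        if len(inliers) < 3:
            continue
        _, _, r = kabsch(mobile[inliers], reference[inliers])
        score = (len(inliers), -r)
        if best is None or score > (best[0], -best[1]):
            best = (len(inliers), r, rot, trans)
    if best is None:
        # no consensus core: fall back to the global fit
        return kabsch(mobile, reference)
    return best[2], best[3], best[1]


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply ``x -> R x + t`` to an ``(n, 3)`` coordinate array."""
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (un-superposed) RMSD between matched coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum(axis=-1).mean()))


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign, in (-180, +180].

    Accepts single points or stacked ``(..., 3)`` arrays and is fully
    vectorized over leading dimensions.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    # components orthogonal to the central bond
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # arctan2 yields [-180, 180]; fold the -180 branch onto +180
    return np.where(ang <= -180.0, ang + 360.0, ang)


def nerf_place(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms A, B, C.

    D is at distance ``bond`` from C, with angle B-C-D ``angle_deg`` and
    torsion A-B-C-D ``torsion_deg`` (natural-extension reference frame
    construction, the standard way of growing a polymer chain from ideal
    internal coordinates).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local
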