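"""Two-way conformational decomposition of an ensemble.

A trajectory is decomposed into discrete conformations in two independent
ways — average-linkage agglomerative clustering of the pairwise superposed
Cα-RMSD matrix, and a dihedral-state segmentation that discretizes every
backbone torsion into angular states and places transitions where the
per-frame state string changes — and the agreement of the two transition
sets is quantified.  Cluster ids are renumbered by first temporal
appearance, so an essentially irreversible multi-state trajectory reads as
the monotone sequence 1, 2, 3, ...
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ConsistencyError, InputError, ParameterError, SelectionError
from .geometry import kabsch
from .pdbio import DihedralSeries, Trajectory

__all__ = [
    "RMSDMatrix",
    "ClusterAssignment",
    "OccupancyTimeline",
    "Segmentation",
    "ConcordanceReport",
    "DashParams",
    "superpose_kabsch",
    "pairwise_rmsd",
    "cluster_frames",
    "occupancy_timeline",
    "dash_segment",
    "transition_concordance",
]

# re-export under the operation name the rest of the package uses
superpose_kabsch = kabsch


@dataclass
class RMSDMatrix:
    """Symmetric matrix of pairwise superposed RMSDs over a fixed selection."""

    values: np.ndarray  # (n, n), Å
    selection: np.ndarray  # atom indices used

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InputError(f"RMSD matrix must be square, got {v.shape}")

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])


@dataclass
class ClusterAssignment:
    """Per-frame cluster labels (1..K by first appearance) with medoids."""

    labels: np.ndarray  # (n,) int, 1-based
    medoids: dict[int, int]  # cluster id -> representative frame index
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)

    def transition_frames(self) -> np.ndarray:
        """Frame indices where the cluster label changes (index of the new epoch's first frame)."""
        return np.flatnonzero(np.diff(self.labels) != 0) + 1

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"frame": np.arange(len(self.labels)), "cluster": self.labels})
        _write_csv_with_header(df, path, f"cluster assignment; cutoff={self.cutoff} A; medoids={self.medoids}")


@dataclass
class OccupancyTimeline:
    """Per-window cluster population fractions (fractions sum to 1 per window)."""

    window_length: int
    table: pd.DataFrame  # columns: window, cluster, fraction

    def to_csv(self, path: str | Path) -> None:
        _write_csv_with_header(self.table, path, f"occupancy timeline; window_length={self.window_length} frames")


@dataclass
class Segmentation:
    """Dihedral-state segmentation: transition frames and per-epoch labels.

    ``boundaries[i]`` is the first frame of epoch ``i + 1``; recurrent epochs
    (the trajectory revisiting an earlier conformation) share a label.
    """

    boundaries: np.ndarray  # strictly increasing frame indices
    epoch_labels: np.ndarray  # (n_epochs,) int, 1-based; recurrences share ids
    n_frames: int

    def epoch_ranges(self) -> list[tuple[int, int]]:
        edges = [0, *self.boundaries.tolist(), self.n_frames]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    def frame_labels(self) -> np.ndarray:
        out = np.empty(self.n_frames, dtype=int)
        for (lo, hi), lab in zip(self.epoch_ranges(), self.epoch_labels):
            out[lo:hi] = lab
        return out

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"frame": np.arange(self.n_frames), "conformation": self.frame_labels()})
        _write_csv_with_header(df, path, f"dihedral-state segmentation; boundaries={self.boundaries.tolist()}")


@dataclass
class ConcordanceReport:
    """Matching between cluster transitions and segmentation boundaries."""

    matched_pairs: list[tuple[int, int]]
    tolerance: int
    precision: float
    recall: float

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matched_pairs, columns=["cluster_transition", "segment_boundary"])
        _write_csv_with_header(
            df, path,
            f"transition concordance; tolerance={self.tolerance} frames; "
            f"precision={self.precision:.4f}; recall={self.recall:.4f}",
        )


def _write_csv_with_header(df: pd.DataFrame, path: str | Path, comment: str) -> None:
    buf = io.StringIO()
    buf.write(f"# {comment}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


# --- pairwise RMSD ----------------------------------------------------------


def pairwise_rmsd(trajectory: Trajectory, selection: np.ndarray) -> RMSDMatrix:
    """All-pairs superposed RMSD over ``selection``, computed once per pair.

    Uses the closed-form singular-value identity of the optimal-superposition
    RMSD, evaluated with batched 3x3 SVDs, so the full matrix for ~1000
    frames remains cheap.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise SelectionError("empty selection for pairwise RMSD")
    X = trajectory.frames[:, selection, :].astype(float)
    n, m, _ = X.shape
    X = X - X.mean(axis=1, keepdims=True)
    ssd = (X**2).sum(axis=(1, 2))

    out = np.zeros((n, n))
    for i in range(n - 1):
        rest = X[i + 1 :]
        cov = np.einsum("mk,jml->jkl", X[i], rest)
        u, s, vt = np.linalg.svd(cov)
        sign = np.sign(np.linalg.det(np.einsum("jab,jbc->jac", u, vt)))
        trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
        msd = np.maximum(ssd[i] + ssd[i + 1 :] - 2.0 * trace, 0.0) / m
        out[i, i + 1 :] = np.sqrt(msd)
    out += out.T
    return RMSDMatrix(out, selection)


# --- clustering -------------------------------------------------------------


def cluster_frames(matrix: RMSDMatrix, cutoff: float) -> ClusterAssignment:
    """Average-linkage agglomerative clustering cut at ``cutoff`` Å.

    Labels are renumbered by first temporal appearance; each cluster's
    representative is its medoid (minimal summed RMSD to the other members,
    earliest frame on ties).
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    v = matrix.values
    n = matrix.n_frames
    if n == 1:
        return ClusterAssignment(np.array([1]), {1: 0}, cutoff)
    raw = fcluster(linkage(squareform(v, checks=False), method="average"), t=cutoff, criterion="distance")
    # renumber by first appearance
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for t, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[t] = remap[r]
    medoids: dict[int, int] = {}
    for c in range(1, labels.max() + 1):
        members = np.flatnonzero(labels == c)
        sums = v[np.ix_(members, members)].sum(axis=1)
        medoids[c] = int(members[int(np.argmin(sums))])
    return ClusterAssignment(labels, medoids, cutoff)


def occupancy_timeline(assignment: ClusterAssignment, window_length: int) -> OccupancyTimeline:
    """Fraction of frames each cluster occupies per fixed-length window.

    The final partial window, if any, is normalized by its own size.
    """
    if window_length < 1:
        raise ParameterError("window_length must be >= 1")
    labels = assignment.labels
    rows = []
    for w, start in enumerate(range(0, len(labels), window_length)):
        chunk = labels[start : start + window_length]
        ids, counts = np.unique(chunk, return_counts=True)
        for c, cnt in zip(ids, counts):
            rows.append({"window": w, "cluster": int(c), "fraction": cnt / len(chunk)})
    return OccupancyTimeline(window_length, pd.DataFrame(rows))


# --- dihedral-state segmentation --------------------------------------------


@dataclass(frozen=True)
class DashParams:
    """Parameters of the dihedral-state segmentation.

    ``bin_width`` (deg) sets the circular histogram resolution; peaks closer
    than ``peak_merge`` deg are merged.  State strings are majority-filtered
    over ``smooth_window`` frames before the consecutive-frame similarity is
    compared against ``transition_threshold``; epochs whose consensus strings
    agree at ``recurrence_threshold`` or better share a conformation id.
    """

    bin_width: float = 10.0
    peak_merge: float = 30.0
    smooth_window: int = 11
    transition_threshold: float = 0.8
    recurrence_threshold: float = 0.9
    smooth_sigma: float = 25.0  # deg; circular histogram smoothing scale
    peak_floor: float = 0.05  # min peak height, fraction of the tallest peak


def _circular_histogram_states(angles: np.ndarray, params: DashParams) -> np.ndarray:
    """Assign each angle sample of one dihedral to a histogram-peak state.

    ``angles``: (n_frames,) degrees.  Returns integer state symbols.
    """
    nbins = int(round(360.0 / params.bin_width))
    shifted = np.mod(angles + 180.0, 360.0)
    hist, _ = np.histogram(shifted, bins=nbins, range=(0.0, 360.0))
    # circular Gaussian smoothing at roughly the thermal-jitter scale keeps
    # one peak per underlying angular state instead of one per noise wiggle
    sigma_bins = params.smooth_sigma / params.bin_width
    offs = np.arange(nbins)
    offs = np.minimum(offs, nbins - offs)
    kernel = np.exp(-0.5 * (offs / sigma_bins) ** 2)
    smooth = np.real(np.fft.ifft(np.fft.fft(hist) * np.fft.fft(kernel / kernel.sum())))

    left = np.roll(smooth, 1)
    right = np.roll(smooth, -1)
    floor = params.peak_floor * smooth.max()
    is_peak = (smooth >= left) & (smooth >= right) & (smooth >= floor)
    candidates = np.flatnonzero(is_peak)
    if candidates.size == 0:
        candidates = np.array([int(np.argmax(hist))])
    order = candidates[np.argsort(-smooth[candidates], kind="stable")]
    centers: list[float] = []
    merge_bins = params.peak_merge / params.bin_width
    for b in order:
        c = (b + 0.5) * params.bin_width
        if all(_circ_dist_deg(c, e) >= merge_bins * params.bin_width for e in centers):
            centers.append(c)
    centers_arr = np.asarray(centers)
    d = np.abs(shifted[:, None] - centers_arr[None, :])
    d = np.minimum(d, 360.0 - d)
    return np.argmin(d, axis=1)


def _circ_dist_deg(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _circular_moving_average(angles: np.ndarray, window: int) -> np.ndarray:
    """Sliding circular mean (degrees) of an (n_frames, n_dih) angle array.

    Averaging on the unit circle shrinks the per-frame angular jitter by
    roughly sqrt(window) without wrap-around artefacts, which is what makes
    the subsequent discretization robust to heavy thermal noise.
    """
    if window <= 1:
        return angles
    from scipy.ndimage import uniform_filter1d

    r = np.radians(angles)
    s = uniform_filter1d(np.sin(r), window, axis=0, mode="nearest")
    c = uniform_filter1d(np.cos(r), window, axis=0, mode="nearest")
    return np.degrees(np.arctan2(s, c))


def dash_segment(series: list[DihedralSeries], params: DashParams | None = None) -> Segmentation:
    """Segment a trajectory into sequential conformations from its dihedrals.

    Every defined backbone torsion is circularly averaged over
    ``smooth_window`` frames and discretized into angular states by
    circular-histogram peak assignment; a transition is placed wherever the
    similarity (fraction of matching symbols) between state strings one
    window apart falls below ``transition_threshold``, one boundary per
    below-threshold run.  Epochs whose consensus strings agree at
    ``recurrence_threshold`` or better are assigned the same conformation
    id, so a revisited conformation is recognized as a recurrence.
    """
    if params is None:
        params = DashParams()
    if len(series) < 2:
        raise InputError("segmentation needs at least 2 frames")
    angles = np.stack([s.angles for s in series])  # (n_frames, n_res, 2)
    n_frames = angles.shape[0]
    flat = angles.reshape(n_frames, -1)
    defined = ~np.isnan(flat).any(axis=0)
    if not defined.any():
        raise InputError("all dihedrals are undefined")
    flat = flat[:, defined]

    smoothed = _circular_moving_average(flat, params.smooth_window)
    filtered = np.column_stack(
        [_circular_histogram_states(smoothed[:, j], params) for j in range(smoothed.shape[1])]
    )

    # compare state strings one smoothing window apart: a transition smeared
    # across the averaging window still produces a full-depth dip, while
    # within-state flicker does not accumulate
    half = params.smooth_window // 2
    lag = max(1, min(2 * half, n_frames - 1))
    sim = (filtered[:-lag] == filtered[lag:]).mean(axis=1)  # centred at i + lag/2
    below = sim < params.transition_threshold
    boundaries: list[int] = []
    t = 0
    while t < len(below):
        if below[t]:
            run_end = t
            while run_end + 1 < len(below) and below[run_end + 1]:
                run_end += 1
            run = sim[t : run_end + 1]
            minima = np.flatnonzero(run == run.min())
            centre = t + int(minima[len(minima) // 2])
            boundary = centre + (lag + 1) // 2  # map similarity index to frame
            if 0 < boundary < n_frames:
                boundaries.append(boundary)
            t = run_end + 1
        else:
            t += 1

    edges = [0, *boundaries, n_frames]
    consensus: list[np.ndarray] = []
    labels: list[int] = []
    for e in range(len(edges) - 1):
        chunk = filtered[edges[e] : edges[e + 1]]
        cons = np.array([np.bincount(col).argmax() for col in chunk.T])
        assigned = 0
        for prev_label, prev_cons in zip(labels, consensus):
            if (cons == prev_cons).mean() >= params.recurrence_threshold:
                assigned = prev_label
                break
        if assigned == 0:
            assigned = (max(labels) if labels else 0) + 1
        labels.append(assigned)
        consensus.append(cons)
    return Segmentation(np.asarray(boundaries, dtype=int), np.asarray(labels, dtype=int), n_frames)


# --- concordance ------------------------------------------------------------


def transition_concordance(
    assignment: ClusterAssignment, segmentation: Segmentation, tolerance: int
) -> ConcordanceReport:
    """Greedy temporal matching of cluster transitions to segmentation boundaries.

    Cluster transitions are processed in temporal order; each is matched to
    the nearest unmatched segmentation boundary within ``tolerance`` frames.
    Recall is the matched fraction of cluster transitions, precision the
    matched fraction of segmentation boundaries (both 1.0 when the two sets
    are empty).
    """
    if len(assignment.labels) != segmentation.n_frames:
        raise ConsistencyError(
            f"cluster labels cover {len(assignment.labels)} frames, "
            f"segmentation covers {segmentation.n_frames}"
        )
    cluster_t = assignment.transition_frames()
    seg_t = segmentation.boundaries
    unmatched = list(seg_t.tolist())
    pairs: list[tuple[int, int]] = []
    for ct in cluster_t:
        if not unmatched:
            break
        dists = [abs(ct - s) for s in unmatched]
        best = int(np.argmin(dists))
        if dists[best] <= tolerance:
            pairs.append((int(ct), unmatched.pop(best)))
    n_c, n_s = len(cluster_t), len(seg_t)
    precision = len(pairs) / n_s if n_s else (1.0 if n_c == 0 else 0.0)
    recall = len(pairs) / n_c if n_c else (1.0 if n_s == 0 else 0.0)
    return ConcordanceReport(pairs, tolerance, precision, recall)
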