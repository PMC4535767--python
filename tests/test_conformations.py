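"""Clustering, dihedral-state segmentation and their transition concordance."""

import numpy as np
import pytest

from crypticpocket.conformations import (
    DashParams,
    cluster_frames,
    dash_segment,
    occupancy_timeline,
    pairwise_rmsd,
    transition_concordance,
)
from crypticpocket.errors import ConsistencyError, InputError, ParameterError, SelectionError
from crypticpocket.geometry import kabsch
from crypticpocket.pdbio import (
    AtomRecord,
    DihedralSeries,
    Structure,
    Trajectory,
    backbone_dihedrals,
    select_atoms,
)
from crypticpocket.synthetic import StateSchedule, generate_trajectory, make_state_library


def _tiny_structure(n_atoms=6):
    atoms = [
        AtomRecord(i + 1, "CA", "GLY", i + 1, "A", "C", (float(i) * 3.8, 0.0, 0.0))
        for i in range(n_atoms)
    ]
    return Structure(atoms)


def _synthetic_series(angle_matrix):
    """DihedralSeries list from an (n_frames, n_dih) matrix (ψ column padded)."""
    n_frames, n_dih = angle_matrix.shape
    out = []
    for f in range(n_frames):
        angles = np.column_stack([angle_matrix[f], angle_matrix[f]])
        out.append(
            DihedralSeries(
                f, angles, np.arange(1, n_dih + 1), np.ones((n_dih, 2), dtype=bool)
            )
        )
    return out


class TestPairwiseRMSD:
    def test_identical_frames_give_zero_matrix(self):
        s = _tiny_structure()
        frames = np.tile(s.positions, (4, 1, 1))
        m = pairwise_rmsd(Trajectory(s, frames, 1.0), np.arange(6))
        assert np.allclose(m.values, 0.0, atol=1e-9)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(0)
        s = _tiny_structure()
        q = rng.normal(size=4); q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        frames = np.stack([s.positions, s.positions @ rot.T + np.array([1.0, 2.0, 3.0])])
        m = pairwise_rmsd(Trajectory(s, frames, 1.0), np.arange(6))
        assert m.values[0, 1] < 1e-9

    def test_matches_per_pair_kabsch(self):
        rng = np.random.default_rng(1)
        s = _tiny_structure(8)
        frames = s.positions + rng.normal(scale=1.5, size=(3, 8, 3))
        sel = np.arange(8)
        m = pairwise_rmsd(Trajectory(s, frames, 1.0), sel)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                _, _, r = kabsch(frames[i][sel], frames[j][sel])
                assert m.values[i, j] == pytest.approx(r, abs=1e-10)
        assert np.allclose(m.values, m.values.T)

    def test_empty_selection_rejected(self):
        s = _tiny_structure()
        traj = Trajectory(s, s.positions[None], 1.0)
        with pytest.raises(SelectionError):
            pairwise_rmsd(traj, np.array([], dtype=int))


class TestClustering:
    def test_zero_matrix_single_cluster(self):
        s = _tiny_structure()
        frames = np.tile(s.positions, (5, 1, 1))
        m = pairwise_rmsd(Trajectory(s, frames, 1.0), np.arange(6))
        asg = cluster_frames(m, cutoff=1.0)
        assert asg.n_clusters == 1
        assert set(asg.labels) == {1}

    def test_two_planted_states_recovered(self, toy_protein):
        lib = make_state_library(toy_protein, 2, 4.0, seed=3, min_separation=5.0)
        sched = StateSchedule((("S1", 0, 100), ("S2", 100, 200)))
        traj, truth = generate_trajectory(lib, sched, noise_sd=0.4, seed=4)
        ca = select_atoms(toy_protein, "name CA")
        asg = cluster_frames(pairwise_rmsd(traj, ca), cutoff=2.5)
        assert asg.n_clusters == 2
        # adjusted Rand index of 1.0 == exact agreement up to relabelling
        assert all(asg.labels[:100] == asg.labels[0])
        assert all(asg.labels[100:] == asg.labels[100])
        assert asg.labels[0] != asg.labels[100]
        # temporal renumbering: first state is cluster 1
        assert asg.labels[0] == 1

    def test_tiny_cutoff_fragments_into_singletons(self):
        rng = np.random.default_rng(5)
        s = _tiny_structure(8)
        frames = s.positions + rng.normal(scale=2.0, size=(6, 8, 3))
        m = pairwise_rmsd(Trajectory(s, frames, 1.0), np.arange(8))
        asg = cluster_frames(m, cutoff=min(m.values[m.values > 0]) / 2)
        assert asg.n_clusters == 6

    def test_medoid_minimizes_summed_rmsd(self, toy_protein):
        lib = make_state_library(toy_protein, 2, 4.0, seed=3, min_separation=5.0)
        sched = StateSchedule((("S1", 0, 40), ("S2", 40, 80)))
        traj, _ = generate_trajectory(lib, sched, noise_sd=0.4, seed=4)
        ca = select_atoms(toy_protein, "name CA")
        m = pairwise_rmsd(traj, ca)
        asg = cluster_frames(m, cutoff=2.5)
        for c, medoid in asg.medoids.items():
            members = np.flatnonzero(asg.labels == c)
            sums = m.values[np.ix_(members, members)].sum(axis=1)
            assert m.values[medoid, members].sum() == pytest.approx(sums.min())


class TestOccupancy:
    def _assignment(self, labels):
        from crypticpocket.conformations import ClusterAssignment

        return ClusterAssignment(np.asarray(labels), {1: 0}, 1.0)

    def test_single_cluster_fractions_are_one(self):
        tl = occupancy_timeline(self._assignment([1] * 10), window_length=4)
        assert np.allclose(tl.table["fraction"], 1.0)

    def test_window_one_gives_indicators(self):
        tl = occupancy_timeline(self._assignment([1, 2, 1]), window_length=1)
        assert len(tl.table) == 3
        assert np.allclose(tl.table["fraction"], 1.0)

    def test_block_transition_counted_exactly(self):
        labels = [1] * 100 + [2] * 100
        tl = occupancy_timeline(self._assignment(labels), window_length=50)
        got = {(int(r.window), int(r.cluster)): r.fraction for r in tl.table.itertuples()}
        assert got == {(0, 1): 1.0, (1, 1): 1.0, (2, 2): 1.0, (3, 2): 1.0}

    def test_fractions_sum_to_one_per_window(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(1, 4, size=103)
        tl = occupancy_timeline(self._assignment(labels), window_length=10)
        sums = tl.table.groupby("window")["fraction"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_bad_window_rejected(self):
        with pytest.raises(ParameterError):
            occupancy_timeline(self._assignment([1]), window_length=0)


class TestDashSegment:
    def test_constant_series_one_epoch(self):
        series = _synthetic_series(np.full((50, 8), -60.0))
        seg = dash_segment(series)
        assert len(seg.boundaries) == 0
        assert list(seg.epoch_labels) == [1]

    def test_synchronized_jump_recovered_within_window(self):
        angles = np.full((400, 10), -60.0)
        angles[200:] += 120.0
        seg = dash_segment(_synthetic_series(angles))
        assert len(seg.boundaries) == 1
        assert abs(seg.boundaries[0] - 200) <= DashParams().smooth_window

    def test_recurrent_epochs_share_label(self):
        angles = np.full((400, 10), -60.0)
        angles[150:250] += 150.0  # A(150) -> B(100) -> A(150)
        seg = dash_segment(_synthetic_series(angles))
        assert len(seg.boundaries) == 2
        labels = list(seg.epoch_labels)
        assert labels[0] == labels[2]
        assert labels[0] != labels[1]

    def test_all_undefined_is_input_error(self):
        series = []
        for f in range(10):
            series.append(
                DihedralSeries(
                    f,
                    np.full((4, 2), np.nan),
                    np.arange(1, 5),
                    np.zeros((4, 2), dtype=bool),
                )
            )
        with pytest.raises(InputError):
            dash_segment(series)

    def test_noise_on_angles_does_not_create_boundaries(self):
        rng = np.random.default_rng(7)
        angles = np.full((300, 12), -60.0) + rng.normal(scale=25.0, size=(300, 12))
        seg = dash_segment(_synthetic_series(angles))
        assert len(seg.boundaries) == 0


class TestConcordance:
    def _assignment(self, labels):
        from crypticpocket.conformations import ClusterAssignment

        return ClusterAssignment(np.asarray(labels), {1: 0}, 1.0)

    def _segmentation(self, boundaries, n_frames):
        from crypticpocket.conformations import Segmentation

        return Segmentation(
            np.asarray(boundaries, dtype=int),
            np.arange(1, len(boundaries) + 2),
            n_frames,
        )

    def test_identical_transition_sets(self):
        labels = [1] * 50 + [2] * 50 + [3] * 50
        rep = transition_concordance(
            self._assignment(labels), self._segmentation([50, 100], 150), tolerance=5
        )
        assert rep.precision == 1.0 and rep.recall == 1.0
        assert rep.matched_pairs == [(50, 50), (100, 100)]

    def test_disjoint_sets_beyond_tolerance(self):
        labels = [1] * 50 + [2] * 100
        rep = transition_concordance(
            self._assignment(labels), self._segmentation([100], 150), tolerance=10
        )
        assert rep.precision == 0.0 and rep.recall == 0.0

    def test_each_boundary_matched_at_most_once(self):
        labels = [1] * 30 + [2] * 30 + [3] * 90
        rep = transition_concordance(
            self._assignment(labels), self._segmentation([32], 150), tolerance=30
        )
        assert len(rep.matched_pairs) == 1
        assert rep.matched_pairs[0] == (30, 32)

    def test_planted_three_transition_fixture_end_to_end(self, toy_protein):
        lib = make_state_library(toy_protein, 4, 4.0, seed=1, min_separation=4.0)
        sched = StateSchedule(
            (("S1", 0, 100), ("S2", 100, 220), ("S3", 220, 300), ("S4", 300, 400))
        )
        traj, _ = generate_trajectory(lib, sched, noise_sd=0.5, seed=2)
        ca = select_atoms(toy_protein, "name CA")
        asg = cluster_frames(pairwise_rmsd(traj, ca), cutoff=2.0)
        seg = dash_segment(backbone_dihedrals(traj))
        rep = transition_concordance(asg, seg, tolerance=10)
        assert rep.precision == 1.0 and rep.recall == 1.0
        assert len(rep.matched_pairs) == 3

    def test_mismatched_frame_ranges_rejected(self):
        with pytest.raises(ConsistencyError):
            transition_concordance(
                self._assignment([1] * 10), self._segmentation([5], 20), tolerance=2
            )
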