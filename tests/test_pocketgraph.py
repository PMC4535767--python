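"""Pocket overlap graph, candidate-site classification and persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crypticpocket.conformations import ClusterAssignment
from crypticpocket.errors import ConsistencyError, InputError
from crypticpocket.pocketgraph import (
    CRYSTAL_LABEL,
    MappedPocket,
    PocketVertex,
    build_pocket_graph,
    find_candidate_sites,
    map_to_reference,
    mutual_overlap,
    persistence,
)
from crypticpocket.pockets import Grid, Pocket

from .oracles import brute_force_overlap_edges


def _mp(label, pid, points, volume=None):
    pts = set(points)
    return MappedPocket(PocketVertex(label, pid, volume if volume is not None else float(len(pts))), pts)


def _block(x0, y0, z0, nx, ny, nz):
    return {(x0 + i, y0 + j, z0 + k) for i in range(nx) for j in range(ny) for k in range(nz)}


class TestMutualOverlap:
    def test_identity_is_one(self):
        a = _block(0, 0, 0, 4, 4, 4)
        assert mutual_overlap(a, set(a)) == 1.0

    def test_disjoint_is_zero(self):
        assert mutual_overlap(_block(0, 0, 0, 3, 3, 3), _block(10, 10, 10, 3, 3, 3)) == 0.0

    def test_constructed_030(self):
        a = {(i, 0, 0) for i in range(100)}
        b = {(i, 0, 0) for i in range(70, 130)}  # |B|=60, |A∩B|=30
        assert mutual_overlap(a, b) == pytest.approx(0.30)
        assert mutual_overlap(b, a) == pytest.approx(0.30)

    def test_nested_sets_ratio(self):
        a = _block(0, 0, 0, 2, 2, 2)
        b = _block(0, 0, 0, 4, 2, 2)
        assert mutual_overlap(a, b) == pytest.approx(len(a) / len(b))

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            mutual_overlap(set(), _block(0, 0, 0, 2, 2, 2))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=1000))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        pts = [tuple(p) for p in rng.integers(0, 6, size=(30, 3))]
        a = set(pts[: rng.integers(1, 29)])
        b = set(pts[rng.integers(1, 29) :])
        if not a or not b:
            return
        ab = mutual_overlap(a, b)
        assert ab == mutual_overlap(b, a)
        assert 0.0 <= ab <= 1.0
        assert (ab == 1.0) == (a == b)


class TestMapToReference:
    def _grid(self):
        return Grid((0.0, 0.0, 0.0), 1.0, (40, 40, 40))

    def _pocket(self, points, grid):
        pts = np.asarray(sorted(points))
        return Pocket(1, "1", pts, float(len(pts)), pts.mean(axis=0), [], grid)

    def test_identity_mapping(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(5, 30, size=(30, 3))
        grid = self._grid()
        pts = _block(10, 10, 10, 5, 5, 5)
        pocket = self._pocket(pts, grid)
        mapped = map_to_reference(pocket, coords, coords, np.arange(30), grid)
        assert mapped == pts

    def test_rigid_motion_inverted(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(5, 30, size=(30, 3))
        q = rng.normal(size=4); q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        shift = np.array([3.0, -1.0, 6.0])
        grid = self._grid()
        pts = _block(12, 14, 9, 5, 4, 6)
        # move both the structure and the pocket rigidly, then map back
        source = ref @ rot.T + shift
        src_pts = np.asarray(sorted(pts)) @ rot.T + shift
        src_grid = Grid((0.0, 0.0, 0.0), 1.0, (60, 60, 60))
        # pocket points on the source lattice: quantize the moved nodes
        src_ijk = {tuple(q_) for q_ in np.rint(src_pts).astype(int).tolist()}
        pocket = self._pocket(src_ijk, src_grid)
        mapped = map_to_reference(pocket, source, ref, np.arange(30), grid)
        # re-quantization may move individual nodes by one cell at most
        assert len(mapped ^ pts) / len(pts) < 0.5
        cen_m = np.mean(sorted(mapped), axis=0)
        cen_p = np.mean(sorted(pts), axis=0)
        assert np.linalg.norm(cen_m - cen_p) < 1.0

    def test_exact_lattice_translation_maps_exactly(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(5, 30, size=(30, 3))
        shift = np.array([4.0, 2.0, 7.0])  # whole lattice cells
        grid = self._grid()
        pts = _block(11, 12, 13, 4, 4, 4)
        source = ref + shift
        src_ijk = {(p[0] + 4, p[1] + 2, p[2] + 7) for p in pts}
        pocket = self._pocket(src_ijk, grid)
        mapped = map_to_reference(pocket, source, ref, np.arange(30), grid)
        assert mapped == pts

    def test_ca_mismatch_rejected(self):
        grid = self._grid()
        pocket = self._pocket(_block(0, 0, 0, 2, 2, 2), grid)
        with pytest.raises(ConsistencyError):
            map_to_reference(pocket, np.zeros((5, 3)), np.zeros((5, 3)), np.array([0, 1]), grid)


class TestBuildGraph:
    def test_singleton(self):
        g = build_pocket_graph({"1": [_mp("1", 1, _block(0, 0, 0, 5, 5, 5))]}, [])
        assert g.graph.number_of_nodes() == 1
        assert g.graph.number_of_edges() == 0

    def test_identical_pockets_three_snapshots_form_triangle(self):
        pts = _block(0, 0, 0, 5, 5, 5)
        by_snap = {str(k): [_mp(str(k), 1, pts)] for k in (1, 2, 3)}
        g = build_pocket_graph(by_snap, [])
        assert g.graph.number_of_edges() == 3
        import networkx as nx

        assert len(list(nx.connected_components(g.graph))) == 1

    def test_threshold_chain(self):
        a = {(i, 0, 0) for i in range(100)}
        b = {(i, 0, 0) for i in range(60, 160)}   # overlap 40/100
        c = {(i, 0, 0) for i in range(120, 220)}  # b∩c = 40, a∩c = 0... adjust
        # overlaps: a-b 0.4, b-c 0.4, a-c 0.0 < threshold
        by_snap = {"1": [_mp("1", 1, a, 120)], "2": [_mp("2", 1, b, 120)], "3": [_mp("3", 1, c, 120)]}
        g = build_pocket_graph(by_snap, [], min_volume=100, min_overlap=0.30)
        edges = {frozenset(e) for e in g.graph.edges}
        assert edges == {frozenset({"1.1", "2.1"}), frozenset({"2.1", "3.1"})}
        sites = find_candidate_sites(g)
        assert len(sites) == 1 and len(sites[0].vertices) == 3

    def test_min_volume_excludes_vertices(self):
        pts = _block(0, 0, 0, 3, 3, 3)  # 27 points
        g = build_pocket_graph({"1": [_mp("1", 1, pts, volume=27.0)]}, [], min_volume=100)
        assert g.graph.number_of_nodes() == 0

    def test_same_snapshot_pockets_never_connected(self):
        pts = _block(0, 0, 0, 5, 5, 5)
        g = build_pocket_graph({"1": [_mp("1", 1, pts), _mp("1", 2, pts)]}, [])
        assert g.graph.number_of_edges() == 0

    def test_edges_match_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(3)
        mapped = []
        by_snap = {}
        for snap in range(5):
            plist = []
            for pid in range(1, 3):
                x0, y0, z0 = rng.integers(0, 8, size=3)
                pts = _block(int(x0), int(y0), int(z0), 5, 5, 5)
                plist.append(_mp(str(snap), pid, pts, 125.0))
            by_snap[str(snap)] = plist
            mapped.extend(plist)
        g = build_pocket_graph(by_snap, [], min_volume=100, min_overlap=0.30)
        expected = brute_force_overlap_edges(mapped, 0.30)
        got = {frozenset(e) for e in g.graph.edges}
        assert got == expected

    def test_component_count_non_decreasing_in_threshold(self):
        import networkx as nx

        rng = np.random.default_rng(4)
        by_snap = {}
        for snap in range(4):
            x0, y0, z0 = rng.integers(0, 5, size=3)
            by_snap[str(snap)] = [_mp(str(snap), 1, _block(int(x0), int(y0), int(z0), 5, 5, 5), 125.0)]
        counts = []
        for theta in (0.1, 0.3, 0.5, 0.7, 0.9):
            g = build_pocket_graph(by_snap, [], min_volume=100, min_overlap=theta)
            counts.append(len(list(nx.connected_components(g.graph))))
        assert counts == sorted(counts)


class TestCandidateSites:
    def test_crystal_component_not_novel(self):
        pts = _block(0, 0, 0, 5, 5, 5)
        g = build_pocket_graph(
            {"1": [_mp("1", 1, pts)]}, [_mp(CRYSTAL_LABEL, 1, pts)]
        )
        sites = find_candidate_sites(g)
        assert len(sites) == 1
        assert not sites[0].novel

    def test_component_without_crystal_is_novel(self):
        pts = _block(0, 0, 0, 5, 5, 5)
        by_snap = {str(k): [_mp(str(k), 1, pts)] for k in (5, 6, 7)}
        sites = find_candidate_sites(build_pocket_graph(by_snap, []))
        assert len(sites) == 1
        assert sites[0].novel
        assert sites[0].snapshots == {"5", "6", "7"}

    def test_ranked_by_summed_volume(self):
        big = _block(0, 0, 0, 6, 6, 6)
        small = _block(20, 20, 20, 5, 5, 5)
        by_snap = {
            "1": [_mp("1", 1, small, 125.0), _mp("1", 2, big, 216.0)],
            "2": [_mp("2", 1, small, 125.0), _mp("2", 2, big, 216.0)],
        }
        sites = find_candidate_sites(build_pocket_graph(by_snap, []))
        assert sites[0].total_volume >= sites[-1].total_volume

    def test_full_pipeline_recovers_planted_site(self, analysis_bundle):
        novel = analysis_bundle.novel_sites
        assert len(novel) == 1
        assert novel[0].md_snapshots == {"2", "3"}


class TestPersistence:
    def _site(self, snapshots):
        return type(
            "S", (), {"md_snapshots": set(snapshots), "snapshots": set(snapshots)}
        )()

    def _assignment(self, labels):
        return ClusterAssignment(np.asarray(labels), {1: 0}, 1.0)

    def test_single_cluster_run(self):
        labels = [1] * 100 + [2] * 100 + [3] * 100
        ns, contiguous = persistence(self._site({"2"}), self._assignment(labels), 1.0)
        assert ns == 100.0
        assert contiguous

    def test_separated_runs_not_contiguous(self):
        labels = [1] * 50 + [2] * 50 + [1] * 50
        ns, contiguous = persistence(self._site({"1"}), self._assignment(labels), 1.0)
        assert ns == 100.0
        assert not contiguous

    def test_unknown_cluster_rejected(self):
        with pytest.raises(ConsistencyError):
            persistence(self._site({"9"}), self._assignment([1, 1, 2]), 1.0)

    def test_planted_open_duration_recovered(self, analysis_bundle):
        site = analysis_bundle.novel_sites[0]
        assert site.persistence_ns == pytest.approx(200.0, abs=10.0)
        assert site.contiguous
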