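"""Cross-snapshot pocket comparison: overlap graph and candidate sites.

Pockets detected on each cluster representative (and on the reference
crystal structure, labelled ``"c"``) are mapped onto the reference lattice
via Cα superposition, compared pairwise by mutual overlap of their lattice
point sets, and organized in an undirected graph whose edges require at
least the minimum overlap (30% by default).  Connected components are the
candidate sites; a component containing no crystal vertex is a site absent
from the reference structure — the transient-pocket signal this package
exists to find.  A site's persistence is the total simulated time its
member conformations are occupied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .conformations import ClusterAssignment
from .errors import ConsistencyError, InputError
from .geometry import apply_transform, trimmed_kabsch
from .pockets import Grid, Pocket

__all__ = [
    "PocketVertex",
    "PocketGraph",
    "CandidateSite",
    "MappedPocket",
    "map_to_reference",
    "mutual_overlap",
    "build_pocket_graph",
    "find_candidate_sites",
    "persistence",
    "graph_to_graphml",
    "graph_to_dot",
    "sites_to_json",
]

CRYSTAL_LABEL = "c"


@dataclass(frozen=True)
class PocketVertex:
    """(snapshot, pocket) identity with its volume; snapshot "c" is the reference."""

    snapshot_label: str
    pocket_id: int
    volume: float

    @property
    def key(self) -> str:
        return f"{self.snapshot_label}.{self.pocket_id}"


@dataclass
class MappedPocket:
    """A pocket expressed as lattice points on the reference grid."""

    vertex: PocketVertex
    points: set[tuple[int, int, int]]


@dataclass
class PocketGraph:
    """Undirected overlap graph over mapped pockets."""

    graph: nx.Graph
    min_volume: float
    min_overlap: float


@dataclass
class CandidateSite:
    """A maximal connected component of the pocket graph.

    ``novel`` is true iff no member vertex comes from the reference
    structure.  ``persistence_ns``/``contiguous`` are filled by
    :func:`persistence` once a cluster assignment is available.
    """

    vertices: list[PocketVertex]
    novel: bool
    total_volume: float
    persistence_ns: float | None = None
    contiguous: bool | None = None

    @property
    def snapshots(self) -> set[str]:
        return {v.snapshot_label for v in self.vertices}

    @property
    def md_snapshots(self) -> set[str]:
        return {s for s in self.snapshots if s != CRYSTAL_LABEL}


def map_to_reference(
    pocket: Pocket,
    source_coords: np.ndarray,
    reference_coords: np.ndarray,
    ca_indices: np.ndarray,
    reference_grid: Grid,
) -> set[tuple[int, int, int]]:
    """Transform a pocket's lattice points into the reference grid.

    The source frame is superposed onto the reference over the shared Cα
    selection with a consensus core fit — conformations that differ by a
    large local rearrangement still map their invariant region, and hence
    any pocket it hosts, consistently.  Pocket node centres are transformed
    and re-quantized to the nearest reference lattice cell.
    """
    ca_indices = np.asarray(ca_indices, dtype=int)
    if ca_indices.size < 3:
        raise ConsistencyError("need >= 3 shared Cα atoms for mapping")
    rot, trans, _ = trimmed_kabsch(source_coords[ca_indices], reference_coords[ca_indices])
    pts = apply_transform(pocket.grid.point_coords(pocket.points), rot, trans)
    quant = reference_grid.quantize(pts)
    return {tuple(q) for q in quant.tolist()}


def mutual_overlap(points_a: set, points_b: set) -> float:
    """Symmetric overlap |A ∩ B| / max(|A|, |B|) of two lattice point sets.

    Reaches a threshold θ exactly when both directed overlap fractions do,
    which is the natural reading of a "mutual" overlap requirement.
    """
    if not points_a or not points_b:
        raise InputError("mutual overlap of an empty point set is undefined")
    inter = len(points_a & points_b)
    return inter / max(len(points_a), len(points_b))


def build_pocket_graph(
    pockets_by_snapshot: dict[str, list[MappedPocket]],
    reference_pockets: list[MappedPocket],
    min_volume: float = 100.0,
    min_overlap: float = 0.30,
) -> PocketGraph:
    """Vertices for every pocket at/above ``min_volume``; edges for pairs from
    different snapshots whose mutual overlap reaches ``min_overlap``.

    Reference pockets join the graph under the label ``"c"``; two pockets of
    the same snapshot are never connected (they are disjoint components of
    one scan by construction).
    """
    all_pockets: list[MappedPocket] = []
    for label in sorted(pockets_by_snapshot):
        all_pockets.extend(pockets_by_snapshot[label])
    all_pockets.extend(reference_pockets)
    all_pockets = [p for p in all_pockets if p.vertex.volume >= min_volume]

    g = nx.Graph()
    for p in all_pockets:
        g.add_node(
            p.vertex.key,
            snapshot_label=p.vertex.snapshot_label,
            pocket_id=p.vertex.pocket_id,
            volume=p.vertex.volume,
        )
    for i in range(len(all_pockets)):
        for j in range(i + 1, len(all_pockets)):
            a, b = all_pockets[i], all_pockets[j]
            if a.vertex.snapshot_label == b.vertex.snapshot_label:
                continue
            ov = mutual_overlap(a.points, b.points)
            if ov >= min_overlap:
                g.add_edge(a.vertex.key, b.vertex.key, overlap=float(ov))
    return PocketGraph(g, min_volume, min_overlap)


def find_candidate_sites(graph: PocketGraph) -> list[CandidateSite]:
    """Connected components classified novel vs. crystal-present.

    Components are ranked by summed member volume descending (component size
    breaks ties); isolated vertices form their own single-member sites.
    """
    sites: list[CandidateSite] = []
    for comp in nx.connected_components(graph.graph):
        vertices = [
            PocketVertex(
                graph.graph.nodes[n]["snapshot_label"],
                graph.graph.nodes[n]["pocket_id"],
                graph.graph.nodes[n]["volume"],
            )
            for n in sorted(comp)
        ]
        novel = all(v.snapshot_label != CRYSTAL_LABEL for v in vertices)
        sites.append(CandidateSite(vertices, novel, sum(v.volume for v in vertices)))
    sites.sort(key=lambda s: (-s.total_volume, -len(s.vertices)))
    return sites


def persistence(
    site: CandidateSite, assignment: ClusterAssignment, frame_interval: float
) -> tuple[float, bool]:
    """Total occupied time of a site's member clusters and its contiguity.

    ``persistence_ns`` counts every frame assigned to any member cluster;
    ``contiguous`` is true iff those frames form one unbroken run.
    """
    known = {str(c) for c in np.unique(assignment.labels)}
    members = site.md_snapshots
    unknown = members - known
    if unknown:
        raise ConsistencyError(f"site references unknown clusters: {sorted(unknown)}")
    mask = np.isin(assignment.labels.astype(str), sorted(members))
    frames = np.flatnonzero(mask)
    if frames.size == 0:
        return 0.0, True
    contiguous = bool(frames[-1] - frames[0] + 1 == frames.size)
    return float(frames.size * frame_interval), contiguous


# --- exports ---------------------------------------------------------------


def graph_to_graphml(graph: PocketGraph, path: str | Path) -> None:
    nx.write_graphml(graph.graph, str(path))


def graph_to_dot(graph: PocketGraph, path: str | Path, show_isolated: bool = False) -> None:
    """DOT rendering; isolated vertices are hidden by default (a rendering
    choice only — they remain in the data model)."""
    lines = ["graph pockets {"]
    g = graph.graph
    for n, data in g.nodes(data=True):
        if not show_isolated and g.degree[n] == 0:
            continue
        lines.append(f'  "{n}" [label="{n}\\n{data["volume"]:.0f} A3"];')
    for u, v, data in g.edges(data=True):
        lines.append(f'  "{u}" -- "{v}" [label="{data["overlap"]:.2f}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def sites_to_json(sites: list[CandidateSite], path: str | Path) -> None:
    payload = [
        {
            "vertices": [
                {"snapshot": v.snapshot_label, "pocket_id": v.pocket_id, "volume": v.volume}
                for v in s.vertices
            ],
            "novel": s.novel,
            "total_volume": s.total_volume,
            "persistence_ns": s.persistence_ns,
            "contiguous": s.contiguous,
        }
        for s in sites
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
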