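"""End-to-end orchestration: fixture generation and the full analysis.

``generate_fixture`` writes a self-contained synthetic study — topology,
reference (crystal-like) structure, multi-model PDB ensemble and a ground
truth JSON — from one declarative spec.  ``run_analysis`` executes the whole
chain on any compatible inputs: pairwise-RMSD clustering and dihedral-state
segmentation with their concordance, pocket detection on every cluster
medoid and on the reference, the cross-snapshot overlap graph, candidate
sites with novelty and persistence, and the per-frame structural metrics.
Every stage writes its table next to a machine-readable report that echoes
the complete parameter set.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import conformations as conf
from . import metrics as met
from . import pocketgraph as pg
from . import pockets as pk
from .errors import SpecError
from .pdbio import (
    Structure,
    backbone_dihedrals,
    read_structure,
    read_trajectory,
    select_atoms,
    write_structure,
    write_trajectory,
)
from .synthetic import (
    CavitySpec,
    StateSchedule,
    ToyProteinSpec,
    build_toy_protein,
    generate_trajectory,
    make_state_library,
    plant_transient_cavity,
)

__all__ = ["FixtureSpec", "PipelineConfig", "ReportBundle", "generate_fixture", "run_analysis"]

log = logging.getLogger("crypticpocket")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic study.

    The defaults are the package's reference conditions: a 64-residue
    four-helix bundle, four conformational states visited irreversibly over
    400 frames at 1 ns, 0.5 Å isotropic coordinate noise, and one 150 Å³
    transient cavity gated by residues 12-19 that is open in states 2 and 3
    (200 consecutive ns).  ``cavity=False`` produces the matched negative
    control with no planted site.
    """

    n_residues: int = 64
    n_helices: int = 4
    helix_radius: float = 6.0
    n_states: int = 4
    displacement: float = 4.0
    min_separation: float = 4.0
    noise_sd: float = 0.5
    frame_interval: float = 1.0
    state_bounds_ns: tuple[float, ...] = (0.0, 100.0, 220.0, 300.0, 400.0)
    cavity: bool = True
    gate_range: tuple[int, int] = (12, 19)
    open_states: tuple[str, ...] = ("S2", "S3")
    target_volume: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise SpecError(f"n_states must be >= 1, got {self.n_states}")
        if len(self.state_bounds_ns) != self.n_states + 1:
            raise SpecError(
                f"state_bounds_ns needs {self.n_states + 1} edges for {self.n_states} states"
            )

    def schedule(self) -> StateSchedule:
        return StateSchedule(
            tuple(
                (f"S{i + 1}", float(self.state_bounds_ns[i]), float(self.state_bounds_ns[i + 1]))
                for i in range(self.n_states)
            )
        )


def default_cavity_center(structure: Structure, gate_range: tuple[int, int], target_volume: float) -> np.ndarray:
    """Cavity centre just outside the gate loop, on the outward normal.

    The gate Cα centroid is pushed away from the protein centroid by the
    cavity radius plus 1 Å, so the closed-state loop occludes the site and
    the opened gate can cage it.
    """
    resnums = structure.residue_numbers()
    names = np.array([a.name.upper() for a in structure.atoms])
    mask = (resnums >= gate_range[0]) & (resnums <= gate_range[1]) & (names == "CA")
    if not mask.any():
        raise SpecError(f"gate_range {gate_range} has no Cα atoms")
    g_ctr = structure.positions[mask].mean(axis=0)
    u = g_ctr - structure.positions.mean(axis=0)
    u /= np.linalg.norm(u)
    r_cav = (3.0 * target_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return g_ctr + u * (r_cav + 1.0)


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write topology/reference/ensemble PDB files plus ground-truth JSON.

    Returns the manifest (paths and ground truth).  Rerunning with the same
    spec reproduces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    protein = build_toy_protein(
        ToyProteinSpec(spec.n_residues, spec.n_helices, spec.helix_radius, spec.seed)
    )
    library = make_state_library(
        protein, spec.n_states, spec.displacement, seed=spec.seed + 1,
        min_separation=spec.min_separation,
    )
    cavity_center: list[float] | None = None
    if spec.cavity:
        center = default_cavity_center(protein, spec.gate_range, spec.target_volume)
        cavity_center = [float(c) for c in center]
        library = plant_transient_cavity(
            library,
            CavitySpec(spec.gate_range, tuple(center), spec.open_states, spec.target_volume),
        )
    schedule = spec.schedule()
    trajectory, labels = generate_trajectory(
        library, schedule, spec.noise_sd, seed=spec.seed + 2, frame_interval=spec.frame_interval
    )

    topology_path = outdir / "topology.pdb"
    reference_path = outdir / "reference.pdb"
    ensemble_path = outdir / "ensemble.pdb"
    truth_path = outdir / "truth.json"
    write_structure(protein, topology_path)
    write_structure(protein, reference_path)  # crystal-like reference = base state
    write_trajectory(trajectory, ensemble_path)

    open_frames = [i for i, lab in enumerate(labels) if lab in spec.open_states]
    truth = {
        "spec": asdict(spec),
        "state_labels": [str(lab) for lab in labels],
        "transition_frames": [
            int(round(b / spec.frame_interval)) for b in spec.state_bounds_ns[1:-1]
        ],
        "cavity_center": cavity_center,
        "cavity_radius": library.cavity.cavity_radius if library.cavity else None,
        "open_states": list(spec.open_states) if spec.cavity else [],
        "open_frames": open_frames if spec.cavity else [],
        "min_separation": library.min_separation,
    }
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    manifest = {
        "topology": str(topology_path),
        "reference": str(reference_path),
        "ensemble": str(ensemble_path),
        "truth": str(truth_path),
    }
    log.info("fixture written to %s (%d frames, %d atoms)", outdir, trajectory.n_frames, protein.n_atoms)
    return manifest


@dataclass
class PipelineConfig:
    """Complete parameterization of one analysis run."""

    topology: str
    ensemble: str
    reference: str | None = None
    output_dir: str = "results"
    frame_interval: float = 1.0
    cluster_cutoff: float = 2.0
    dash: conf.DashParams = field(default_factory=conf.DashParams)
    detector: pk.DetectorParams = field(default_factory=pk.DetectorParams)
    min_overlap: float = 0.30
    concordance_tolerance: int = 10
    loop_gap_ranges: tuple[tuple[int, int], tuple[int, int]] | None = None
    helicity_range: tuple[int, int] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "dash" in raw:
            raw["dash"] = conf.DashParams(**raw["dash"])
        if "detector" in raw:
            raw["detector"] = pk.DetectorParams(**raw["detector"])
        for key in ("loop_gap_ranges", "helicity_range"):
            if raw.get(key) is not None:
                val = raw[key]
                raw[key] = tuple(tuple(v) if isinstance(v, (list, tuple)) else v for v in val) \
                    if key == "loop_gap_ranges" else tuple(val)
        return cls(**raw)

    def echo(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class ReportBundle:
    """Machine-readable summary of a run: manifest, parameter echo, stage results."""

    report: dict
    sites: list[pg.CandidateSite]
    assignment: conf.ClusterAssignment
    segmentation: conf.Segmentation

    @property
    def novel_sites(self) -> list[pg.CandidateSite]:
        """Novel candidate sites seen in more than one MD snapshot.

        A transient site must be apparent in multiple cluster representatives
        and absent from the reference; single-snapshot components are kept in
        ``sites`` but not promoted to candidate-site status.
        """
        return [s for s in self.sites if s.novel and len(s.md_snapshots) >= 2]


def run_analysis(config: PipelineConfig) -> ReportBundle:
    """Execute the full pipeline and write all outputs under ``output_dir``."""
    t_start = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    stages: dict[str, dict] = {}

    def _stage(name: str, t0: float, **summary) -> None:
        stages[name] = {"seconds": round(time.time() - t0, 3), **summary}
        log.info("stage %-14s %s", name, summary)

    # -- inputs
    t0 = time.time()
    topology = read_structure(config.topology)
    trajectory = read_trajectory(config.ensemble, topology, config.frame_interval)
    reference = read_structure(config.reference) if config.reference else None
    _stage("load", t0, n_frames=trajectory.n_frames, n_atoms=topology.n_atoms)

    # -- conformational decomposition
    t0 = time.time()
    ca = select_atoms(topology, "name CA")
    matrix = conf.pairwise_rmsd(trajectory, ca)
    assignment = conf.cluster_frames(matrix, config.cluster_cutoff)
    assignment.to_csv(outdir / "clusters.csv")
    manifest["clusters"] = "clusters.csv"
    timeline = conf.occupancy_timeline(assignment, window_length=max(1, trajectory.n_frames // 20))
    timeline.to_csv(outdir / "occupancy.csv")
    manifest["occupancy"] = "occupancy.csv"
    _stage("cluster", t0, n_clusters=assignment.n_clusters,
           transitions=assignment.transition_frames().tolist())

    t0 = time.time()
    dihedrals = backbone_dihedrals(trajectory)
    segmentation = conf.dash_segment(dihedrals, config.dash)
    segmentation.to_csv(outdir / "segments.csv")
    manifest["segments"] = "segments.csv"
    concordance = conf.transition_concordance(assignment, segmentation, config.concordance_tolerance)
    concordance.to_csv(outdir / "concordance.csv")
    manifest["concordance"] = "concordance.csv"
    _stage("segment", t0, n_epochs=len(segmentation.epoch_labels),
           boundaries=segmentation.boundaries.tolist(),
           precision=concordance.precision, recall=concordance.recall)

    # -- pockets on medoids and reference
    t0 = time.time()
    pockets_by_snapshot: dict[str, list[pk.Pocket]] = {}
    all_rows: list[pk.Pocket] = []
    for cluster_id, frame in sorted(assignment.medoids.items()):
        plist = pk.detect_pockets(
            topology, config.detector, coords=trajectory.frames[frame],
            snapshot_label=str(cluster_id),
        )
        pockets_by_snapshot[str(cluster_id)] = plist
        all_rows.extend(plist)
    reference_pockets: list[pk.Pocket] = []
    if reference is not None:
        reference_pockets = pk.detect_pockets(
            reference, config.detector, snapshot_label=pg.CRYSTAL_LABEL
        )
        all_rows.extend(reference_pockets)
    pk.pockets_to_csv(all_rows, outdir / "pockets.csv", config.detector)
    manifest["pockets"] = "pockets.csv"
    _stage("pockets", t0, per_snapshot={k: len(v) for k, v in pockets_by_snapshot.items()},
           reference=len(reference_pockets))

    # -- overlap graph and candidate sites
    t0 = time.time()
    ref_coords = reference.positions if reference is not None else trajectory.frames[0]
    ref_struct = reference if reference is not None else topology
    ref_grid = pk.build_grid(ref_struct, config.detector.grid_margin, config.detector.spacing)
    mapped_by_snapshot: dict[str, list[pg.MappedPocket]] = {}
    for label, plist in pockets_by_snapshot.items():
        frame = trajectory.frames[assignment.medoids[int(label)]]
        mapped_by_snapshot[label] = [
            pg.MappedPocket(
                pg.PocketVertex(label, p.id, p.volume),
                pg.map_to_reference(p, frame, ref_coords, ca, ref_grid),
            )
            for p in plist
        ]
    mapped_reference = [
        pg.MappedPocket(
            pg.PocketVertex(pg.CRYSTAL_LABEL, p.id, p.volume),
            {tuple(q) for q in p.points.tolist()} if p.grid == ref_grid
            else pg.map_to_reference(p, ref_coords, ref_coords, ca, ref_grid),
        )
        for p in reference_pockets
    ]
    graph = pg.build_pocket_graph(
        mapped_by_snapshot, mapped_reference,
        min_volume=config.detector.min_volume, min_overlap=config.min_overlap,
    )
    sites = pg.find_candidate_sites(graph)
    for site in sites:
        if site.md_snapshots:
            site.persistence_ns, site.contiguous = pg.persistence(
                site, assignment, config.frame_interval
            )
    pg.graph_to_graphml(graph, outdir / "pocket_graph.graphml")
    pg.graph_to_dot(graph, outdir / "pocket_graph.dot")
    pg.sites_to_json(sites, outdir / "candidate_sites.json")
    manifest["pocket_graph"] = "pocket_graph.graphml"
    manifest["pocket_graph_dot"] = "pocket_graph.dot"
    manifest["candidate_sites"] = "candidate_sites.json"
    novel = [s for s in sites if s.novel and len(s.md_snapshots) >= 2]
    _stage("graph", t0, n_vertices=graph.graph.number_of_nodes(),
           n_edges=graph.graph.number_of_edges(), n_components=len(sites),
           n_novel_sites=len(novel))

    # -- structural metric series
    t0 = time.time()
    metric_files = []
    if config.loop_gap_ranges is not None:
        ra, rb = config.loop_gap_ranges
        gap = met.loop_gap_series(
            trajectory, met.ResidueRange(*ra), met.ResidueRange(*rb)
        )
        met.series_to_csv(gap, outdir / "loop_gap.csv", config.frame_interval)
        metric_files.append("loop_gap.csv")
    if config.helicity_range is not None:
        hel = met.helicity_series(dihedrals, met.ResidueRange(*config.helicity_range))
        met.series_to_csv(hel, outdir / "helicity.csv", config.frame_interval)
        metric_files.append("helicity.csv")
    for f in metric_files:
        manifest[Path(f).stem] = f
    _stage("metrics", t0, series=metric_files)

    report = {
        "config": config.echo(),
        "manifest": manifest,
        "stages": stages,
        "summary": {
            "n_frames": trajectory.n_frames,
            "duration_ns": trajectory.duration_ns,
            "n_clusters": assignment.n_clusters,
            "cluster_transitions": assignment.transition_frames().tolist(),
            "segment_boundaries": segmentation.boundaries.tolist(),
            "concordance_precision": concordance.precision,
            "concordance_recall": concordance.recall,
            "novel_sites": [
                {
                    "snapshots": sorted(s.md_snapshots),
                    "total_volume": s.total_volume,
                    "persistence_ns": s.persistence_ns,
                    "contiguous": s.contiguous,
                }
                for s in novel
            ],
        },
        "elapsed_seconds": round(time.time() - t_start, 3),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return ReportBundle(report, sites, assignment, segmentation)
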