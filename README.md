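# crypticpocket

Discovery of transient ("cryptic") binding pockets in protein conformational
ensembles.

Orphan nuclear receptors and other apparently undruggable proteins often show
no usable cavity in their crystal structures, yet long molecular-dynamics
simulations reveal conformations in which a druggable pocket opens
transiently. This package implements the complete analysis chain for finding
such sites in an ensemble, for computational structural biologists who have a
trajectory and want an auditable answer to "does a pocket open that the
crystal structure does not show, where, and for how long?"

## The method

Given a topology and a multi-model PDB ensemble (one frame per fixed time
interval, 1 ns by default):

1. **Conformational decomposition, two independent ways.**
   The pairwise superposed Cα-RMSD matrix (Kabsch superposition computed
   per pair) is clustered by average-linkage agglomerative clustering with a
   distance cutoff; clusters are renumbered by first temporal appearance and
   represented by their medoids. Independently, every backbone (φ, ψ) torsion
   is circularly smoothed, discretized into angular states by
   circular-histogram peak assignment, and a transition is placed wherever
   the per-frame state string changes by more than a threshold fraction;
   recurrent epochs share a conformation id. The two transition sets are
   matched greedily within a frame tolerance, giving a precision/recall
   concordance report.
2. **Pocket detection per representative.**
   A cubic lattice (1 Å) is laid over each cluster medoid and over the
   reference (crystal) structure. Lattice points outside the protein are
   scanned with 30 fixed quasi-uniform ray directions (length 10 Å, sampled
   every half spacing); a point is buried when at least `buriedness_min` of
   the rays pass within 2.5 Å of a heavy atom. Buried points form
   26-connected components; components of at least 100 Å³ are the pockets,
   numbered by volume ascending, each annotated with its flanking residues
   (heavy-atom contact within 4.5 Å).
3. **The pocket overlap graph.**
   Every pocket is mapped onto the reference lattice through a consensus
   core superposition, and pockets from different snapshots are connected
   when their mutual overlap |A∩B| / max(|A|,|B|) reaches 30%. Connected
   components are candidate sites; a component with no crystal vertex is a
   **novel** site, and its persistence is the total simulated time spent in
   its member clusters. A novel site must appear in at least two cluster
   representatives to be reported.
4. **Structural metric series.** Flap-gap distance (minimum Cα–Cα distance
   between two residue ranges), helicity fraction (φ ∈ [−100°, −30°],
   ψ ∈ [−80°, −5°]), and ligand pose RMSD under protein-frame superposition,
   with Schmitt-trigger event detection (threshold ± hysteresis, minimum
   dwell).

Because real trajectories of this scale are rarely shareable, the package
ships a synthetic-ensemble generator (`crypticpocket.synthetic`): a
helix-bundle pseudo-protein with ideal backbone geometry, a library of
well-separated conformational states, a piecewise-constant state schedule
with Gaussian coordinate noise, and a transient cavity of prescribed volume
gated by a flap of consecutive residues — with ground-truth labels for every
planted feature. All analyses are validated against this ground truth and
against independent oracles (quaternion superposition, Monte-Carlo void
volumes, brute-force graph arithmetic).

## Worked example

The numbered scripts under `analysis/` reproduce the whole study:

```sh
python analysis/01_generate_ensemble.py
python analysis/02_conformations.py
python analysis/03_pockets_and_sites.py
python analysis/04_ligand_metrics.py
```

which prints (seed 0):

```
study written: 400 frames, states separated by 6.4 A, cavity open for 200 ns in states ['S2', 'S3']
clusters: 4 (planted: 4); cluster transitions at [100, 220, 300] (planted: [100, 220, 300])
dihedral segmentation boundaries at [99, 219, 300]; epoch labels [1, 2, 3, 4]
concordance at ±10 frames: precision 1.00, recall 1.00
novel site: clusters {2, 3}, total volume 306 A^3, persists 200 ns (contiguous)
negative control novel sites: 0
ligand pose RMSD: stable regime median 3.4 A (59% of frames); excursions median 8.4 A
gate-loop gap: open-state mean 10.5 A, closed-state mean 6.4 A
```

Reading the output: the 400 ns ensemble visits four conformations
irreversibly; both decompositions find the same three transitions. Pocket
detection on the four cluster medoids and the reference finds the planted
cavity only in clusters 2 and 3; in the overlap graph those two pockets form
one component with no crystal vertex — a novel site covering 306 Å³ across
its two representatives that exists continuously for 200 ns, exactly the
planted open window. The cavity-free control ensemble yields no novel site.
The ligand series shows a stable ~3 Å pose with recurring excursions toward
~8 Å, and the flap-gap series separates open from closed epochs by ~4 Å.

The same pipeline runs from a shell on any topology + multi-model PDB:

```sh
crypticpocket fixture --outdir study --seed 0
crypticpocket analyze --topology study/topology.pdb --ensemble study/ensemble.pdb \
    --reference study/reference.pdb --outdir results
crypticpocket report results/report.json
```

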