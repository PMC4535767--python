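# Methods

This note records the models, parameter choices and numerical decisions
behind `crypticpocket`, in the order the pipeline runs them, together with
what the synthetic validation data does and does not establish.

## Scope and assumptions

The pipeline assumes a single-chain protein observed as a conformational
ensemble sampled at a fixed interval (default 1 ns per frame), with a
reference ("crystal") structure available for comparison. It treats the
ensemble as a sequence of metastable conformations separated by discrete
transitions — the regime in which cryptic-pocket analysis is meaningful.
Hydrogens are ignored everywhere; only heavy atoms participate in exclusion
and ray tests. Multi-chain input is accepted, with selections acting on
(chain, residue number) pairs, but all shipped studies are single-chain.

## Conformational clustering

The frame-frame distance is the Cα-RMSD after optimal proper-rotation
(Kabsch) superposition, computed independently for every pair (O(n²) in
frames; the batched 3×3-SVD evaluation keeps 1,000-frame matrices cheap —
default studies use 400). Clustering is average-linkage agglomerative with a
distance cutoff, the standard choice for trajectory clustering; the default
cutoff of half the smallest planted state separation (2 Å for the default
study) sits far above the within-state spread (≈0.7 Å at the default noise)
and far below the between-state distances (≥4 Å). scipy's deterministic
merge order resolves equal-distance merges; cluster ids are renumbered by
first temporal appearance so an irreversible multi-state trajectory reads
1, 2, 3, …; the representative of a cluster is its medoid (minimum summed
RMSD to the other members, earliest frame on ties).

The superposition residual is evaluated explicitly from the rotated
coordinates rather than through the singular-value identity, which loses
half the significant digits to cancellation exactly where it matters
(near-zero RMSD). Reflections are never returned (determinant forced to +1),
so mirror-image point sets superpose with a residual instead of silently
inverting chirality; collinear point sets are rejected as degenerate.

## Dihedral-state segmentation

Each backbone (φ, ψ) torsion series is first smoothed by a sliding circular
mean (window 11 frames), then discretized: a 10°-bin circular histogram is
smoothed with a wrapped Gaussian (σ = 25°), local maxima above 5% of the
tallest peak become angular states (peaks closer than 30° merge), and every
frame's angle is assigned to the nearest peak. Transitions are placed where
the similarity (fraction of matching symbols) between state strings one
smoothing window apart falls below 0.8, one boundary per below-threshold
run, at the run's minimum; epochs whose consensus strings agree at ≥0.9
share a conformation id, so a revisited conformation is a recurrence, not a
new state.

Two design points deserve explanation:

- **Smoothing in angle space, before discretization.** Isotropic Gaussian
  coordinate noise of 0.5 Å produces per-torsion jitter of 45–80° — far too
  broad for direct histogram peak-picking. Averaging on the unit circle
  over the window shrinks the jitter by ≈√11 before any discretization,
  after which peaks separated by ≥140° resolve cleanly. A majority filter
  applied after discretization (the obvious alternative) cannot rescue
  dihedrals whose histogram has already collapsed to a single peak.
- **Window-lagged similarity.** Comparing consecutive frames dilutes a
  transition that the smoothing has spread across the window: an 11-frame
  moving average turns a one-frame similarity dip of 0.5 into eleven dips
  of ~0.95, none of which crosses the threshold. Comparing strings one full
  window apart restores the full-depth dip while within-state flicker does
  not accumulate. Boundaries therefore carry an uncertainty of about half
  the smoothing window, which is the tolerance the concordance step and the
  validation tests use.

Transition concordance matches cluster-change frames to segmentation
boundaries greedily in temporal order within a tolerance (default 10
frames), each boundary used at most once; recall is the matched fraction of
cluster transitions, precision the matched fraction of segmentation
boundaries.

## Pocket detection

The detector is a grid buriedness scan: lattice spacing 1.0 Å, candidate
points farther than 2.5 Å from every heavy atom, 30 golden-spiral ray
directions of length 10 Å sampled every half spacing with a 2.5 Å hit
radius, buried points grouped by 26-connectivity, components of ≥100 Å³
reported ascending by volume. Distances are pre-evaluated once on a
half-spacing sub-lattice (exact at candidate points, which coincide with
sub-lattice nodes; ray samples use nearest-node lookup, a quantization no
coarser than the half-spacing ray sampling itself). Flanking residues are
those with a heavy atom within 4.5 Å of any pocket point.

**Buriedness threshold.** The package's default is 26 of 30 rays. On
desk-scale compact structures (the ~64-residue validation bundle, radius of
gyration ≈10 Å) a permissive threshold such as 16/30 marks the entire
inter-helix groove network as buried and percolates it into a single
~1800 Å³ surface-hugging component that touches every residue — a
qualitatively wrong answer, not a marginal one. At 26/30 only strongly
enclosed voids survive, which is the regime a planted cavity (and any void
worth calling a pocket on a structure this small) occupies. On larger
proteins with deeper surface topography a lower threshold is appropriate;
the value is an explicit `DetectorParams` field, as are all scan constants.

## Pocket mapping and the overlap graph

Pockets live on per-snapshot lattices and must be compared on the reference
lattice. Each medoid frame is superposed onto the reference over the shared
Cα selection using a **consensus core fit**: every contiguous 12-residue
window seeds a Kabsch fit, each candidate is refined on its inliers (Cα
within 2 Å after superposition), and the fit with the most inliers wins. A
plain global fit is the wrong tool here: when conformations differ by a
large local rearrangement (9–12 Å Cα-RMSD between the validation states),
least squares splits the difference between core and moved region and
scatters the mapped pocket by 5–15 Å; simple iterative trimming inherits the
bad global starting point and stalls. The consensus fit is deterministic,
needs no ground-truth knowledge of which residues form the core, and reduces
exactly to the global fit when the structures agree. Pocket node centres are
transformed and re-quantized to the nearest reference cell (error ≤ one
spacing per node).

Mutual overlap is |A∩B| / max(|A|,|B|): it reaches a threshold θ exactly
when both directed overlap fractions do, which is the natural meaning of a
mutual 30% requirement (Jaccard is available as an alternative measure of
the same sets). Edges connect pockets of different snapshots only; two
pockets of one scan are disjoint components by construction. Connected
components are candidate sites, ranked by summed member volume; a component
containing no reference vertex is novel. Isolated vertices stay in the data
model (hiding them is a rendering option of the DOT export only).

The pipeline's report promotes a novel component to a *candidate site* only
if it spans at least two distinct cluster representatives. A pocket seen in
a single snapshot of a noisy ensemble is indistinguishable from a packing
accident of that one structure; requiring multiple representatives is the
cross-validation the ensemble itself provides. Site persistence is the
summed duration of all frames assigned to the site's member clusters, with a
contiguity flag (true iff those frames form one unbroken run).

## Structural metrics

The flap gap is the minimum Cα–Cα distance between two disjoint residue
ranges — minimum rather than centroid distance so internal rearrangement of
a disordered loop does not masquerade as opening. Helicity of a range is
the fraction of residues with φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°], a
broad α-region window; residues with undefined torsions leave the
denominator. Ligand pose RMSD superposes each frame onto the first over the
protein selection and measures the ligand atoms with no separate ligand
refit, so excursions within a stable protein frame register directly.
Event detection is a Schmitt trigger: falling events fire after the series
stays below threshold − hysteresis for a minimum dwell, rising events
symmetrically above threshold + hysteresis; events alternate by
construction, and any noise realization bounded by the hysteresis yields
the same event set.

## The synthetic study

The generator emulates the statistical structure the analyses assume, at
desk scale:

- **Protein**: a 64-residue four-helix bundle built residue-by-residue from
  canonical internal coordinates (bond lengths exact; helical segments at
  ideal α torsions φ = −60°, ψ = −45°), helix axes antiparallel on a 6 Å
  circle; the four-residue connectors are solved by least squares with
  clash-avoidance penalties so the chain closes onto the planned bundle. A
  CB pseudo-side-chain atom per residue keeps the core packed the way real
  side chains would, so the only sizeable cavity is the planted one.
- **States**: conformer 1 is the base structure; further conformers apply
  one fixed near-antipodal torsion flip (140–180°) per tail torsion over
  Gray-coded blocks of the C-terminal 55% of the chain. This makes every
  dihedral at most bimodal across the whole library (robust discretization
  under heavy noise), changes a full block of torsions at every consecutive
  transition (detectable by both decompositions), and leaves the N-terminal
  core identical across states (pockets map consistently). Realized
  pairwise Cα separations are 5–12 Å, reported as δ in the library;
  generation retries with a wider tail if a requested minimum separation is
  missed.
- **Schedule and noise**: states are visited irreversibly
  (100/120/80/100 ns by default) and each frame adds iid isotropic Gaussian
  displacement (0.5 Å default) per atom. This noise model is deliberately
  crude: it reproduces the *magnitude* of thermal scatter but none of its
  correlations, and (as noted above) it produces much larger torsion jitter
  than real dynamics. Passing recovery tests under it therefore shows
  robustness to worst-case angular noise, but says nothing about
  correlated motions, solvent effects or force-field realism.
- **Cavity**: the gate (residues 12–19, spanning a loop and its flanking
  helix turns near the N-terminus) is displaced outward onto a quasi-uniform
  shell around a centre placed just outside the closed loop; the shell
  radius is solved by bisection so the enclosed void (fine-grid integral at
  the detector's 2.5 Å probe clearance) matches the 150 Å³ target. Closed
  states are untouched — the site is then ordinary convex surface, which is
  why no pocket is found there. Planting never moves a non-gate atom, and
  planting fails loudly if a non-gate atom occludes the centre.

Ground truth (per-frame state labels, transition frames, open-state frames,
cavity centre and realized shell radius) is serialized as JSON beside the
multi-model PDB.

## Validation and oracles

Every layer is checked against an implementation that takes a different
route: superposition RMSD against the quaternion characteristic-polynomial
method (agreement to 10⁻⁸ Å over random point sets); dihedrals against an
explicit plane-normal construction and against MDAnalysis; planted-state
recovery for K ∈ {2, 3, 4} states at 0.5 Å noise (clustering ARI ≥ 0.9,
every planted transition within the smoothing window, concordance
precision = recall = 1 at 10-frame tolerance); detector volumes within ±20%
of Monte-Carlo void integration (measured: within a few percent); the
overlap-graph edge set equal to brute-force all-pairs set arithmetic; and
end-to-end recovery of exactly one novel site spanning exactly the open-state
clusters with persistence equal to the planted open window, with zero novel
sites on the cavity-free control. `scripts/acceptance.py` re-runs all of
this from scratch for any seed.

## Known limitations

- The dihedral segmentation is a documented variant of dihedral-state
  analysis, not a re-implementation of any published tool's exact smoothing
  and repair passes; its guarantees are those stated here.
- Consecutive-state detectability of the segmentation is engineered for
  libraries of up to ~4 states (two Gray blocks); more states shrink the
  per-transition block and weaken the dihedral signal.
- The buriedness scan reports enclosed voids; shallow druggable grooves on
  large proteins need a lower buriedness threshold and correspondingly more
  careful false-positive control.
- Pocket volumes are lattice counts: ±1 spacing-shell quantization under
  rigid motion (≤10% for ~150 Å³ pockets).
- The generator's Gaussian noise is uncorrelated; elastic-network-style
  correlated noise is a possible extension and would sharpen, not weaken,
  the dihedral analysis.
- PDB dialect support is minimal by design (no altlocs, insertion codes or
  anisotropic records); binary trajectory formats are out of scope.
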