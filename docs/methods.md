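# Methods

This note records the models, defaults and numerical choices behind
`beadmap`, and what the synthetic studies do and do not demonstrate.

## The reconciliation model

Two instruments observe the same FIFO queue of objects: an imaging flow
cytometer (the reference readout) and a plate camera on the dispensing
robot. Objects are cells or marker beads; beads come in three sizes
(10/20/30 µm) written as symbols A/T/C. A readout is summarised as a
**marker sequence**: the bead-symbol string plus, for each of the
`len(symbols)+1` gaps, the ordered cells that fell in it. Mixing cells and
beads 2:1 keeps the mean interior gap at n̄ = 2 cells, small enough that a
per-gap count comparison is informative.

Two error processes corrupt the plate-side queue:

* **deletion** — each event independently removed with probability *r*
  (an object trapped in the fluidics);
* **misplacement** — each event independently relocated by a uniformly
  random nonzero offset in [−`max_shift`, +`max_shift`] positions
  (default 5), clamped to the stream bounds. Order scrambling in laminar
  flow is local, so relocation distance is bounded; the true displacement
  distribution of the physical system is unknown, and this choice is a
  documented model, not a measured fact. Moves are applied sequentially;
  each truth record stores removal and re-insertion indices at move time
  (local moves leave indices outside the moved span untouched, so these
  stay within a couple of positions of the pre-error frame).

Out-of-focus cells are a generation-time attribute (default probability 0),
not an error process: they keep their place in the queue but their image is
unusable, so they are mapped with `usable=False`.

## Alignment and error classification

The two symbol strings are globally aligned with Needleman–Wunsch scoring
match +5 / mismatch −4 / gap −8 (linear). These defaults mirror the NUC44
substitution values and default gap penalty of the MATLAB-style aligners
commonly used for this task; all three are configurable. Linear rather than
affine gaps: bead losses are independent events, not bursts. The aligner is
Biopython's `PairwiseAligner`; among co-optimal alignments the first
traceback is taken, which is deterministic for fixed inputs. Alignment
score is validated in the test suite against an independent brute-force
enumeration of all global alignments for short sequences.

Discrepancy columns of the consensus map are classified:

1. symbol-over-gap → candidate **deletion** (bead imaged, missing on the
   plate); gap-over-symbol → candidate **insertion**;
2. a candidate deletion and insertion of the *same* symbol within
   `pair_window` columns (default 10) merge into one **misplacement**;
3. adjacent complementary mismatch columns (x,y)(y,x) — the signature of a
   swapped neighbour pair — merge into one misplacement;
4. residual isolated mismatches are misplacements; leftover candidates
   keep their deletion/insertion class.

**Localization convention.** A gap placed inside a run of identical symbols
is positionally ambiguous: every placement within the run is a co-optimal
alignment. Each reported error therefore carries the maximal
same-symbol run containing its site, and an injected error counts as
*located* when its true position lies within `tolerance` symbols (default
±2) of that span — for misplacements, of the removal span on the imaging
coordinate or the re-insertion span on the plate coordinate. Any quoted
detection probability is conditional on this convention and on the
misplacement-distance model; both must travel with the number.

## What the Monte Carlo study shows

With length-10,000 i.i.d. symbol sequences and 20 replicates
(`mc_experiments.detection_curve`):

* at 5 % deletion, ~99.5 % of injected deletions are located; at 1 %,
  effectively all of them;
* at 5 % misplacement under the local ±5 model, ~90–91 % are located.
  This figure has a structural ceiling: a move confined to a run of
  identical symbols leaves the sequence byte-identical and is undetectable
  *in principle* from the sequences. Under the local model the expected
  invisible fraction is E[(1/3)^|d|] ≈ 9.9 % of moves (d uniform on
  ±{1..5}), which is exactly the gap to 100 % — the classifier finds
  essentially every visible move at this rate. The ceiling is
  rate-independent, so misplacement detection does not reach 1.0 even at
  0.5 % rates. In the full pipeline such invisible bead moves are harmless
  to mapping only when no cells separate the swapped beads; otherwise they
  surface as per-gap count mismatches and are dropped by the count check.

## Drop rules and the yield/accuracy trade

A gap is accepted iff (i) both flanking bead columns are clean matches,
(ii) the matched beads are adjacent in *both* sequences (no error between
them), and (iii) imaged and plated cell counts agree. Flanking gaps (before
the first / after the last bead) have no verifying pair and are always
dropped. A directional variant ("drop only the gap *after* an erroneous
bead") collapses to this symmetric rule in practice, because a gap without
a cleanly matched left bead cannot be count-verified anyway; only the
symmetric rule is implemented.

Within an accepted gap, pairing is strictly positional. Equal counts with
internally reordered cells are therefore an *undetectable residual risk*:
at 1 % + 1 % error rates on all events, simulations (20 seeds,
1,000 markers) put retention at ~87 % with ~1.3 % of retained cells
misassigned, all of them from within-gap relocations. Zero-error runs map
every interior cell with zero misassignment, and when injected errors fall
only in dropped segments the retained cells are exactly right — the safety
property the drop rules exist for.

`retention_fraction` uses interior (verifiable) imaged cells as the
denominator, since flanking gaps are dropped by construction;
`retention_fraction_total` reports the all-cells denominator alongside.

## Plate imaging

Synthetic plates emulate a low-resolution wide-field camera at 2.5 µm/pixel:
anti-aliased bright disks (objects) over dimmer small disks (membrane
pores, ≤5 µm, Poisson-placed at ~200/mm²) plus additive Gaussian noise.
Detection: light Gaussian blur (σ = 0.5 px), global Otsu threshold
(configurable fixed threshold), removal of connected components with
equivalent diameter ≤ 8 µm (pores; the cutoff must stay below the 10 µm
bead), then per-component intensity-weighted centroids and equal-area
diameters, in µm with the pixel-centre convention. Classes are assigned by
configurable diameter bands; the defaults separate 10/20/30 µm beads and an
18 µm synthetic cell size. Real cells overlap bead sizes optically — band
configuration is per-experiment, and the synthetic fixtures deliberately
use separable sizes. Coordinates are registered by translating the first
marker bead in dispensing order (ascending x, then y) to (0, 0). On
20-object fixtures the worst registered centroid error is well under 1 µm,
comfortably inside the ±10 µm pickup requirement; what the fixtures do not
model is uneven illumination, object blur gradients, touching objects or
membrane texture beyond circular pores.

## Morphology and clustering

2D features (area, equivalent-ellipse major/minor axes, Crofton perimeter)
come from `skimage.measure.regionprops` on the transmission-image mask; 3D
features are voxel counts (volume) and exposed voxel faces (surface area),
which are exact for axis-aligned shapes and biased high (~1.5×) on smooth
ones — accepted for testability against analytic cubes and spheres.
Optional extras (eccentricity, solidity, sphericity, extent, aspect ratio)
are off by default and clearly labelled: only six canonical features are
standard in this workflow's registration tables.

`MorphoKMeans` is a from-scratch Lloyd's algorithm with k-means++ seeding,
`n_init = 10` restarts (best inertia kept), z-score standardisation frozen
at fit time and reapplied at predict time, convergence when the centroid
shift drops below `tol = 1e-6` or after `max_iter = 300` iterations, ties
to the lowest centroid index, and `k = 2` by default (diseased vs normal
morphology). Identical-point degenerate input replicates a single centroid
and warns. The implementation is cross-checked against scikit-learn's
KMeans inertia in the test suite, never backed by it.

## Problem sizes and determinism

Every stochastic routine takes an explicit integer seed and spawns child
generators from it; equal seeds give byte-identical outputs. Default study
sizes — 10,000 symbols × 20 replicates for detection curves, 1,000 markers
× 20 seeds for retention, 20-object plates — were chosen as the package's
standard desk-scale operating points; the acceptance script and tests state
the sizes they use in their output.
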