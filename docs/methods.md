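# Methods

`nephtrack` reconstructs individual kidney tubules (nephrons) in three
dimensions from an ordered stack of serial histological section images.
Nephrons are densely packed, highly tortuous epithelial tubes whose open
interior channel — the lumen — is the only structure that can be
isolated reliably on toluidine-blue sections, because tubule walls touch
one another. The system therefore segments lumens per slice, abstracts
them into point "nodes" carrying shape information, and links nodes
across slices from a user-supplied seed with a guarded graph search.
This note documents the model, its parameters, the numerical choices,
and what the synthetic phantoms do and do not establish.

## Preprocessing

Each slice is converted to grayscale, the bare slide background is
removed (threshold at `background_threshold`, largest connected
component, morphological closing with a circular kernel, inversion and
multiplication), contrast is equalised twice with contrast-limited
adaptive histogram equalisation (a large `global_eq_window`, then a
small `local_eq_window`), and a simple threshold at `binary_threshold`
produces the binary lumen mask. Erode/dilate cycles with a disk kernel
(`erode_dilate_radius`, `erode_dilate_cycles`) strip thin interstitial
slivers, and components outside [`min_area`, `max_area`] =
[10, 100 000] px² are discarded as non-lumen.

Intensity convention: lumens are bright against dark-stained walls, and
the empty slide is brighter than any tissue. The convention is a flag
(`lumen_bright`) because staining chemistry can invert it. Background
pixels are pinned to zero again *after* equalisation: adaptive
equalisation has no notion of "empty slide" and would otherwise remap
constant background tiles to full intensity.

Tubule diameter collapses abruptly at the outer-medullary transition
zone (thick limbs of ~60 µm narrowing to thin limbs of 10–15 µm), so
every numeric preprocessing parameter may be scheduled over depth with a
logistic curve

    v(n) = medulla + (cortex − medulla) · σ(−k (n − n₀)),

parameterised by its two asymptotic values, the inflection slice `n₀`
(placed at the transition zone) and steepness `k` (1/slices). The value
is monotone in depth and bounded by the asymptotes.

Defaults (`binary_threshold` 0.7 post-equalisation, `background_threshold`
0.85, kernel radius 1, one cycle, CLAHE clip limit 0.02) are calibration
values for intensity range [0, 1]; like any histology pipeline they are
expected to be re-calibrated per dataset and are all exposed in the run
configuration. The area limits are fixed points of the method.

Defective slices (detected as mean-intensity outliers beyond 3 robust
standard deviations from the stack median, or listed explicitly) are
replaced by a copy of the nearest intact neighbour, preferring the slice
above on ties, so slice numbering never changes.

## Feature extraction

Binary slices are segmented into 4-connected components ("cross
sections"). Each component is abstracted by:

- **Nodes** — K-means centroids over the component's pixels. K starts at
  1 and increments until the mean spacing between adjacent nodes
  (nearest-neighbour chain order, started from the node farthest from
  the centroid) falls below `node_spacing` (default 20 px). At K = 1
  there is no pair to measure, so the node's *reach* — the maximum
  distance from the lone centroid to any component pixel — stands in:
  a round lumen keeps one centroid while a long thin component still
  splits. Clustering is seeded (K-means++ with 3 restarts, fixed
  `random_state`) so runs are reproducible; centroids are rounded to the
  nearest pixel and snapped onto the component when concavity pushes a
  centroid off the mask.
- **Shape factors** — circularity 4πA/P² (boundary-chain perimeter with
  √2 diagonal weighting), eccentricity and axis lengths of the
  moment-equivalent ellipse, solidity A/A_hull, aspect ratio
  major/minor, plus the absolute descriptors area and minor axis length.
  One-pixel components use defined fallbacks (eccentricity 0, aspect
  ratio 1, minor axis 1).
- **Shape (centroidal) profiles** — the boundary radius sampled every
  15° (24 values) around each node. The component boundary is extracted
  as an ordered closed sub-pixel contour; each boundary segment
  contributes the grid angles it crosses, with the radius linearly
  interpolated at the crossing; multivalued angles keep the *first*
  crossing along increasing radius, since the profile describes the
  local lumen outline. Profiles are computed on the binary mask
  boundary, not on a grayscale edge map.

Coordinates are 0-based with x = column, y = row, z = slice index;
angles are measured from the +x axis.

## Tracking

From a seed node the tracker grows a tree with open/closed lists. Each
expansion proposes at most one **vertical** link per direction — the
nearest node on the slice above/below within the tracking radius
`r_track`, strictly — and **horizontal** links chaining all nodes of an
entered cross section by nearest-neighbour order. Before a vertical
candidate is searched, the two slices are locally registered: a
`registration_window`-sized patch around the current node is matched by
normalised cross-correlation within ±`max_shift` px, translation only,
and the offset is reverted once the link is committed so offsets never
accumulate. Flat patches yield a zero offset flagged low-confidence.

Proposed vertical moves then pass a rule base ordered by computational
cost:

1. **Distance rule** — the xy distance must be strictly less than
   `distance_coefficient` × (r_parent + r_child), with r = half the
   minor axis length.
2. **Skip rule** (only when slices are skipped) — at most `max_skip` = 2
   images may be skipped, and each of the six shape factors may change
   by at most `shape_change_limit` = 30 %. The percentage change is
   taken relative to the pre-skip value floored at the factor's
   characteristic scale (0.5 for the bounded dimensionless factors,
   1 px for the minor axis, 10 px² for area): a raw relative change on a
   near-zero eccentricity would reject legitimate skips on round tubes.
3. **Bidirectionality rule** — re-running the vertical search from the
   candidate back toward the parent's slice must return the parent
   itself.
4. **Machine-learned validation** (optional, below).

Skips are attempted only at dead ends, gated by a direction buffer (the
last 5 accepted move directions must agree to ≥ 80 %) and a refractory
period (≥ 10 accepted moves between attempts), so skipping never fires
on turns and bends. A rejected or empty direction is a true dead end
only if no sibling node of the same cross section continues that way.
When the open list empties, remaining dead ends either set the
"correction requested" flag or, when a correction provider is given,
are offered to it most-recent-first; a returned bridge node is linked
as a manual correction and tracking resumes. This realises manual
intervention non-interactively: tests supply ground-truth bridges, a
front end can supply user clicks.

`r_track` may be a constant (default 25 px), a depth schedule, or
`"auto"` (1.5× the mean nearest-neighbour spacing of cross-section
centroids on the target slice).

A class-5 "region signal" from the classifier switches tracking to
unidirectional mode for the inner medulla: expansion proposes vertical
candidates only in the dominant depth direction, reversing once when a
hairpin (loop-of-Henle turn, detected as a horizontally traversed
multi-node cross section with no forward continuation) is reached.

**Reconstruction** keeps the longest root-to-leaf path by node count
(ties: deepest terminal z, then smallest node id), annotated with the
per-point lumen radius (half minor axis). **Evaluation** against a
reference path uses per-slice xy residuals with a 15 px threshold:
accuracy α is the percentage of tracked points within the threshold of
the reference on the same slice, extent β the percentage of reference
points matched by some tracked point. α is undefined (an error) for an
empty path.

## Machine-learned move validation

A move between two cross sections is a 66-value vector: 6 shape-factor
means, 6 differences, the offset-corrected xy distance, the relative z
position in the stack, the image difference (1–3), the registration
offset (dx, dy), both 24-sample profiles, and the Pearson correlation of
the profiles (two zero-variance profiles count as perfectly correlated,
one as uncorrelated). Five classes are distinguished: (1) normal move
between circular cross sections and (2) between elongated ones — valid;
(3) abnormal move onto interstitial tissue or vessels — invalid;
(4) move involving a glomerulus — terminates tracking at the nephron
origin; (5) move in the inner medulla — a region signal, not a validity
verdict, and excluded from valid/invalid accuracy accounting.

Two one-vs-all families are trained on z-scored features
(standardisation fitted on the training split only; default split
0.7 : 0.15 : 0.15): a feed-forward neural network (one hidden layer of
20 logistic units — the topology is a design choice, exposed in config)
and an SVM with an RBF kernel of width 5 (γ = 1/(2·5²)). Voting is the
argmax over the five scores; for the neural network a winning valid
class must additionally clear a score threshold (default 0.3), so
raising the threshold monotonically rejects more moves — the sensitivity
dial that trades tracked extent against false positives. Training
examples are captured from unregulated tracker runs (no ML validation)
and labelled by a callable — ground truth on phantoms, a human in
production — with per-class balancing done by generating more data, not
by duplication. Models persist to a versioned archive carrying the
scaler, per-class learners, threshold, and a feature-layout hash that
load-time verification checks.

## Synthetic phantoms

The generator renders tubes slice-by-slice as a dark wall annulus
around a bright lumen inside an interstitial tissue matrix (intensity
0.40) bounded by a 3-px bare-slide frame (0.92). The tissue matrix is
load-bearing: background removal closes its mask with a circular
kernel, and isolated structures floating on bare slide would be
swallowed by that closing. Tube centerlines are Gaussian-smoothed random
walks (per-slice step s.d. = tortuosity) with optional constant drift;
oblique tubes are drawn as ellipses elongated by sec(tilt) along the
travel direction, which is what produces genuinely elongated (class-2)
cross sections. Radius follows the same logistic schedule as the
preprocessing parameters (reference condition: 12 px → 4 px across
slice 120, echoing the thick-to-thin-limb transition). Optional
ingredients: thin 3-px-wide clutter slivers kept mutually disjoint
(components per slice = `clutter_density`), whole-slice or rectangular
blank artefacts, a lobulated glomerulus surrogate at a tube origin, a
hairpin turn, per-slice integer misalignment ~ round(N(0, sd)) recorded
in the ground truth, and Gaussian intensity noise. Everything is
deterministic given the seed; ground truth includes per-tube centerline
paths (in both shifted and unshifted frames), the shift table, and a
per-pixel label volume.

Default nuisance magnitudes follow the regime the generator emulates —
serial sections that have already been globally registered, leaving a
few pixels of residual local misalignment: s.d. 2 px on the reference
phantom, 4 px where the half-normal shift statistic itself is under
test, 2.5 µm slice thickness, ~1.16 µm pixels.

What the phantoms do **not** emulate: real toluidine-blue texture and
staining variability, tissue folds and nonrigid distortion, touching
lumens that merge through thin walls, the detailed internal structure of
glomeruli, and inter-animal variability. Passing phantom tests
demonstrates the algorithmic machinery — isolation, abstraction,
guarded linking, skip logic, classifier recovery of planted class
structure — not histology-grade segmentation accuracy; classifier
accuracies on phantom move data mirror the *shape* of real-data results,
never their value.

## Problem sizes and numerics

Tests and the acceptance script use 96–220 px slices and 16–220-slice
stacks: large enough that every mechanism (transition-zone narrowing,
clutter rejection, skip gating, class balance) is exercised, small
enough to keep full runs to minutes on one core. Ties in K-means are
fixed by seeding; component labels follow raster order; the longest-path
tie-break is documented above; degenerate inputs (empty slices, flat
registration patches, 1-px components, empty graphs) all have defined
behaviour rather than exceptions, except where the contract demands an
error (seed off any cross section, empty path in α, all slices
defective).

## Known limitations

- Strict node-level bidirectionality can reject valid moves when a cross
  section carries several nodes; the cross-section-level dead-end test
  recovers most of these, but a cross-section-level reverse check is a
  possible refinement.
- Unidirectional (inner-medulla) mode reverses at most once per hairpin
  and relies on the region signal being raised near the transition.
- Registration is translation-only by design; rotational or nonrigid
  local distortion is out of scope.
- The correction provider contract is non-interactive; no GUI is
  included.
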