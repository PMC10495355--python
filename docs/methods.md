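# Methods

This note documents the models, estimators and numerical conventions
implemented in `myxotrack`, the assumptions behind the synthetic-scene
generator, and the design choices made where the analysis was genuinely
underdetermined.

## Coordinate and unit conventions

All images are (row, col), 0-based, origin top-left; frames are 0-based.
Spatial quantities are in pixels and temporal quantities in frames unless a
`dt` or `pixel_nm` conversion is applied. The default acquisition constants
mirror a fast time-lapse predation assay: 106 nm per pixel and a 38 s frame
interval (midpoint of a 35–40 s cadence).

## Synthetic predation scenes

The generator (`myxotrack.synthetic`) emulates the statistical structure
the analysis stages assume, not the microscopy physics:

- **Cells** are axis-capsules (rectangle plus semicircular caps) at
  configured length and width, painted into integer label images in cell-id
  order; when capsules overlap, the later id wins the pixels while the
  ground truth keeps the true geometry. Default geometry is 40 × 5 px
  (≈ 4.2 × 0.5 µm), a typical rod.
- **Motion** comes in three regimes. Directed: constant speed along a
  heading performing a Gaussian random walk (default 10 px/frame
  ≈ 1.7 µm/min, heading sd 0.2 rad/frame). Brownian: iid Gaussian
  displacements (default sd 2 px/frame/axis). Confined: Brownian steps
  radially reflected at a disk around an anchor (default radius 5 px).
  These produce MSD exponents above, at, and below 1 respectively, which is
  what the directionality analysis must distinguish.
- **Populations and classes.** Scouts move directed, loners confined, and
  swarm members ride a latent group-centroid path (directed at half speed)
  plus a small random offset clamped to the cohesion radius (default
  30 px), so members provably stay within that radius of their group's
  path. Each cell's true class evolves as a 3-state Markov chain switching
  to each other class with a configured per-frame probability (default
  0.01); a cell entering the swarm class joins the nearest group, one
  leaving it anchors or strikes out where it stands. Transition rates are
  free parameters of the generator — no empirical rates are implied — and
  symmetric defaults make forward and reverse transitions equally probable
  by construction.
- **Trail following.** A `trail_following` knob in [0, 1] sets the
  probability that a swarm group retraces a scout's actual path with a
  5-frame delay, its members strung out along the path (the offset
  component perpendicular to the local tangent is damped). This gives a
  controlled dial for trail-sharing analyses.
- **Prey channel.** The lawn has unit intensity; a lysis front starting at
  a configured row advances down the rows at a configured speed, and each
  point decays as exp(−λ·(time since the front passed)) with λ the lysis
  rate (default 0.02 frame⁻¹). Rendering multiplies by a centred Gaussian
  excitation profile (peak 1), by exp(−b·t) for bleaching (default
  b = 0.002 frame⁻¹), and adds Gaussian noise, clipping at zero.
- **Determinism.** One master seed is split per cell id (and per purpose)
  through NumPy seed sequences, so output is bit-identical across reruns
  and independent of iteration order.

What the generator does **not** emulate: cell growth and division, true
steric interactions (overlaps are resolved by z-order, not mechanics),
photophysics beyond exponential bleaching, segmentation errors other than
the occlusions that overlap produces, and any spatial feedback between the
predator and prey channels. Passing tests therefore demonstrate that the
estimators recover what the model puts in — boundaries, rates, exponents,
time constants — not that they are robust to every artifact of real
segmentations.

## Tracking

Candidate links between consecutive frames are restricted to mask pairs
with centroid distance ≤ 30 px (about one cell length at default geometry)
or nonzero pixel overlap. Three similarity criteria, each normalized to
[0, 1]: overlap / min(areas); min/max of areas; min/max of backbone
lengths. The composite score is their weighted sum with Analytic Hierarchy
Process weights: the normalized principal eigenvector of a positive
reciprocal comparison matrix, by default overlap : area : length at 3 : 1
and 2 : 1 (a perfectly consistent matrix; the Saaty consistency ratio is
checked < 0.1 for user-supplied matrices). The one-to-one assignment per
frame pair maximizes total score over candidates with score ≥ 0.1
(Hungarian method on the negated score matrix, with an epsilon that steers
equal-score optima toward smaller label pairs for determinism).

A mask at t+1 overlapping two or more predecessors is flagged as a fusion
and, by default, terminates the incoming tracks rather than inheriting one
identity — fusions are segmentation artifacts and merging identities would
corrupt downstream per-cell statistics. There is no gap closing across
missing frames and no division handling. In dense swarms, occlusion by
overlapping capsules fragments tracks; near-complete link recovery is only
expected (and only asserted) for cells whose trajectories stay separated.

## Spatial descriptors

**Backbones.** Masks are skeletonized (scikit-image); skeleton pixels with
three or more 8-connected skeleton neighbours are branchpoints and are
deleted, splitting the skeleton into simple segments. Each segment's length
is its geodesic diameter on the 8-connected pixel graph (orthogonal steps
weigh 1, diagonal √2), its midpoint is the point at half that arc length,
and its tortuosity is path length over end-to-end distance (1 for a
straight segment). Branchpointed masks contribute one Voronoi seed per
segment; such a mask's V is the summed area of its segments' polygons.

**Voronoi areas.** The tessellation is computed on backbone midpoints
together with their mirror images across the four field edges; this closes
every border cell exactly, so intersecting with the field rectangle gives
the clipped polygon areas directly (they sum to the field area to 1e-6
relative). Duplicate seeds are perturbed by a deterministic epsilon with a
warning. A single seed owns the whole field.

**Clusters.** The binary union of masks is dilated with a square kernel
(default 10 px). An even kernel has no centre pixel; the anchor is fixed at
the top-left element of the central 2 × 2 block, so a 10-px kernel reaches
4 px up/left and 5 px down/right — the convention is arbitrary but
deterministic and matched by the test oracle. Connected components
(8-connectivity) of the dilated image define clusters; cluster area is the
summed **non-dilated** member area, and N = area / mean single-cell area.
The mean single-cell area defaults to the median area of this frame's
single-member clusters, falling back to a configured constant (200 px²,
the default capsule's area) when every mask is clustered; the estimator for
"average single-cell area" is not otherwise determined.

## Classification

The decision rules over (log₁₀ V, N) are: loner ≤ (4.5, 2); scout
(≥ 4.5, ≤ 20); swarm (≤ 4.5, > 2). Two corners need conventions. At
log₁₀ V = 4.5 both the loner and scout rules hold; the tie goes to scout
(isolation is the marked condition). The region log₁₀ V > 4.5 with N > 20
is covered by no rule and is returned as `unclassified` rather than being
silently assigned — inventing a rule there would be inventing biology. Both
conventions are configurable. The motile filter keeps tracks whose
end-to-end displacement strictly exceeds 2 px; a variant normalizing by
track length (displacement per frame > threshold) is available by flag,
since both formulations are in circulation for motile-only histograms.

2D histograms over (log₁₀ V, N) default to 100 linear bins over
log₁₀ V ∈ [2, 7] and 100 log-spaced bins over N ∈ [1, 10³]; per-replicate
histograms are normalized to unit mass before averaging, and differences
are taken bin-wise (summing to ~0).

## Motion statistics

MSD is time-averaged over all overlapping start points per lag — the usual
convention of trajectory-analysis toolkits; a brute-force pair-loop oracle
checks it in the tests. The directionality exponent α is the OLS slope of
log MSD versus log lag over lags 1–5. A zero MSD at any fitted lag makes
the fit undefined and is reported as missing: such cases arise from stalled
or mis-linked tracks and a fabricated exponent would be noise. Speed at
frame t is the straight distance between positions t−5 and t+5 divided by
the 10-frame interval; frames within 5 of a track end are skipped, not
zero-filled. The gyration radius is the **mean** (not RMS) distance of
trajectory points from their centroid.

## Transition kinetics

Class series are smoothed with a 10-frame rolling modal filter, centred
with the shorter side trailing (window [t−5, t+4]) and truncated at series
ends — padding would invent labels. Modal ties break by the fixed priority
scout < loner < swarm; determinism matters more than the (arbitrary)
direction of the break. An event is any frame where the smoothed label
changes; transition probabilities are row-normalized over change events
(diagonal excluded), matching the between-class arrows of a state diagram,
with a dwell-including per-frame variant by flag. Rows without events are
flagged rather than normalized. The triangle embedding maps classes to the
corners of a unit equilateral triangle (scout, loner, swarm
counterclockwise, scout at the origin) plus isotropic Gaussian jitter
(default sd 0.05 side lengths) — geometry and jitter are presentation
choices fixed for reproducibility.

## Trails and similarity

Trajectories are rasterized with 8-connected discrete line segments
(Bresenham); each touched pixel accumulates the frame time of the segment's
start, and aggregation by mean makes the map independent of track input
order. Cells change class mid-track, so the scout-versus-rest split is
framewise: a track contributes each contiguous run of frames to the map of
the class it holds during that run. The similarity map is SSIM between the
two binarized occupancy maps over a 3-px uniform window with the standard
stabilizing constants C1 = (0.01 L)², C2 = (0.03 L)², L = 1. Shared-trail
segments are connected components of the map thresholded at 0.5
(configurable), restricted to pixels that actually carry trail so that
empty background — trivially similar — does not count; each component's
pixel area is reported. Area, not skeleton length, is the reported size of
a shared portion. The full-scale trail grid is 5880 × 5880; synthetic
scenes use a grid equal to their field size so that the analysis scales
down proportionally.

## Prey consumption

Each frame is divided by the excitation profile — supplied, or fitted as a
centred 2D Gaussian (amplitude and sigma free) to the temporal median
image. The field is then split into three equal bands along the invasion
axis (remainder rows go to the unused middle band): the invaded band is the
predation zone, the far band the safe zone. Per-band mean intensities are
normalized to their first frame. Since bleaching multiplies every zone by
the same exp(−b·t), the predation/safe ratio cancels it exactly on
noiseless data; the corrected series is fitted with a·exp(−t/τ) and τ is
the decay time. "Decay time" has no canonical operational definition in
this setting; the exponential time constant is the package's choice, with a
half-life estimator (first crossing of 0.5, linearly interpolated) by flag.
A fit whose total predicted decay over the observed series is below 2% is
flagged non-decaying instead of reporting an effectively infinite τ. Note
the temporal-median profile fit degrades once lysis darkens a large part of
the field; fitting on an early frame, or passing the known profile, is
preferred when available.

## Acquisition-side preprocessing

Offset estimation evaluates normalized (Pearson) cross-correlation of the
overlapping regions at every integer shift within the search window and
returns the argmax, with the convention that the result is the displacement
of the second image relative to the first; constant inputs or a peak below
0.3 are flagged low-confidence. Focus selection splits the image into a
4 × 4 ROI grid (edge-padded when not divisible), scores each plane per ROI
by the variance of its high-pass residual (Gaussian sigma 2), takes the
lowest-index plane on ties, and restitches. Spot detection band-passes each
plane with a difference of Gaussians (sigmas 1 and 5 px), locally
normalizes over a 32-px window, sums the four central z-planes, finds local
maxima above threshold and refines positions by intensity-weighted centroid
in a 5 × 5 neighbourhood. The detection threshold (default 10) was
calibrated on synthetic data only: pure-noise stacks yield no detection in
well over 95% of trials while injected spots at SNR 10 are found within
1 px.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, a deliberate
scaling-down of the study geometry: ensembles of 500 trajectories of
100–200 steps for the motion-regime checks; scenes of 200–640 px and 12–40
frames with 8–20 cells for tracking, classification and trail analyses; and
90 × 60 px, 80-frame stacks for the prey-decay recovery. The analytic
boundary values (class thresholds, motile cutoff) are scale-free and exact
at any size.

## Known limitations

- Track fragmentation in dense swarms is expected: occlusion is resolved by
  z-order and fused masks cut tracks by design.
- Synthetic loners are placed anywhere, so their Voronoi areas need not be
  small; class recovery on synthetic scenes is qualitative unless the scene
  density is chosen to match the class thresholds.
- The Voronoi mirror-closure assumes a rectangular field.
- The SSIM of two *sparse* binary maps is near zero on empty background;
  shared-trail extraction therefore restricts to trail-carrying pixels.
- No gap closing, division handling, or 3D support anywhere in the chain.
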