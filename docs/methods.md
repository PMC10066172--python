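# Methods

This note documents the models, rules and numerical choices behind
`centerfind`, and what the synthetic validation does and does not show.

## Coordinate convention and arena construction

All analysis happens in a canonical frame: centimetres, cool spot at the
origin, x right, y up. The four arenas are built from their printed
dimensions:

* circle ⌀30 cm → radius 15, area π·15² = 706.86 cm²;
* square, 27 cm edge → 729 cm²;
* equilateral triangle, 40 cm edge → (√3/4)·40² = 692.82 cm²;
* asymmetric quadrilateral, edges a–d = 37, 24, 23, 26 cm with interior
  angles 67°, 80°, 100°, 113°.

The quadrilateral's angle-to-vertex assignment is not given explicitly by
the printed dimensions; we walk the edges in printed order with the
printed interior angles at successive vertices, starting with 67° at the
vertex joining edges d and a. This choice closes the polygon to within
0.44 cm (tolerance 1 cm — printed values are rounded to whole cm and
degrees) and yields a shoelace area of 709.06 cm², i.e. exactly the common
design area, which validates the assignment. All four areas fall inside
the 709 ± 3% design band and construction fails loudly otherwise.

The cool spot is a closed disc of radius 3.0 cm (⌀60 mm cooling block) at
the center of symmetry, or — for the quadrilateral — at the **area
centroid** (the shoelace-weighted centroid). "Intersection of the medians"
is ambiguous for quadrilaterals; the vertex average is also computed (the
two differ by ≈0.9 cm here) but the area centroid is the default because
it is the center of mass of the floor, the natural target of a
geometry-based search. Containment is **closed** (boundary points count as
inside): insects touch the walls constantly.

Point-to-perimeter distance is an unsigned magnitude (valid inside and
outside), computed in closed form for the circle and by vectorised
point-to-segment projection for polygons; tests check it against shapely
and against dense boundary sampling (10⁴ points per edge) to 10⁻³ cm.

## Calibration

Trackers report pixels and label the four arena landmarks (corners, or
the four ends of two perpendicular diameters for the circle) in arbitrary
order. We fit a proper similarity transform (scale, rotation,
translation) by closed-form complex least squares, trying all cyclic
orders and both orientations of the landmark sequence and keeping the
minimum-RMS fit. Duplicated or collinear landmarks raise a degenerate-
input error; an RMS residual above 1 cm (configurable) fails calibration.
For rotationally symmetric arenas the orientation is inherently
unidentifiable — any symmetry rotation fits equally well — which is
harmless because every downstream quantity (spot distance, wall distance,
speed) is invariant under the arena's symmetry group.

## Trial metrics

* **On-spot**: animal center within the closed 3 cm disc.
* **Stay**: an on-spot bout of ≥ 5 s. Each frame credits one frame
  interval, so 150 frames at 30 fps is exactly 5.0 s. Off-spot
  interruptions ≤ 0.2 s are bridged before thresholding: tracker jitter at
  the spot edge should not split a bout. The bridging gap is configurable
  and logged; 0.2 s ≈ 6 frames is comfortably above single-frame jitter
  and well below a genuine departure.
* **Latency**: time of the first on-spot frame; if the spot is never
  reached the trial duration (300 s) is recorded with a censoring flag.
  The slope analysis uses censored values as-is at the censoring value.
* **Movement characteristics**: path length (sum of segment lengths), time
  in rest (speed < 0.5 cm/s by central differences on the time stamps) and
  wall-following time (within 2 cm of the perimeter, about one body
  width). Neither threshold is printed in the source experiments; both
  are config keys with these defaults.
* **Occupancy maps**: pooled 1 cm histograms normalised to sum 1, with
  out-of-arena cells masked.

Duration thresholds are always converted to frames with the recording's
median frame interval, never the nominal fps.

## Approach paths and featurization

For each successful stay the window `[start − 3 s, start)` is isolated;
it ends exactly at the stay's first on-spot frame. Windows truncated by
the trial start are dropped, not padded — padding would fabricate data
that DTW would then happily align. Windows with > 95% of frames already
on-spot are excluded as spot-edge jitter, using the same on-spot
predicate as bout detection. Multiple stays in one trial yield
independent windows.

Each window becomes a 1-D series of per-frame minimum wall distances,
min–max scaled to [0, 1] **per series** (each path carries its own
extrema; a config switch enables global scaling for sensitivity
analysis). A constant raw series maps to all zeros — "pinned at its own
minimum" — avoiding division by zero.

## DTW and clustering

DTW is the classic dynamic program over monotone warping paths with
absolute-difference local cost. Both common symmetric step patterns are
implemented (symmetric1; symmetric2 with double-weighted diagonal —
the default, mirroring the usual default of partitional time-series
clustering packages), plus an optional Sakoe–Chiba band and path-length
normalisation. Series are compared at native length; no resampling. The
kernel is verified against exhaustive warping-path enumeration for short
series.

Clustering is PAM on the precomputed distance matrix: greedy BUILD
initialisation (deterministic, reproducible) followed by steepest-descent
SWAP; exact cost ties break toward the lowest index. Nothing assumes the
triangle inequality, which DTW violates. Cluster labels are canonicalised
by descending cluster size; medoids are reported as representative
trajectories. Validity indices: mean silhouette in distance-matrix form
(0/0 → 0 convention, singletons score 0; cross-checked against
scikit-learn) and a within/between mean-cost ratio, scanned over k = 2…8
to support the choice k = 4.

## Learning statistics

The time-on-spot proportion is √-transformed and the latency
log-transformed (offset +1 s, configurable; censored 300 s values enter
as-is) to normalise their skewed distributions. The learning slope per
arena is estimated in two stages: OLS of the transformed response on
trial number per animal, then the mean of per-animal slopes with
se = sd/√n and a t-quantile 95% CI, optionally complemented by a
percentile bootstrap over animals (2000 resamples). This two-stage
estimator deliberately replaces a random-intercept-and-slope mixed model:
it targets the same estimand (the mean per-trial change on the
transformed scale), is fully specifiable, and is testable against
simulation; numerical identity with mixed-model coefficients is not
claimed. With a balanced design and ≥ 3 usable trials per animal the
two approaches estimate the same population slope.

Mann–Whitney U uses midranks; the p value is exact by enumeration of all
rank assignments when n₁+n₂ ≤ 12 with no ties, otherwise a normal
approximation with tie and continuity corrections (two-sided throughout).
Bonferroni adjustment is min(1, m·p) with m defaulting to the family
size. The 2×2 chi-square is the uncorrected Pearson closed form
N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with an optional Yates correction; the
looming-response control table [[13, 2], [5, 10]] gives χ² = 8.89,
p = 0.003.

## Synthetic sessions

The generator's purpose is ground truth: every trial realises a known
plan, so the pipeline's estimates can be compared with what was put in.

Movement is parameterised radially from the cool spot: p = r·(cos θ,
sin θ) with r = ρ(θ) − w, where ρ(θ) is the boundary distance along θ
(all four arenas are convex, hence star-shaped from the spot) and w a
target wall-distance profile. Heading and wall-distance noise are AR(1)
(discrete Ornstein–Uhlenbeck) processes — the minimal
correlated-random-walk structure. Containment is enforced by clamping r
inside [0, ρ], the radial analogue of a reflective boundary.

The four approach archetypes are defined by their normalised
wall-distance profiles over the 3 s window:

* **wall_then_direct** — flat at the wall band for about half the window,
  then a committed straight run to the spot;
* **spiral_inward** — a gradual concave approach with superimposed
  advance–retreat oscillation (hesitant intermittent locomotion);
* **arch_ventures** — an arch out to mid-arena and back to the wall,
  then a final run in;
* **center_out_return** — starts on the spot, ventures out, returns.

A note on identifiability: DTW on min–max-scaled series is invariant to
time warping, so two *monotone* profiles (e.g. a pure flat-then-rise and
a pure smooth rise) are nearly indistinguishable regardless of their
timing. The gradual strategy's advance–retreat oscillation is therefore
its load-bearing signature; it is also behaviorally the honest one —
gradual approaches in open-field insects are hesitant, not monotone. The
archetype parameters (oscillation amplitude 0.22 of the scaled range,
arch height 0.5, excursion depth 0.8) were chosen so that the four
strategies are genuinely separable under DTW at the default "high"
separation, which is the benchmark's purpose. A `separation` level blends
every archetype profile toward a common linear ramp: "high" (1.0) keeps
them distinct, "zero" (0.0) collapses all four to identical parameters,
giving the null benchmark on which the adjusted Rand index should be ≈ 0.

Sessions follow the experimental design: 15 animals × 10 trials of 300 s
at 30 fps per arena shape. Learning is linear on the analysis scales —
√(proportion) gains 0.026 per trial from a 0.15 start; log(latency+1)
falls 0.185 per trial from e^5 ≈ 148 s — with animal-level intercept
variation (sd 0.04 / 0.25) and trial-level noise (sd 0.05 / 0.30). The
slope magnitudes are realistic settings for a well-learning circular
condition, not truth claims about any particular dataset. Latency and
on-spot time are scheduled in exact frame counts (exploration avoids the
spot, the approach window's last frame is the first on-spot frame, stay
bouts and excursions fill the remainder), so realised metrics match the
plan to within one frame and slope-recovery simulations measure the
estimator, not the generator. The first approach of a trial draws one of
the three outside-in archetypes (weights 0.45/0.25/0.12 — the
wall-then-direct strategy dominates, as observed in this paradigm);
later approaches arise from center-out-and-return excursions and are
labeled accordingly.

What the generator does **not** emulate: biomechanics (speed profiles
are kinematically plausible but not cricket-calibrated), thermal-gradient
taxis, tracker noise and dropouts (tested separately via the I/O layer),
inter-individual strategy preferences, and arena-rotation controls.
Passing tests therefore show that the pipeline recovers what it claims
to measure from data with the assumed structure — not that real crickets
behave like the generator.

## Problem sizes and numerical choices

The cluster-recovery benchmark uses 40 paths per archetype (160 series,
~12,700 DTW pairs of 90-frame series; the DP kernel is numba-compiled).
Slope recovery uses 100 replicate sessions of 15 × 10 trials, rendered
and measured in full. Polygon-distance validation uses 1000 random
points per shape against 10⁴ boundary samples per edge. DTW validation
enumerates all warping paths for 200 random pairs of length ≤ 6 per step
pattern.

Floating-point conventions: min–max scaling guards the constant case at
10⁻³⁰⁰; PAM swap acceptance requires an improvement > 10⁻¹²; distance
matrices are validated symmetric to 10⁻⁹ with zero diagonal to 10⁻¹²;
silhouette uses the 0/0 → 0 convention. Known limitations: exact
mixed-model coefficients, printed cluster sizes and approach totals of
any specific real dataset are out of reach without that dataset (and the
unprinted DTW/clustering settings used on it); the pipeline instead
reproduces the full report *structure* and validates every stage against
oracles and ground truth.
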