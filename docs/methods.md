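# Methods

This note documents the models, conventions and numerical choices behind
`palmleaf`, and what the synthetic validation does and does not show
about real photographic data.

## The estimation problem

A cassava plant carries up to several hundred palmate leaves (3–7
lanceolate lobes radiating from the petiole attachment). The quantity of
interest is the plant's total one-sided leaf area. Exhaustive
measurement — leaf-area meter or per-leaf photography — is accurate but
slow; the package implements two layers of approximation on top of it
and quantifies what each costs.

### Cluster-based sampling (the scoring board)

Leaves are binned by the smallest board square that contains their
length × width footprint. The board has grid lines at 3.5, 4.5, …, 15.5
inches (`BoardSpec`; inches appear nowhere else — all data files are in
cm, converted at 2.54 cm/in). Binning rounds each dimension *up* to the
nearest grid line; a value exactly on a line belongs to that line's cell
(closed upper bound, with a 1e-9 in tolerance absorbing the cm→inch
float round trip). Leaves below the smallest square clamp to it; leaves
beyond the largest fall in an explicit overflow cell, since field leaves
can outgrow any printed board.

Per cluster, `k` representatives (default 2) are drawn uniformly without
replacement from a seeded generator, and the cluster's representative
area `LA_rep` is the arithmetic mean of their areas — measured areas in
"photo" mode, allometric predictions in "hybrid" mode. The plant total
is Σ (LA_rep · LN) over clusters. Two properties anchor the tests:

- **Identity limit.** With singleton clusters the estimator equals the
  exact sum of leaf areas to machine precision.
- **Unbiasedness and refinement.** Uniform sampling makes the estimator
  unbiased for any board: E[mean of a k-sample] is the cluster mean, so
  the expected total is the exact sum at *every* grid step. Refining the
  grid therefore does not move the estimate's centre; it shrinks its
  spread, because clusters become more homogeneous in area. The
  refinement check is accordingly formulated on the estimator's expected
  absolute error (mean |error| over 30 representative draws per
  population): a single random draw's realized error is not monotone in
  the step size almost surely, and asserting that would test luck, not
  the estimator.

### Through-origin allometry

Candidate predictors x ∈ {L, W, L+W, L·W, L/W} are screened by a Pearson
correlation t-test at α = 0.01 (screening is advisory: excluded
predictors are logged and can be forced). Each surviving predictor is
fitted as LA = a·x with the closed-form least-squares slope
a = Σxᵢ·LAᵢ / Σxᵢ²; a numeric SSE minimiser serves as an independent
oracle in the tests (agreement to 1e-6 relative on 1000 random
instances).

Reported diagnostics: RMSE with denominator n (not n−p), and R² defined
as the squared Pearson correlation between fitted and observed values.
The centred R² of a no-intercept fit can leave [0, 1] and is not
comparable across predictors; the squared-correlation form is bounded
and comparable, and the uncentred 1 − SSE/Σla² variant is available via
`r2_method="uncentered"`. Model selection ranks by R² descending, then
RMSE ascending, then predictor simplicity in the order L, W, L+W, L·W —
deterministic under exact ties.

Published cassava slopes ship as a registry (`BUILTIN_MODELS`): 11.58·L,
8.54·W, 4.92·(L+W) and the recommended 0.42·L·W, with their reported
diagnostics carried as metadata (metadata only — the raw 111-leaf
dataset behind them is not published, so those numbers are not
recomputable and are never asserted).

## Image measurement

Assumptions inherited from the photographic protocol: one detached leaf
per image, flattened on a white chart, photographed perpendicularly,
with either a known pixels-per-cm scale or a dark square fiducial of
known side in a corner.

- **Segmentation.** Otsu's threshold on luminance (leaf darker than
  background; fixed-threshold override available), 8-connected
  components (4-connectivity severs lobe tips thinner than √2 px),
  removal of components touching a border band of 2% of the smaller
  image side (rulers, chart edges, fiducials), hole filling (specular
  spots, insect damage), then the largest remaining component. An image
  with no contrast or no component of ≥ 64 px raises "no leaf found".
- **Area.** Foreground pixel count / ppcm². Pixel-centre rasterisation
  makes this converge to the true polygon area; at 20 px/cm the error on
  leaf-sized shapes is well under 1%.
- **Descriptors, `axis-extent` (default).** Extents of the silhouette
  along and across the principal axis of its second-moment ellipse, plus
  one pixel for the pixel footprint. Deterministic and
  rotation-invariant; appropriate for clearly elongated shapes.
- **Descriptors, `tip-based`.** Lobe apices are local maxima of the
  contour's radial distance from the centroid (profile smoothed
  circularly; peaks kept above 20% radial-range prominence — genuine
  apices sit at ≥ 40%, bumps near the petiole base at ≤ 15% — and snapped
  to the raw maximum). Because a tapering lobe becomes thinner than one
  pixel before its true apex, each detected apex is extended by
  extrapolating the lobe's half-width profile (1-px bins) linearly to
  zero width, capped at 8 px. From the apex set, L is the maximum Feret
  diameter (largest apex-to-apex distance) and W the minimum Feret
  width.
- **Scale calibration.** In the chosen corner region, the largest dark
  component that is square-like (bounding-box aspect within 4:3, fill
  ratio ≥ 0.8) gives ppcm = √(pixel area) / side_cm.

### Why Feret spans for the tip descriptors

The field convention measures L between the central-leaflet apex and the
southernmost-leaflet apex, and W between the farthest lateral apices —
definitions that depend on how the leaf is oriented under a human's
ruler and cannot be reproduced exactly by any automatic method. Two
natural mechanical translations fail quantitatively for this leaf
family: spans along the second-moment principal axis are ill-conditioned
when the silhouette is nearly isotropic (L ≈ W is common in cassava),
and letting the longest apex pair define the axis flips discretely
between the two near-equal diagonals of a symmetric leaf, jumping W by
~10%. The maximum Feret diameter and minimum Feret width are continuous
functions of the apex coordinates, agree with the intuitive spans for
elongated leaves, and are applied identically to the generator's exact
tips and to the raster-detected tips, so the validation isolates raster
measurement fidelity. Across 300 default-architecture leaves at
20 px/cm the worst L error is 3.2% and the worst W error 2.5%.

## Synthetic leaves

`generate_leaf` builds each lobe as a lanceolate outline with half-width
w(t) = ½·lobe_width_ratio·l·sin(πt)^shape_exponent along its axis
(exponent 0 is the rectangle limit used by degenerate tests), unions the
lobes with a small attachment pad (radius 5% of the central-lobe length;
without it, zero-width lobe bases would touch only at a point and the
union would not be a simple polygon), and records the exact polygon,
its shoelace area, the analytic apex coordinates and the Feret L/W.
Defaults — 5 lobes, 200° angular spread, width ratio 0.25, exponent 1.5,
basal lobes tapering to 0.55 of the central length — were chosen once to
resemble cassava leaf silhouettes; optional seeded jitter on lobe angles
(σ = 3°) and lengths (σ = 5%) emulates biological asymmetry.

`render_leaf` rasterises by pixel-centre point-in-polygon testing, with
an irrational sub-pixel registration phase so that axis-aligned polygon
edges never coincide exactly with pixel centres (where inclusion would
be numerically arbitrary). `generate_population` samples descriptor
records in the published cassava envelope (L 6.28–29.26 cm,
W 5.00–40.58 cm): L uniform, W = 1.28·L·(1+η) with η ~ N(0, 0.15)
clipped to the envelope — the source data publish only marginal ranges,
so the joint distribution is a modelling choice — and
LA = a·L·W·(1+ε), ε ~ N(0, noise_sd), default a = 0.42 and 5% noise.
`generate_plant_truths` varies only overall leaf size within a shared
lobe architecture, making true area exactly proportional to L·W — the
noiseless limit in which the hybrid pipeline can be audited end to end.

What passing these tests shows: the geometry, sampling and fitting
machinery are correct, and rasterisation/segmentation losses are within
the stated tolerances at ≥ 20 px/cm. What they do not show: robustness
to shadows, uneven illumination, petioles left attached, perspective
distortion, or overlapping leaves — none of which the generator
emulates; the segmentation assumes the white-chart protocol.

## Evaluation metrics

For an estimate M_o against a benchmark M_b over n plants:
RMSE = √(Σ(M_o−M_b)²/n), MAE = Σ|M_o−M_b|/n, MRE = Σ(|M_o−M_b|/M_b)/n.
The benchmark is always the second argument and supplies the MRE
denominator. Reports round to 2 decimals (4 for r) for display and keep
full precision internally. When the two vectors are identical, r is
flagged undefined rather than reported as 1.0. The bundled per-plant
totals of the nine field plants (image-based vs meter-based, with and
without clustering) and six greenhouse plants (hybrid vs image-based)
reproduce every published comparison metric at printed precision when
run through `evaluate_methods`; these totals are treated as given
unit-free numbers.

## Problem sizes and determinism

Simulation-backed checks use: n = 111 leaves per population (matching
the reference fit) with 100 seeded replicates for slope and
model-selection recovery; 50 rendered leaves at 20 px/cm for measurement
fidelity; 20 populations × 3 grid steps × 30 representative draws for
the refinement property; and a 50-leaf noiseless plant for the
end-to-end audit. All randomness flows through explicit
`numpy.random.default_rng` seeds — there is no hidden global state — and
every CLI run logs its configuration hash and seed, so outputs are
byte-reproducible.

## Known limitations

- The 0.42·L·W registry slope is specific to cassava-like lanceolate
  palmate leaves; other morphologies need refitting.
- The automatic descriptors approximate, but cannot replicate, manual
  apex-to-apex measurements; agreement is tolerance-level by design.
- Scale calibration expects an isolated, square fiducial; ruler-based
  scales must be converted to an explicit `--ppcm` by the user.
- One leaf per image; multi-leaf scenes are out of scope.
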