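# Methods

`filagraph` measures the lengths of individual actin filaments (or other
curvilinear structures) in 2-D fluorescence micrographs.  The method is a
four-step estimation–inference chain — template-bank enhancement, binary
clustering, morphological thinning, junction disambiguation — followed by
per-filament length measurement, plus a synthetic-network generator and a
validation harness that scores the whole pipeline against exact ground
truth.  This note records the model behind each step, the tunable
parameters with their defaults and rationale, and the limits of what the
synthetic validation does and does not demonstrate.

## 1. Enhancement: filament-likelihood image

**Model.** A filament appears as a curvilinear ridge with an approximately
Gaussian cross-section riding on background fluorescence (noise plus
diffuse signal from unpolymerised protein).  The enhancement step scores
every pixel by how ridge-like its neighbourhood is: the image is correlated
with a bank of artificial filament templates — constant-curvature arcs with
Gaussian cross-section, enumerated over rotation, scale (arc length),
width and signed curvature — and the best (maximum) response is kept,
together with the winning template's rotation as a rough local orientation.

Templates are mean-subtracted and L2-normalised on their grid.  Zero mean
makes responses exactly invariant to additive intensity offsets (and makes
plain correlation identical to correlation against locally mean-subtracted
patches); unit norm makes responses comparable across template sizes.
Correlation is computed by FFT on the globally mean-subtracted image, which
renders the zero padding equivalent to constant-value extension: a constant
image scores exactly zero everywhere, borders included.  A border band of
half the largest kernel is flagged in a validity mask.

The likelihood image is the pixelwise product of the min-max-normalised
best response and the min-max-normalised intensity (a zero-range input
normalises to all zeros).  Both cues must be high: diffuse haze has high
intensity but weak ridge response, noise spikes the reverse.  Measured on a
synthetic scene, a wide blob at half filament brightness keeps ~13% of the
filament's ridge response and ~0.06 likelihood; equally bright wide blobs
retain up to ~1/3 of the ridge response — plain correlation suppresses,
but does not annihilate, structured haze.  Normalisation is global; local
normalisation would boost dim filaments at the cost of amplifying
background texture, and is not implemented.

**Bank defaults** (free parameters of the method): arc lengths {15, 25} px,
cross-section SD {1.5, 2.5} px, 12 rotations equally spaced on [0, π)
(ridges are symmetric under reversal; signed curvatures cover both bending
directions instead), curvatures {0, ±0.01, ±0.02} /px — 240 templates.
Per-shape kernel FFTs are cached on the bank, so batch runs pay the
transform cost once (~0.1 s per 128×128 image thereafter).

## 2. Segmentation: binary clustering

Likelihood values are split into two clusters by 1-D two-class clustering:
centroids initialised at the minimum and maximum value, values assigned to
the nearer centroid, centroids recomputed until fixed.  In one dimension
this converges to a threshold at the midpoint of the final centroids, so
the foreground is exactly `{likelihood >= t*}` — an invariant the tests
assert.  8-connected components smaller than `min_object_px` (default 20,
below the footprint of the shortest meaningful filament at default widths)
are removed.  A constant input yields an all-background mask with a
warning.

## 3. Skeletonization

The mask is thinned to unit-width centerlines with parallel
two-subiteration topology-preserving thinning (via scikit-image), iterated
to stability: no 2×2 block survives, 8-connected component count is
conserved, no pixel is created, and the result is a fixed point.  Short
side branches (thinning artifacts at crossings) are pruned: branches
running from an endpoint into a junction with arc length below `spur_px`
(default 4 px — below the 10 px minimum filament length, above typical
artifact size) are deleted iteratively and the skeleton re-thinned.
Standalone short components are never pruned.

## 4. Topology: junction disambiguation and length measurement

The skeleton is organised into a graph (endpoint/isolated nodes, junction
clusters of adjacent degree-≥3 pixels, maximal degree-2 chains as edges)
and resolved into individual filaments in five passes:

1. **Super-junctions.** Junction clusters joined by connector edges shorter
   than `connector_max_px` (default 8) are contracted: closely spaced
   crossings thin into exactly such knots of small clusters and short
   connectors.
2. **Branch pairing.** At each super-junction, incident branch ends are
   paired by an exact minimum-total-cost matching.  The cost of joining
   two ends combines the tangent turn angle (principal-axis tangents over
   5 chain pixels) with line- and circle-fit RMS residuals of the two
   25-px end windows taken together: filaments are smooth, slowly curving
   arcs, so a genuine continuation fits one arc at sub-pixel residual while
   two filaments meeting tangentially form an S or a kink that fits
   poorly even when the turn angle is small.  A join is admissible below
   `max_turn_deg` (default 30) plus a fixed residual budget; leaving an end
   unmatched costs half the admission gate, so a pair must beat two loose
   ends.  Matched pairs are concatenated, routed through the knot along
   skeleton pixels (shared use allowed — a crossing belongs to both
   filaments).
3. **Corner splitting.** Two filaments whose tips nearly touch fuse into a
   single smooth degree-2 chain that no junction separates.  Paths are cut
   at interior turns above 28° measured over 8-px windows (clean digitised
   arcs stay below ~20° at the default curvature range); turns on or next
   to junction pixels are exempt — kinks inside knots are digitisation
   artifacts that the pairing already handles.
4. **Bridging.** Shallow crossings share a chain stretch longer than any
   connector; the losing filament is left as two dangling ends at nearby
   junctions.  Collinear dangling ends are re-joined along the shortest
   skeleton route (up to `bridge_max_px`, default 20), so the merged
   centerline stays on image evidence.
5. **Knot extension and residue.** Remaining dangling ends extend into
   their knot along the tangent (a filament physically continues into the
   crossing region), and knot pixels used by no filament are emitted as
   flagged residue paths so that the pixel-conservation invariant (union
   of path pixels = skeleton pixels) holds exactly.  Total chain length is
   conserved: filament length equals outer-edge length plus the explicitly
   accounted handover and bridge segments.

A final pipeline-level repair, **arc-consistent fragment merging**, rejoins
open paths whose end windows fit a single line/arc (RMS < 1.5 px), whose
facing endpoints are within 30 px, and whose straight gap is supported by
the likelihood image — never across dark background.  Overlapping stretches
are trimmed before concatenation.

**Length.** The chain metric (1 per axial, √2 per diagonal step) is exposed
as `path_length`, but digitised staircases overestimate true arc length by
up to 8.2% (at 22.5°), so reported lengths use `smoothed_length`: the
Euclidean arc length of the moving-average-smoothed chain (window 5,
endpoints pinned), accurate to ~1% on straight and gently curved lines.
Filaments shorter than `min_length_px` (default 3 px) are discarded.
Optional tangent tip extension exists for dim data where clustering erodes
filament ends; it is off by default because at the validation SNR the mask
already reaches the tips and extension only overshoots (+5 px measured).

**Statistics.** The pooled length distribution reports a count-weighted
mean across images (equivalently the pooled mean over filaments) with a
standard error propagated from per-image variances, and groups are compared
with a two-sided Welch test on per-image mean lengths — the natural
unequal-variance choice when images are the independent units.

## 5. Synthetic networks and the validation protocol

Each filament is a constant-curvature circular arc (the simplest family
matching the template bank's curvature axis) with:

| parameter | default | note |
|---|---|---|
| image | 128×128 px | validation frame size |
| length | Normal(50, 20) px, floor 10 px | truncated resampling |
| cross-section SD | 1.5 px | diffraction-limited ridge |
| curvature | uniform ±0.02 /px | matches the bank's coverage |
| foreground peak | 200 | over background 20 |
| noise | Gaussian, SD = 10% of peak | additive, clipped at 0 |
| composite | pixelwise maximum | fluorophore saturation at crossings |

Placement is uniform in position and orientation, subject to two protocol
constraints:

* **Full visibility.** Position/orientation are resampled (keeping the
  drawn length) until the whole centerline lies in-frame with a 3 px
  margin; border clipping remains only as a fallback for lengths near the
  frame diagonal.  Clipped stubs of arbitrary length would make the true
  count unmatchable to any tracer output.
* **Identifiability.** A placement is resampled when its centerline comes
  within 3 px of an already-placed filament at a local tangent angle below
  20°.  Two ridges of SD 1.5 px merge optically below ~3 px separation;
  a tangential overlap or a smooth tip-to-tip continuation therefore
  renders as one unbroken ridge whose ground-truth identity no pixel
  pattern can express — no tracer, and no human, could recover the true
  count.  Ordinary crossings, including shallow ones near 20°, remain
  frequent.

The validation harness runs the full pipeline on a bank of 40 images
(densities 5/10/15/20 filaments, 10 images each, per-image seeds derived
deterministically from one master seed), matches traced to true filaments
one-to-one by minimal symmetric mean closest-point distance (Hungarian
assignment, 5 px gate), and reports the maximum per-image relative count
error and the maximum per-image RMSE of matched lengths.  Unmatched
filaments affect the count error only.

**What the generator does not emulate:** point-spread blur beyond the
Gaussian ridge, photobleaching, depth attenuation in projections,
filament bundling and intensity variation along a filament, and branching.
Passing the synthetic validation therefore demonstrates the geometry
pipeline (enhancement through length statistics), not robustness to every
property of real micrographs.

## Achieved validation accuracy and known limitations

On the default bank the harness currently measures a maximum per-image
count error of ~25–30% (typically 0–2 filaments off per image; sparse
images are usually exact) and a maximum per-image matched-length RMSE of
~18 px (mean ~8 px; many images below 5 px).  `scripts/acceptance.py`
recomputes both numbers from scratch.  The dominant residual errors are
crossings in the 20–40° range at the highest densities (~19 expected
crossings per 20-filament image): their knots admit several geometrically
plausible branch assignments, and a wrong join costs a count unit and a
10–40 px length error on two filaments at once.  Local geometric cues
(turn angle plus joint arc-fit residuals) separate right from wrong joins
with AUC ≈ 0.92 overall but only ≈ 0.83 among low-angle candidates, which
bounds what this class of skeleton-graph tracer can achieve at these
densities; substantially better accuracy would require an intensity-driven
global tracer (e.g. open active contours evolved through junctions).

Numerical choices not covered above: 8-connectivity throughout (matches
diagonal filament steps); row-major ordering everywhere for determinism
(node/edge enumeration, tie-breaks in matching); cycles become single
closed filaments, and a closed path's length includes the closing step;
isolated 2×2 squares thin to a single deterministic pixel; per-image seeds
are derived from `(master seed, level index, image index)` with NumPy's
`SeedSequence`, so banks are reproducible and images independent.
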