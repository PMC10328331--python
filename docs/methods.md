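# Methods

## Input model and physical scaling

The pipeline analyzes one worm head per frame: a 2-D maximum-intensity
projection (8- or 16-bit grayscale) of the four GFP-tagged CEP neurons,
plus the camera pixel size in µm/px. Multi-page inputs are max-projected
internally (per-pixel maximum; idempotent). RGB input is rejected rather
than converted: which channel carries the reporter is a scientific
decision that must be made upstream.

Every length-like parameter is stored in µm in `AnalysisConfig` and
converted to pixels at its point of use through `PixelScale`
(`effective = microns_per_pixel / resize_factor`). This is the mechanism
behind cross-setup portability: the same configuration analyzes 0.1 and
0.2 µm/px acquisitions, and the test suite holds feature counts identical
and lengths within 5% across those scales.

## Cropping to a dendrites-only region

* Global contrast stretch between the 0.5th and 99.9th percentiles. The
  upper clip protects the soma threshold from isolated hot pixels; the
  stretch guarantees the brightest structures saturate the range.
* Soma segmentation thresholds at 0.7× the dynamic range (after the
  stretch the somas, the brightest biological mass, sit near full range;
  a percentile-of-all-pixels rule was rejected because the background
  fraction changes whenever rotation pads the canvas). Components smaller
  than 4 µm² are discarded; components more than 10× longer than wide
  are discarded as well, so a somas-missing frame fails with "no cell
  body found" instead of mistaking saturated dendrites for somas.
* Multi-worm guard: surviving components are grouped by single-linkage
  clustering of centroids cut at 25 µm; more than one group raises a
  "multiple worms in frame" error (one worm per frame is a documented
  precondition of the method).
* Orientation: the line fitted through soma centroids (principal axis of
  the merged cluster when fewer than three centroids survive) is rotated
  to horizontal. The angle is only defined modulo 180°; whether the
  dendrites end up above or below is resolved by side selection.
* Split and select: the frame is cut at the soma bounding box (plus a
  0.5 µm clearance) and each half is binarized with Otsu. A half scores
  by its count of components with major axis ≥ 10 µm, orientation within
  30° of vertical, and circularity (4πA/P², clipped to [0, 1.05]) ≤ 0.5;
  ties break on summed major-axis length. The losing half is discarded
  and the winner flipped if needed so the proximal edge is the bottom
  edge — the canonical orientation every downstream "distance from the
  cell body" computation assumes.
* Cleanup: components touching the lateral borders, and any component
  both more circular than 0.7 and larger than 8 µm² (a residual soma),
  are removed; the crop tightens to the remaining mask plus a 2 µm
  margin. The soma-area cutoff sits above the largest expected bleb
  (~5 µm² at 2.5 µm diameter) and below a 4 µm soma (~12.6 µm²).

## Feature (bleb) detection

CLAHE local contrast is applied with a clip limit scaled down as
`base / (1 + 100·σ̂_raw)` — noisy images get gentler equalization because
aggressive local equalization amplifies background grain. Background is
removed with a white top-hat (disk radius 2 µm, applied at the native
grid where it is ~16× cheaper than after upsampling and equivalent for a
physically sized element), then the image is upsampled 4× (bicubic) so
morphological operations have sub-dendrite resolution at any camera
scale. The noise level σ̂ is the scaled median absolute deviation
(×1.4826) of below-Otsu pixels and is recorded on the enhanced image.

The global dendrite threshold is `Otsu + k·σ̂` with k = 1 — one
interpretable knob implementing "noisier images need a higher
threshold". The binary mask is eroded with a horizontal line of 1.4 µm
(~2× the nominal 0.5–1 µm dendrite width): dendrites vanish, blebs
survive. Survivors under 0.25 µm² (single-pixel debris at 4×) and
survivors touching the proximal frame edge (cell-body glow at the crop
line) are discarded.

Each seed is dilated by 0.3 µm and evolved for 60 iterations of
morphological Chan-Vese (the morphological ACWE formulation of the
Chan-Vese energy) on a window padded 3 µm around the seed. The evolved
contour readily leaks along the bright dendrite, so the region is cut
back: spans no wider than the erosion element are removed, the wide
component containing the seed is kept, and its rim is restored by a
dilation bounded inside the evolved region. Regions from different seeds
that still overlap are fused into one feature; a collapsed contour drops
its seed with a log note.

Descriptors: area, perimeter, circularity, extent (area / bounding-box
area; exactly 1 for a filled rectangle), eccentricity, and exact min/max
caliper (Feret) diameters by rotating calipers on the convex hull of the
pixel corner points. Mean intensity is sampled bilinearly from the
*original, un-enhanced* image in native camera units — enhancement is
image-adaptive and would make intensities incomparable across images.

## Dendrite tracking

Each row of the enhanced image contributes up to four intensity maxima
(`scipy.signal.find_peaks`), requiring prominence ≥ max(2σ̂, 0.02),
height above the permissive break-detection threshold (so pure
background never yields track points), and ≥ 1 µm separation. A vertical
morphological closing (5 µm, computed on a zero-padded array so runs are
neither extended past the frame nor eroded at their ends) bridges
detection dropouts; true breaks are deliberately over-bridged here
because break detection happens later against the binarized image —
tracks are supposed to span breaks. The closed mask is skeletonized and
points are binned row by row, distal to proximal, to the dendrite whose
exponential-moving-average x (weight 0.1/row) is nearest within a 2 µm
gate; duplicate claims keep the nearer point, equidistant ties go to the
lower index. Unmatched points may seed new candidates only in the distal
25% of rows; up to 8 candidates are carried and, if more than four
persist, the four with the most detected points are kept (stray noise
columns lose to real dendrites by evidence).

Finalization trims each track end back to the first contiguous run of
≥ 1 µm of detected rows (an isolated noise point cannot extend a track
past the dendrite tip, which would otherwise read as a phantom tip
break), drops tracks with under 5 µm of total evidence, interpolates
interior gaps linearly, smooths with a 2 µm moving average, and
re-indexes tracks left to right. The detected/interpolated distinction
is preserved for downstream use.

A documented consequence of the forward-only row scan: x is a function
of y, so a dendrite folding back on itself (a ≥ 90° kink) is
interpolated through rather than followed.

## Breaks, the 20-metric report, and the categorical score

Break detection probes an independent, permissive binarization of the
dendrites (0.5× the feature threshold — it answers "is there any signal
here", not "what shape is it") within ±0.5 µm of the track at every row
of its span. Maximal runs of signal-free rows ≥ 0.5 µm become break
segments; sub-0.5 µm dropouts are sensor noise at all supported pixel
sizes. Segment length is the arc length of the track across the gap, so
`total_break + remaining = length` holds exactly.

Features are matched to the laterally nearest track within 5 µm
(equidistant ties to the lower index; farther features stay unassigned
and are excluded from per-dendrite aggregates). The report carries 20
metrics: dendrite length (track arc length), remaining length, %
remaining, break count / total / largest, mean dendrite intensity
(native units, non-break rows), feature count, features per length and
per remaining length, and mean feature intensity / total and mean area /
perimeter / circularity / extent / eccentricity / min and max caliper /
normalized location. Normalized feature location runs from 0 at the
proximal (cell-body) end to 1 at the distal tip. Feature aggregates are
null-coded (NaN), not zero, when no features are present; counts stay 0.
Tracks shorter than 5 µm are flagged unreliable.

The categorical score is a total, deterministic function with breakage
precedence: % remaining < 50 → 4; 50 ≤ % ≤ 85 → 3; otherwise bleb count
0 → 0, 1–4 → 1, ≥ 5 → 2. Two boundary conventions are fixed here because
the verbal rule leaves them open: 85% exactly falls in the break branch
(score 3), and exactly 5 blebs scores 2 ("fewer than five" read as 1–4).

## Cohort statistics

Each dendrite is one observation. z-scores versus control use the
control-group SD (not pooled): z = (x̄_t − x̄_c)/s_c, so the sign encodes
effect direction relative to control; the choice of denominator is
recorded in the CLI output metadata. Zero-variance or all-null control
metrics give null-coded z with a warning. Per-metric one-way ANOVA
(`scipy.stats.f_oneway`) is followed by either all-pairwise t-tests with
Bonferroni multiplication (clipped at 1) or Dunnett's many-to-one
comparison via the multivariate-t distribution (`scipy.stats.dunnett`).
Groups with fewer than two observations are excluded with a warning.

## The phantom generator: what it emulates and what it does not

Phantoms emulate the geometry and contrast of a projected CEP image:
four soft-edged soma disks (4 µm, peak 0.9 of range) in a row at the
proximal end; four Gaussian-profile dendrites (FWHM 0.8 µm, peak 0.35,
default 40 µm long, 5 µm apart, ±1 µm cosine bow); blebs as Gaussian
blobs at 1.5× dendrite peak (blebs are conspicuously brighter than the
dendrite in real images); breaks as zeroed spans; a linear background
ramp; Poisson shot noise at a configurable photon budget plus Gaussian
read noise; frame rotation applied last; 8- or 16-bit quantization. All
randomness flows from the spec's seed — identical specs render
bit-identical images. Default frame sizes (560×320 px at 0.1 µm/px,
scaled counterparts at 0.2 µm/px) keep a full render-and-analyze cycle
at a few seconds so the whole validation suite runs in well under a
minute of phantom work; they preserve the ~40 µm dendrite field of the
real acquisitions.

Not emulated: gut autofluorescence, out-of-focus haze, overlapping or
crossing dendrites, >90° kinks, partial worms, or 3-D stacks. Passing
the phantom suite therefore demonstrates correct recovery of geometry,
counts, and scores under noise, rotation, scale, and bit-depth changes —
it does not certify performance on confounds the generator does not
produce.

## Numerical choices and degenerate inputs

* Blank frames (zero variance) and degenerate contrast windows raise
  typed errors; batch runs log and skip failing images and only fail
  outright when every image fails.
* An empty break-binarization mask means a fully lost dendrite (0%
  remaining), not an error.
* Circularity of small discrete disks can exceed 1; values are clipped
  to [0, 1.05] and never treated as probabilities.
* Caliper diameters use pixel corners, so a single pixel measures
  (1, √2) px rather than (0, 0).
* Even-sized separable filter windows can shift a morphological run end
  by one row; tolerances throughout allow one effective pixel.
* All tie-breaks (track binning, feature matching) go to the lower
  index for determinism.

## Known limitations

One worm per frame; exactly the CEP geometry (≤ 4 roughly parallel,
near-vertical dendrites after orientation); kinked dendrites are
interpolated, not followed; dendrites dimmer than half the adaptive
threshold read as broken; feature sub-types (bleb vs swelling vs
fragment) are not distinguished — every detected abnormality is a
"feature".
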