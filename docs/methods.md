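# Methods

## The counting problem

A colocalized cell is a cell co-stained for a nuclear marker and one or
two immune markers.  Because nuclear and cytoplasmic stains occupy
different subcellular compartments, the signals co-express without
overlapping in space; colocalization is therefore decided between
*objects* (detections reduced to points) rather than between pixels.  Both
engines in this package consume one grayscale channel at a time and
exchange category-tagged point sets: category 1 = nuclei, categories 2/3 =
markers; the combined categories 12 and 123 are the colocalized-cell
counts for two- and three-channel fields.

## Automated pipeline

1. **Illumination correction.**  Shading across a stitched field is
   modelled as a bivariate quadratic surface `a + bx + cy + dx² + ey² +
   fxy` least-squares fitted to all pixels over coordinates normalized to
   [0, 1] (conditioning).  Illumination is treated as multiplicative: the
   image is divided by the surface scaled to unit mean, which preserves
   the global intensity scale; a `subtract` mode removes the mean-centred
   surface instead, and `off` skips the step.  The evaluated surface is
   floored at 1e-3 x its maximum so division cannot blow up in dark
   corners; an all-zero fit falls back to the unit surface.  One model is
   fitted per image (not per batch).
2. **Segmentation.**  Global three-class Otsu thresholding: the two
   thresholds maximize the between-class variance, computed exhaustively
   over all threshold pairs of a 256-bin histogram (exact integer bins for
   8-bit data).  Ties are broken toward the lexicographically smallest
   threshold pair, making the result deterministic.  Empty classes are
   allowed (they contribute zero variance).  The middle class goes to
   background by default — the conservative choice for dim, nonspecific
   staining — and is configurable to foreground.  Components are labeled
   with 8-connectivity; an optional `[min_area, max_area]` filter
   (default off) suppresses specks and relabels 1..n.  No declumping /
   watershed splitting is performed: touching cells merge into one object,
   a known divergence risk for dense fields, partially mitigated because
   the colocalization criterion runs on centroids.
3. **Shrink and expand.**  Each object becomes its unweighted pixel-mean
   centroid (morphological center, not intensity-weighted), then a closed
   Euclidean disk of `expand_px` = 5 px.  A nucleus is colocalized with a
   marker iff the two disks share at least one in-bounds lattice pixel —
   the construction's effective centroid-distance threshold is therefore
   about 2 x expand_px, not the nominal 5 px; a `max_dist` override
   applies a literal centroid-distance rule for users who want the latter.
   For three channels, a nucleus is in category 123 iff it has a partner
   in *both* marker channels (conjunction filter).

The counting unit is the nuclear point, counted once however many partners
it has.  One marker within reach of two nuclei therefore colocalizes both:
`n_coloc` is bounded by the nuclear count but not by the marker count.

## Semi-automated method

1. **Pre-blur.**  Gaussian smoothing with sigma = `pre_blur_radius`
   pixels (0 = off), computed in floating point with reflective
   boundaries; no re-quantization before detection.
2. **Maxima detection.**  A local maximum is an equal-valued plateau with
   no strictly higher neighbor, reported once at the plateau's pixel
   centroid.  Its *prominence* is its height minus the highest saddle
   connecting it to any strictly higher region; the highest peak (and any
   peak tied with it that connects to it only through strictly lower
   ground) is measured against the image minimum.  A maximum is accepted
   iff prominence > `noise_tolerance` (strict); tolerance 0 accepts every
   local maximum, so a perfectly flat image yields one point at tolerance
   0 and none otherwise.  The computation is a single descending
   union-find flood (numba-compiled), exact, with a deterministic
   processing order (descending intensity, then row-major); results are
   sorted by descending peak intensity then position.  These plateau/tie
   conventions are stated package semantics, not a claim of
   bit-compatibility with any GUI tool's undocumented tie handling.
3. **Point editing.**  Manual correction is modelled as a reproducible
   edit list: each removal snaps to the nearest existing point within
   `snap_radius` (logged no-op otherwise); additions are bounds-checked
   and rejected as duplicates within 0.5 px.  This keeps "semi-automated"
   runs scriptable and testable.
4. **Overlay colocalization.**  Each category carries an overlay radius
   (default 50 px; 30 px is the documented choice for fragmented
   morphologies); two points are colocalized iff their Euclidean distance
   is at most the sum of their radii — evaluated exactly on coordinates,
   no rasterization.  Counting unit as above.

## Synthetic scenes

The generator emulates the two regimes the methods face, with exact ground
truth in place of manual counts:

* **Geometry.**  Default field 512 x 512 px at 0.325 um/px (the reference
  acquisition field of 25,000,000 px², i.e. 5000 x 5000, is available by
  passing `shape`).  Nuclei are Gaussian-profile disks (sigma 5 px ≈ 8 um
  nuclei), rejection-sampled with ≥ 24 px mutual separation and a 20 px
  border margin, so every truth point is at least an object radius from
  the edge.
* **Intensities** (8-bit convention before any 16-bit conversion):
  background 10, nuclei peak ~200, markers peak ~180 — chosen so additive
  Gaussian noise of SD 25 is a meaningful challenge.
* **Colocalization.**  `round(coloc_fraction x n_nuclei)` nuclei carry a
  marker displaced by at most 3 px (co-expression without spatial
  overlap, inside the 10 px automated capture range); the remaining
  `(1 - fraction)` share are decoy markers placed strictly farther than
  15 px (> 2 x expand + 5) from every nucleus, so they are verifiably
  non-colocalized under the automated criterion.  Decoys are *not*
  guaranteed to clear the much larger semi-automated overlay reach
  (r₁ + r₂ = 100 px by default) — with default radii the semi-automated
  count legitimately includes decoy-adjacent nuclei, which is what the
  overlay construction does on real tissue too.
* **Morphologies.**  `easy` markers are single round blobs; `hard`
  markers fragment into 3–7 blobs (sigma 1.5–2.5 px, 60–100% amplitude)
  along a jittered random-walk skeleton, deliberately provoking the
  maxima-overcounting failure mode of irregular macrophage staining.
  Parameters are package conventions, configurable, not calibrated to any
  tissue.
* **Degradations.**  Additive i.i.d. Gaussian noise (clipped to the bit
  range; clipping shifts dark-background means upward, as in any bounded
  acquisition) and optional multiplicative quadratic illumination
  gradients.  Noise never touches the truth metadata.
* **Density classes** (package conventions per 512² field): none = 30
  nuclei and an empty marker channel; medium = 50 nuclei, fraction 0.5;
  high = 200 nuclei, fraction 0.5.  The degraded-image panel is 3 density
  classes x 6 cell types (CD4/CD8/CD20 easy, CD68/IBA1 hard, CD68+IBA1
  three-channel) = 18 paired clean/noisy scenes sharing ground truth.

What passing tests on these scenes does **not** show: performance on real
tissue texture (autofluorescence, PSF blur, anisotropic cell shapes,
touching nuclei needing declumping), staining variability, or the
morphology spectrum of actual macrophages.  The generator provides exact,
reproducible geometry for validating the *algorithms*, not a tissue
simulator.

## Statistics

Squared Pearson correlation (R²) between method and reference counts
(zero-variance input raises an explicit undefined-statistic signal, never
a silent 0); two-sided paired t-tests, t = mean(d) / (sd(d)/sqrt(n)) with
n − 1 df (identically zero differences signal; constant nonzero
differences give t = ±inf, p = 0); overcounting ratios method/reference
per sample, with 0/0 undefined and excluded from the mean ± SD and k/0
(k > 0) flagged separately as false positives on an empty reference.  The
evaluation harness runs each method over a scene panel against ground
truth (per-scene failures are logged and recorded as missing, never
raised) and, for paired clean/noisy panels, reports mean ± SD per
morphology with the paired t between clean and noisy counts and the mean
signed deviation.  Tests are two-sided throughout; no multiple-testing
correction is applied.

## Numerical and design choices

* 8-to-16-bit conversion multiplies by 257 (0 -> 0, 255 -> 65535), the
  standard full-range map; it is exact on integers and idempotent.
* Brightness/contrast stretching is percentile-based (defaults 0.35 /
  99.65); a degenerate window maps to 0 instead of erroring so blank
  fields survive batch runs.  The stretch is monotone and is optional
  before maxima detection (detection is translation-invariant, and the
  prominence threshold is specified on the working image's scale).
* `expand_points` partitions overlapping same-set disks by the
  nearest-point rule (ties to the lower point index), so every detection
  remains one labeled object; the pair *decision* uses the full disks
  (shared-lattice-pixel test), matching the relate-overlaps construction.
* The discrete disk-overlap decision agrees with the continuous rule
  distance ≤ 2 x expand_px except within ±1 px of the boundary; tests
  compare against a brute-force oracle applying the same discrete rule,
  so agreement there is exact.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  `SceneSpec`; pipelines contain no randomness, so fixed seeds give
  bit-identical scenes, counts and CSVs.
* Noise-robustness evaluations in this package use pre-blur 2 px with
  noise tolerance 60 (inside the 50–100 working band for SD-25 noise) for
  the semi-automated method, and `min_area = 5` for the automated method;
  clean-image runs elsewhere use the unfiltered defaults.
* Desk-scale problem sizes: 512² fields, 30–200 cells, 18-scene panels —
  the package's chosen working scale; the full 5000² reference field is
  generated on demand.

## Known limitations

* No watershed declumping; merged adjacent cells undercount nuclei.
* Global thresholding only; strongly nonuniform backgrounds beyond a
  quadratic surface are out of model.
* The three-channel automated path implements the third-channel
  classification/filtering as a conjunction over pairwise relations;
  richer per-object classification is not reproduced.
* Overlay-mode counting with large default radii is deliberately
  permissive and expects observer edits; it is not a precision criterion.
* Pixel-intensity colocalization coefficients (Pearson/Manders) are out
  of scope by design — this package is about object-based counting.
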