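# Methods

This note documents the models, parameter choices and numerical
conventions behind `stromakit`, and what the synthetic-data experiments
do and do not demonstrate.

## Phase-image morphometry

A calibrated phase frame carries per-pixel optical phase shift φ (rad),
pixel pitch (µm/px) and wavelength λ (µm). Processing per frame:

1. **Background removal.** Rolling-ball subtraction: the background is
   the apex height of a ball rolled under the intensity landscape.
   Because phase values are O(1) rad while radii are tens of pixels, the
   ball is an ellipsoid — `rolling_ball_radius` (default 50 px) wide
   spatially and `rolling_ball_height` (default 1 rad) tall. A spherical
   ball would be 50 rad tall and its surface would ride over every cell,
   subtracting them as background. The radius must exceed the half-width
   of the largest cell; with ~17–23 µm-wide cells at 1 µm/px the 50 px
   default has ample margin.
2. **Smoothing.** Normalised Gaussian, σ = 2 px by default: enough to
   suppress pixel noise that would fragment local-maximum detection
   without displacing blob peaks.
3. **Seeding.** Local maxima above the segmentation threshold with a
   minimum separation (`min_seed_distance`, default 10 px). Bright phase
   maxima correspond to the dense peri-nuclear region.
4. **Seed consolidation.** For every seed pair, the minimum intensity
   along the straight line between them is compared against the dimmer
   seed's value; a dip smaller than `consolidation_delta` (default 10%
   of the frame maximum) means both seeds sit on one cell's plateau, and
   only the brightest of the merged group survives (union–find, so
   chains collapse transitively). The along-path reading is one of
   several defensible interpretations of plateau-based consolidation; it
   is exposed as a contract, not claimed to match any vendor
   implementation.
5. **Segmentation.** Seeded watershed on the inverted phase image within
   the thresholded foreground. `threshold="auto"` uses Otsu on the
   preprocessed frame — parameter-free and adequate when cells occupy a
   minority of the field. Seeds falling below threshold produce no
   region and are logged.
6. **Measurement.** Area = pixel count × pixel-pitch²; length and width
   are 4σ along the principal axes of the phase-weighted second-moment
   tensor (with the +1/12 px² per-pixel variance term), which equals the
   full axis length for a uniformly filled ellipse; aspect ratio =
   length/width ≥ 1; dry mass m = λ/(2π·α)·Σφ·pixel-area with α
   configurable (default 0.2 µm³/pg, inside the 0.18–0.21 range of
   cellular specific refractive increments). The aspect ratio is
   insensitive to the choice of radial weighting profile because the
   same factor scales both axes. Coordinates are 0-based, origin at the
   top-left; physical centroids are (col+0.5, row+0.5)·pixel-pitch.

## Tracking and migration

Linking is greedy mutual nearest neighbour between consecutive frames
under `max_link_distance` (recommended ≈ 3 × mean speed × frame
interval); unmatched detections open new tracks, unmatched tracks close.
No gap closing is attempted — a broken link costs a split track, which
the ≥ 20-frame gate then filters, rather than risking identity switches.

Gates: an object is debris if dry mass < 250 pg **or** area < 1000 µm²
(the OR combinator is the stricter, conventional debris gate; an AND
variant is config-switchable), a doublet if area > 25,000 µm²; a track
must span ≥ 20 frames. Every removal is appended to an audit log with
its reason, so |input| = |kept| + |audit| always holds and gating is
idempotent.

Metrics per track: path length (sum of step distances), mean speed =
path length / elapsed time (not mean instantaneous frame speed — the two
differ when frame intervals vary), and displacement = straight-line
distance from first to last position. Rose data translate each track's
origin to (0, 0).

## Synthetic time-lapses

Cell motion is a persistent random walk: a 2-D Ornstein–Uhlenbeck
velocity process with correlation time `persistence_time` (default
60 min) and stationary speed distribution Rayleigh with mean
`mean_speed`. Velocities are sampled at the frame interval and positions
advance by v·Δt with reflecting boundaries, so the *sampled* mean speed
equals the parameter by construction — measured speeds then test the
linking and metric code, not a discretisation of continuous motion.
Per-cell aspect ratio, area and dry mass are drawn once from truncated
normals; the defaults for the two reference populations use the measured
morphometry of the Y201/Y202 phenotypes (aspect ratios 3.59 ± 0.072 and
2.016 ± 0.051, mean ± SD) with areas 1400 vs 1800 µm² reflecting the
larger spread phenotype. Speeds (default 20 µm/h) and persistence are
free parameters chosen at a realistic fibroblast scale; no published
numeric speed is asserted.

Cells render as super-Gaussian elliptical blobs, exp(−ln2·ρ^(2p)) with
p = 4: flat-topped (a realistic plateau that exercises seed
consolidation) with a half-maximum contour exactly on the nominal
ellipse, so a half-max threshold recovers the nominal area. Each blob is
scaled so its integrated phase encodes the cell's dry mass through the
same m = λ/(2πα)·∫φ relation the measurement uses. Background is a
low-frequency linear ramp (default 0.2 rad amplitude) plus white
Gaussian noise (default 0.02 rad). Initial placements are
rejection-sampled (centres at least 0.6× the summed semi-major axes
apart; an overcrowded field raises); moving cells may still touch, and
occasionally two adjacent cells merge into one detection — population
statistics absorb this, single-cell tests use isolated fixtures.

What this generator does *not* emulate: optical artefacts of
ptychographic reconstruction (halo, phase wrapping), cell division and
death, shape change during migration, or cell–cell adhesion. Passing
recovery tests therefore demonstrates correctness of the measurement
chain, not robustness to every property of real phase imagery.

## Plate scans and colony detection

Synthetic plates place 2×3 wells (default diameter 1000 px at the
1200 dpi scanning convention) with dark rim annuli just outside the open
well area. Colonies are radially perturbed discs rendered in optical
density with absorbance in red and green only — crystal violet transmits
blue — and converted to RGB as 10^(−OD); base-10 on both the render and
analysis sides makes the unmixing step exactly invertible. Colony edges
are sharp (sub-pixel sigmoid), as stained colonies are; ground-truth
area is the half-maximum disc. Planted objects keep >40 px clearance so
the closing step never merges distinct ground-truth objects; debris is
rendered below the 60 px detection floor.

Analysis stages and the choices inside them:

* Wells: blue channel < 0.99 marks near-black features; hole-filled
  components with equivalent diameter 1000–2000 px are rim candidates.
  The usable well radius is taken from the rim's interior hole (the
  filled disc includes the rim annulus itself); a regular grid (per-row
  and per-column means of candidate centroids) places ideal circles, and
  the analysis circle is the fitted radius − 5 px ("shrunk by 10 px in
  diameter"). At least 4 rims are required; fewer raises an error naming
  the missing count.
* Stain: OD_c = −log₁₀(I_c) (intensities clipped at 10⁻⁴ with a
  warning), projected onto the unit crystal-violet absorbance vector
  (1, 1, 0)/√2; zeroed outside analysis circles.
* Illumination: per-20-px-block medians, median-filtered at the 80 px
  object scale, then capped at median + 3·1.4826·MAD of the in-well
  block medians before bilinear upsampling and subtraction. The cap is
  this package's choice: without it, colonies wider than the object
  scale survive the median filter, enter the surface and subtract
  themselves. A uniform image still flattens to exactly zero, and a
  smooth shading gradient (which moves the whole block distribution, and
  hence the cap) is still removed.
* Detection: Sobel gradient magnitude rescaled to the stain image's
  dynamic range and added; threshold = background mode (histogram mode
  of analysis-circle pixels) + k·1.4826·MAD with k = 3, floored at
  `min_stain` = 0.1 OD so a clean empty well yields nothing; diamond
  closing of reach 10 (bridges gaps ≤ 20 px, absorbing dispersed-cell
  halos); hole filling; components kept if equivalent diameter is
  60–800 px and clipped to the analysis circles. The threshold
  multiplier, stain floor and Sobel combination rule are config-exposed
  defaults, not claims about any external pipeline.
* Measurement: area in px² and mm² (pixel pitch 25.4/dpi mm — 21.17 µm
  at 1200 dpi), equivalent diameter, eccentricity, integrated stain OD,
  centroid, nearest-well assignment; per-well count and mean area.
  Manual curation is replaced by an optional include/exclude list.

## Subtype classification

Feature space (log aspect ratio, log area): both are right-skewed
positive quantities, and the two reference phenotypes separate along
both axes. Each reference population (n ≥ 30) is summarised by its mean
and covariance; a query cell's Mahalanobis distances d₁, d₂ to the two
profiles decide the call: the nearer class iff |d₁ − d₂| ≥ margin
(default 1.0) and min(d₁, d₂) ≤ d_max (default 3.0), else
"unclassified". The margin implements "between categories"; d_max
rejects outliers unlike either reference. Assignments are deterministic;
increasing the margin can only grow the unclassified fraction; swapping
the references swaps the class counts exactly. The published three-way
split of primary cultures is not a reproduction target — it depends on
primary-culture images not available to a synthetic benchmark — so the
classifier is validated on mixtures with known composition instead.

## Secretome statistics

* Normalisation: each sample column scaled to the across-sample mean
  total (total-ion-intensity normalisation at the protein-table level).
  Idempotent; rescaling one sample changes only the shared target
  factor, leaving every ratio statistic untouched.
* Differential abundance: per-protein one-way ANOVA across groups
  (two groups reduce to F = t²), significance at p < 0.05; fold change =
  ratio of arithmetic group means with a zero floor of (smallest
  positive value)/10. Whether to use ratio-of-means or mean-of-ratios is
  underdetermined for this kind of data; ratio-of-means is used
  throughout. Constant proteins get p = 1 with a warning.
* Matrisome annotation: closed division set {core matrisome,
  matrisome-associated, non-matrisome}; unlisted proteins are
  non-matrisome; conflicting duplicate annotations raise.
* χ² enrichment: expected count = n_significant·K/N from the background
  matrisome rate; Pearson two-category goodness-of-fit, df = 1, **no**
  continuity correction (the Yates-corrected value differs by ~2.7 on
  the headline example, which is how the convention was pinned down);
  a warning fires when an expected count drops below 1.
* Over-representation: K = |set ∩ universe|, k = |set ∩ query|,
  upper-tail hypergeometric p; sets with K > 500 are excluded *before*
  testing (confounding, uninformative terms); Benjamini–Hochberg q over
  the tested sets; results kept at q ≤ 0.05 and ordered by p ascending
  with ties broken by k/K descending. The universe defaults to all
  detected proteins and is overridable. Whether the 500-cap should count
  set members outside the detected universe is ambiguous;
  universe-restricted K is used for both the test and the filter.

The abundance generator plants fold changes at a fixed base abundance an
order of magnitude below the median protein. This mirrors reality —
differential proteins are minor contributors to total ion intensity —
and matters: a dominant planted protein would shift its group's column
totals, and total-intensity normalisation would then attenuate every
fold change and push null proteins toward significance. That is a
genuine property of the normalisation, not an artefact to hide, and the
generator documents it by construction.

## Problem sizes and numerical conventions

Recovery experiments use: ~200 rendered cells per population (7 fields
of 30 cells at 768², single frames) for morphometry; 100
persistent-random-walk tracks over 61 frames for speed recovery; two to
three 6-well plates with 12 planted colonies each plus sub-threshold
debris for colony detection; 861-protein tables with 3 planted effects
for differential abundance; n = 1000 mixtures for the classifier. These
sizes put Monte-Carlo error well inside the stated tolerances while
keeping a full run in minutes. Ties in the watershed and in
nearest-neighbour linking are resolved by processing order and are
deterministic for fixed inputs; all generators draw from a single seeded
`numpy.random.Generator`, and identical spec + seed reproduce outputs
bit for bit.

## Known limitations

* The tracker has no gap closing or division handling; crossing cells
  can swap identities (mutual-NN keeps this rare at realistic speeds).
* Otsu auto-thresholding needs a bimodal phase histogram; near-confluent
  fields require an explicit threshold.
* The illumination cap assumes colonies cover a minority of each well;
  a well mostly covered by stain would bias the surface upward.
* The dry-mass calibration assumes a single global α; real cells vary
  by a few percent.
* Morphometric subtyping uses two features; real phenotypes likely
  separate further in texture and intensity features that are out of
  scope here.
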