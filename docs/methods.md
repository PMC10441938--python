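# Methods

`rhizohair` re-implements, as a tested library, the image-analysis chain
used to phenotype whole root systems and their root hairs from 2-D
rhizobox scans: wheat seedlings grown flat against a dark woven fabric,
scanned at 1200 dpi, segmented, and measured both globally (lengths and
surface areas by diameter class) and locally (root-hair sheath width and
pixel density on 4-mm windows).  Because no public raw scans exist for
this kind of experiment, validation is by *parameter recovery*: a
synthetic-scene generator renders root systems with exactly known
geometry, and the pipeline must recover the programmed traits.

## Synthetic scenes

A scene is a set of geometric elements rendered as anti-aliased bright
capsules (max-composited coverage) on a woven background, then Gaussian
blurred (`blur_sigma_px`, default 0.7) and corrupted with additive
Gaussian noise (`noise_sd`, default 6 gray levels), clipped to 8 bits.
The rendering mask (coverage ≥ 0.5 before blur) is kept as the
segmentation reference.

* **Seminal roots** (default 3, diameter 0.5 mm ± 6%) start at a crown
  near the top margin and walk downward in 1-mm steps with heading
  wobble (σ = 4°) plus mean reversion toward each root's initial
  heading — without the reversion term the walks drift and neighbouring
  roots cross, which no real seminal root system at this age does.
* **Lateral roots** (default 4 per seminal, diameter 0.3 mm, ~9 mm)
  emerge at ~75° to the parent and curve downward (gravitropism),
  and only at axial positions more than `lateral_free_tip_mm` (14 mm)
  behind the tip: laterals emerge in older root zones, and this also
  matches the measurement protocol's premise that the subapical window
  is an unbranched segment.
* **Root hairs** are straight filaments, diameter 0.04 mm (≈ 2 px at
  1200 dpi; real hairs are thinner but scanner blur widens them),
  perpendicular ± 25° to the parent axis, base on the root surface, at
  a Poisson density of 4 per mm of axis per side, absent in the last
  2 mm behind the tip.  Lengths are drawn from a normal distribution
  with mean `hair_length_mm` (default 1.8 mm, the middle of the
  1.4–2.3 mm sheath widths observed along wheat seminal roots) and a
  5% coefficient of variation.
* Roots are constant-diameter tubes per element; diameter varies
  *between* elements, not along them.  This keeps the ground-truth
  invariant "totals are exact sums of per-element π·d·ℓ records"
  trivially true; a taper would force per-segment element records for
  no validation benefit.
* The frame margin is a fixed 3 mm rather than a function of hair
  length, so that the root-system geometry of two experimental
  conditions differing only in hair traits is statistically identical —
  otherwise hair-trait contrasts would leak into root-length contrasts.

Ground truth records every element (class, centerline, diameter,
length) and derives totals, per-window hair statistics, and the exact
trait summary (`truth_summary`) in the pipeline's output schema.

What the generator does **not** emulate: root taper and tip shape,
curved or tangled hairs, hair-length gradients along the axis,
soil particles, scanner vignetting and moiré, condensation on the
glass.  Passing recovery tests therefore demonstrates correctness of
the measurement chain under idealized-but-noisy imaging, not robustness
to every artifact of real scans.

## Segmentation

Interactive pixel-classifier segmentation is replaced by a documented
deterministic approximation:

1. **Texture suppression** — grayscale opening with a window auto-sized
   to 1.5 mm (wider than any root, so root interiors are never
   flattened) estimates the fabric background, which is subtracted.
   This attenuates the periodic weave and maps true background to ≈ 0.
2. **Smoothing** — Gaussian, σ = 0.6 px by default and capped by a
   warning at 0.7 px: stronger smoothing destroys sub-0.1 mm hairs.
3. **Global threshold** — default `"midgray"` (128): after suppression
   the image is near-binary (background ≈ 0, tissue ≈ 255), and the
   mid-contrast level localizes the half-coverage contour of
   blur-widened edges, which keeps thin hairs at their true width.
   Otsu is available but lands on the blur skirt of thin filaments and
   measurably widens hairs (hair-area recovery degrades from ≈ +8% to
   ≈ +18% on default scenes).
4. **Cleaning** — removal of components < 20 px and a 1-px closing.

## Morphometry

* **Skeleton**: Lee thinning (reduces even-width bars to their exact
  centerline).  The pixel graph uses 8-connectivity with redundant
  diagonals removed (a diagonal edge whose corner neighbour is itself a
  skeleton pixel would double-count length at staircase corners).
* **Length**: each edge contributes 1 px (orthogonal) or √2 px
  (diagonal), half to each endpoint, so lengths are additive over any
  pixel partition.  Chain coding systematically overestimates curved
  paths (up to +8% at 22.5°), so each skeleton branch is rescaled by
  the ratio of its chord-polyline length (vertices every 12 px — long
  enough to bridge the 1-px medial-axis zigzag that hair bases induce,
  with negligible sagitta error at real root curvature) to its chain
  length.  Straight chains have ratio exactly 1, so horizontal and
  diagonal closed forms are preserved while a 100-px quarter arc
  measures within ~0.3% of πr/2.
* **Local diameter**: d = 2 × Euclidean distance transform at the
  skeleton pixel — the standard medial-axis thickness estimate.  It is
  quantized at ± ~1 px, which is the dominant error source for hair
  (≈ 2 px wide) diameters and hence for hair area.
* **Diameter classes**: hair if d < 0.2 mm, root if d ≥ 0.2 mm (the
  boundary value is root).  Hair-labelled fragments shorter than 3 px
  wedged between root pixels are relabelled root (diameter dips on an
  axis are not hairs).  This dichotomy requires hairs to be several
  times thinner than the class boundary *in pixels*: at 1200 dpi the
  boundary is 9.4 px and hairs ≈ 2 px, comfortably separated; below
  ≈ 40 px/mm, blur-widened hair crossings exceed the boundary and the
  split collapses.  Resolution is therefore never reduced in scaled
  test scenes — frames and root counts are reduced instead.
* **Hair-base trimming**: a hair's medial-axis branch begins on the
  parent's centerline, so its first segment lies inside the root body —
  carrying root-scale diameters (and without correction inflating root
  length by tens of percent, one radius per hair).  Branch pixels
  closer to their root junction than the junction's medial radius are
  removed, so hairs are measured from the root surface outward, the
  same convention the cylinder-area model and the ground truth use.
* **Spur pruning**: root-class endpoint chains shorter than the medial
  radius at their junction are dropped — the classical criterion that a
  medial-axis branch shorter than the local radius reflects a boundary
  bump, not a real branch.  Here the bumps are hair bases: without this
  rule they spawn radius-scale root-class stubs every few hairs,
  inflating root length by 5–7% and making it correlate with hair
  density.  Hair-class pixels are never pruned.  A fixed pixel
  threshold can be requested instead.
* **Per-class length refresh**: after classification and trimming, step
  lengths are recomputed on each class's own subgraph.  In the full
  graph, hair junctions chop the root axis into paths of a few pixels —
  too short for chord straightening — which silently re-introduces the
  chain-coding overestimate.
* **Areas**: naked root area = Σ π·d·ℓ over root pixels, hair area the
  same over hair pixels; the total is formed as the sum of the two
  converted values so the partition identity is bitwise exact.  Mean
  diameter = naked area / (π · root length).  Reporting units: cm,
  cm², mm.

Known biases, deliberately uncorrected because the reference
measurement carries them too: 2-D projection hides hairs that overlap
the root body; crossing hairs merge and undercount; blur widening
inflates hair diameter by a fraction of a pixel.  Net effect on default
scenes: root length within ±3%, mean diameter within ±3%, hair area
+1 to +13% depending on how often hairs overlap.

## Local root-hair estimators

Measurement windows are 4 mm of axis, anchored 60 mm from the tip on
seminal roots and at the middle of laterals (both configurable).  The
mask is resampled along the centerline's normals so the axis is
horizontal; the centerline comes from ground truth (synthetic scenes),
the root-class skeleton (real scans), or the caller.

* **Sheath width w** — per side, line 1 is the root surface: the
  rolling *median* (window ≈ 0.5 mm) of per-column contiguous-run
  lengths around the axis.  The median matters: a hair growing exactly
  perpendicular is contiguous with the body in its own column, and a
  mean-based surface absorbs it, losing the hair entirely.  Line 2 is
  the envelope of per-column maximal hair extents scanned outward from
  that surface, placed at the mean of the top decile of extents ("the
  tips of the longest hairs", robust to a single stray filament;
  `max` and percentile variants available).  w is their separation in
  mm, sides averaged.
  Profiles only consider the connected component containing the axis,
  so unconnected structures crossing the frame are ignored; an optional
  `max_gap_mm` contiguity rule can additionally cut the scan at the
  first wide background gap for crowded scans (off by default — it
  truncates tilted hairs on clean segments).
* **Pixel density D%** — a line is rasterized parallel to the smoothed
  surface at offset w/2 (nearest-pixel, deliberately not interpolated)
  and D% = 100 × white/total pixels, which on the binary image equals
  100·m_grey/255 exactly.  Undefined when w = 0 (no sheath).

On clean synthetic segments the decile envelope recovers programmed
hair length with ≈ 0 mean bias and ≈ 5–9% per-window scatter; windows
contaminated by a crossing root remain the main outlier source, as in
manual practice, where the operator simply avoids such segments.

## Trait statistics

KUpE, KUE, KUtE as defined above (available K is the watering-solution
delivery, supplied by the caller; the seed's contribution — at most
~10% of plant K in the reference setting — can be subtracted via an
explicit offset, default 0).  Student's t (pooled by default, Welch
optional) and one-way ANOVA with Tukey-HSD compact letters; stars
* p<0.05, ** p<0.01, *** p<0.005.  Degenerate zero-variance input
reports p = 0 when means differ, p = 1 when all equal.

## Demo study and problem sizes

`demo_study` renders two groups of scenes identical in every programmed
parameter except the low-K group's +20% hair length and +20% hair
density — the low-K root-hair response magnitude reported for a
responsive wheat genotype — and runs the pipeline blind on both.
Scenes are 34 × 26 mm frames at full 1200 dpi with 3 seminal roots,
8 plants per group, one seminal-rule window per root anchored 8 mm
from the tip (the analogue of the 6-cm anchor on full-length roots).
Demo scenes are lateral-free: the reference protocol measures visually
chosen clean segments, and with short roots in a small frame a
wandering lateral crosses measurement windows an experimenter would
avoid; growing the measured region unbranched is the programmatic
analogue.  Morphometry validation scenes re-enable laterals.  Lateral
ROI windows are likewise disabled in the demo — the middle of a short
demo lateral lies within the parent's sheath reach, whereas the
protocol measures laterals several centimetres long.  These sizes are
the package's chosen demo conditions; they keep a full two-condition
study around a minute while leaving all tolerances meetable.

Expected demo outcome: w, D% and hair-area-per-root-length
significantly higher in the low-K group (t-test, α = 0.05); root
length and naked area not significantly different; on null batches
(identical groups) hair-trait comparisons stay at the nominal
false-positive level.

## Numerical conventions

Rasters are (row, col), 0-based, physical mm frame anchored at the
top-left pixel centre, px = mm × scale; root polylines run base→tip
with the tip as the deeper endpoint.  All randomness flows through
`numpy.random.default_rng` seeds carried in `SceneSpec.rng_seed` /
`PipelineConfig.rng_seed`; identical spec ⇒ bit-identical raster.
Degenerate inputs: empty masks give empty skeletons and zero-valued
summaries with the mean diameter reported as missing; zero available K
raises; zero plant K makes KUtE missing.
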