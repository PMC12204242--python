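# Methods

## Overview

`pectus` implements a fully automatic measurement pipeline for pectus
excavatum (PE) severity on axial chest images:

1. **Segmentation** — a U-Net predicts the inner thoracic contour on each
   axial slice.
2. **Slice selection** — the slice with the deepest sternal depression is
   found from the *outer* body contour, using a tangent line across the two
   anterior chest crests.
3. **Landmark geometry** — the clinical landmarks are located on the inner
   contour of the selected slice(s).
4. **Indices** — Haller, correction and asymmetry indices are computed from
   the landmark distances, with a severity class from the Haller index.
5. **Agreement statistics** — error rates under a 10 %-of-mean rule with
   fourth-observer correction, Pearson chi-square, ICC(2,1) and
   Bland-Altman limits quantify agreement with manual readings.

Because no clinical CT data ships with the package, a synthetic phantom
generator with closed-form ground truth underpins all testing.

## Coordinate and unit conventions

Axial slices are displayed anterior-up: rows increase posteriorly, columns
increase toward the patient's left. Pixel spacing is carried in mm;
every reported distance is converted to cm. Slice indices are 0-based in
every output. In physical coordinates used internally, `x` (cm) is the
transverse axis (positive toward patient left) and `y` (cm) the
anteroposterior axis (positive anteriorly); the "vertical line" of the
classical correction-index construction is the AP axis.

## The phantom model

A slice is built from two closed-form boundary curves:

* **Inner cavity**: an ellipse with semiaxes `A` (transverse) and `B` (AP).
  The anterior arc is indented by a Gaussian depression of nominal depth
  `D`, center offset `x0` and width `sigma`, tapered by the elliptic height
  factor `sqrt(1-(x/A)^2)` so the curve stays closed and simple:
  `upper(x) = sqrt(1-(x/A)^2) * (B - D*exp(-(x-x0)^2/(2 sigma^2)))`.
  The posterior arc carries a circular vertebral protrusion of radius `r`
  centered on the posterior midline: `lower(x) = max(-B*sqrt(1-(x/A)^2),
  -B + sqrt(r^2-x^2))`. A Gaussian depression was chosen because it is
  smooth and unimodal, matching the "deepest point" landmark language; the
  circular arc guarantees a unique most-anterior spine point.
* **Outer body surface**: the same construction on semiaxes `A+t`, `B+t`
  (`t` = wall thickness), without the vertebral arc.

Both boundaries are single-valued functions of `x`, so the cavity is
vertically convex; rasterization fills, per pixel column, the rows whose
centers lie strictly between `lower` and `upper`. This makes the mask
exact with respect to the analytic curve and guarantees a single connected
component. Intensities are three constant bands (background 20, cavity
interior 70, chest wall 130, arbitrary units) plus seeded additive Gaussian
noise; this is deliberately minimal — enough to train and test segmentation
without modeling Hounsfield units, ribs, lungs or cardiac structures.

Analytic ground-truth indices are evaluated on an 8192-point transverse
grid that is exactly symmetric about zero in floating point, which makes
mirror properties (asymmetry reciprocal under dent-offset negation) hold to
machine precision. A parameter validity check rejects depressions that
would reach the posterior boundary (self-intersecting contour).

The randomized cohort generator draws plausible pediatric-chest geometry
(inner transverse diameters 16–22 cm, AP 10–14 cm, depressions up to 60 %
of the AP semiaxis, dent offsets up to ±2 cm) and rejects draws without a
decisive depression — at least 0.8 cm of dip below the lower anterior crest
and 0.5 cm of outer-surface depth — since a phantom whose anterior boundary
is effectively unimodal has no measurable PE and no well-defined depression
landmarks. Every stochastic quantity derives from one integer seed; there
is no global RNG state.

**What the phantom does not emulate:** CT texture and noise correlation,
ribs and costal cartilage, lungs, mediastinal structures, breast tissue,
respiratory phase, or patient tilt in 3-D. Passing tests therefore show
correctness of the geometry and learning machinery on idealized
cross-sections, not clinical-grade segmentation accuracy.

## Segmentation stage

Slices are resampled to the network input size (default 256², bilinear for
intensities, nearest-neighbor for masks, spacing rescaled so physical
extent is preserved). Augmentation applies three independent families —
rotations −25°…25° in 5° steps (11 members), isotropic scalings 0.85…1.15
in 0.05 steps (7), horizontal/vertical flips (2) — each member producing
one output pair, so one input expands 20-fold. Families are never
composed: this is the only reading consistent with a 550 → 11 000
expansion. Identity members (0°, ×1.0) are kept even though they duplicate
the original. Rotation and scaling use reflect padding so out-of-frame
pixels never invent new anatomy.

The network is the classic U-shaped encoder–decoder: per encoder level two
3×3 convolutions with ReLU then 2×2 max-pooling; a two-convolution
bottleneck; per decoder level a 2×2 up-convolution, skip concatenation and
two 3×3 convolutions; a final 1×1 convolution with sigmoid. Filters double
per level from `base_filters`. At the default depth 4 the network has the
classic 23 weighted layers. It is implemented directly in numpy —
im2col patch extraction feeding BLAS matrix products, with hand-written
backward passes (the input gradient of a same-padded convolution is itself
a convolution with the flipped, channel-transposed kernel). Weights use He
initialization from a seeded generator; two builds with the same seed are
bit-identical, as are two training runs.

Three losses are available on the predicted probability map:

* **Cross-entropy**: mean per-pixel binary cross-entropy.
* **Soft Dice**: `1 - (2 Σpt + eps) / (Σp + Σt + eps)` with `eps = 1e-6`,
  so on binary predictions the loss complements the evaluation Dice to
  within 1e-6.
* **Active contour**: a length term (mean finite-difference gradient
  magnitude of the probability map, `eps`-stabilized) plus a region term
  `mean(p (t-c1)^2 + (1-p)(t-c2)^2)` with `c1 = 1`, `c2 = 0`. The exact
  weighting of the published active-contour formulations varies, so both
  weights are exposed in the configuration with default 1.0 each. The
  length term penalizes ragged, noisy boundaries; it vanishes for constant
  maps.

Training uses Adam (lr 1e-4, β = 0.9/0.999), batch size 4, early stopping
on validation loss with patience 10 epochs (default) and best-weight
restoration. "Until convergence" is not operational; patience-based
stopping is the concrete rule. A non-finite loss aborts with a
diagnostic. Prediction post-processing — threshold 0.5, keep the largest
connected component, fill holes — guarantees the mask invariants
downstream geometry relies on; an empty thresholded map yields a
no-segmentation signal rather than a crash.

## Landmark geometry

The inner contour is traced by marching squares at iso-level 0.5 on a
lightly Gaussian-smoothed (σ = 1 px) copy of the binary mask; smoothing
suppresses the staircase bias that otherwise inflates boundary length by
about 5 %, while displacing a locally straight edge by well under a tenth
of a pixel. Per-column anterior/posterior envelopes are then computed by
exact polyline–column intersection (not vertex binning), which keeps all
landmarks equivariant under horizontal mirroring and translation.

Landmarks, following the classical constructions:

* `d` — most anterior point of the posterior boundary within a midline
  window of ±15 % of the transverse width around the transverse centroid
  (window fraction configurable). The vertebral apex is locally flat, so
  the median of the columns within half a pixel of the top is used. If
  the window has no central protrusion (posterior boundary anterior-most at
  the window edges), `d` falls back to the posterior midline point.
* `S` — transverse line through `d` (the spine tangent).
* `a` — most anterior contour point overall (ties toward smaller column);
  `b` is its AP projection onto `S`; `ab` is the AP distance between them.
* Anterior crests — most anterior point of each half of the anterior
  boundary, split at the transverse centroid; `c` is the most posterior
  point of the anterior boundary *between* the crests; `cd` is its AP
  distance to `S`. If the boundary has no real dip between the crests
  (less than 2 px below the lower crest), the case is flagged `no-dent`,
  `c := a`, and the correction index is 0.
* `L`, `R` — per-hemithorax maximal AP chord (anterior to posterior
  boundary at the same column), hemithoraces split at `d`'s column. A
  configuration flag measures the chords from the spine tangent line
  instead; the full chord is the default.
* Transverse diameter — sub-pixel column extent of the traced contour.

`ab` and `cd` are AP-axis distances to the line `S`, not Euclidean
point-to-point distances; this is what reduces `100 (ab - cd)/ab` to the
established correction-index construction.

## Index definitions and severity

* **Haller index** = transverse diameter / `cd` (the AP distance from the
  deepest sternal point to the anterior vertebral line). `cd ≤ 0`
  (sternum at or behind the spine line) has no finite Haller index and is
  an error carrying its own flag.
* **Correction index** = `100 (ab - cd)/ab` percent; not clamped at 100 —
  values ≥ 100 carry a `dent-past-spine` flag instead of raising.
* **Asymmetry index** = `R / L`, taken literally as a ratio (not ×100).
* **Severity** (from the Haller index): mild < 3.2, moderate 3.2–3.5
  (closed at both ends), severe > 3.5.

One subtlety: in some published figure captions the transverse diameter is
called "height" and the AP distance "width" with the index written
width/height; read literally that would put every index below 1,
contradicting the 3.2/3.5 severity thresholds, so this package follows the
verbal definition (transverse over AP).

## Slice selection

On each slice the outer body contour is extracted (Otsu threshold — with
an optional override — largest component, hole fill, smoothed marching
squares). The two chest crests are the most anterior outer points of each
hemithorax (split at the transverse centroid); the depression depth is the
maximal perpendicular drop of the anterior boundary posterior of the
crest-to-crest line. Because the reference is a tangent line rather than
an image axis, the depth is invariant to moderate in-plane rotation
(verified to 0.1 cm for rotations ≤ 25°).

The target is the argmax of depth (ties broken toward the smallest index
and flagged). The measurement neighborhood defaults to the 7-slice
inclusive window target±3, clipped at stack bounds; a literal six-slice
mode that excludes the target is available, since the clinical description
("three above and three below") can be read either way. Headline indices
are always reported on the target slice; per-slice indices are reported
for the whole neighborhood.

## Agreement protocol

Errors are counted per *case* (one patient × index combination): with
three observers, a case is an error when any observer deviates from the
three-observer mean by more than 10 % of that mean (threshold
configurable). Per-observer counting is rejected because it cannot
produce the per-index case denominators the protocol reports. On flagged
cases the most deviant reading (ties toward the lowest observer number)
is replaced by a fourth observer's value and the rule is re-evaluated; the
corrected triple may legitimately remain an error. The automatic
measurement is an error when it deviates more than the same fraction from
the pre- or post-correction manual mean — the only reading under which the
automatic error rate can change across correction while the automatic
values are fixed. Repeated reads per observer are modeled as a
pre-averaged input column.

Statistics: Pearson chi-square on 2×2 tables via the closed form
`n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))` with df = 1 and optional Yates
correction; ICC as two-way random effects, absolute agreement, single
measures (ICC(2,1), computed through pingouin), chosen because the
protocol compares two fixed "methods" drawn from a larger population of
possible raters; Bland-Altman bias and 1.96-SD limits, defaulting to
percent differences of the pair mean so indices on different scales are
comparable.

## Numerical choices and degenerate inputs

* Binary masks quantize every boundary to half-pixel precision; landmark
  distances therefore carry up to ~1 px of irreducible noise. At 256²
  grids (≈1–1.2 mm/px on a pediatric chest) this keeps all three indices
  within 2 % of analytic truth across the randomized phantom suite; the
  error shrinks roughly linearly with resolution (verified at 128/256/512).
* Mask↔contour orientation, vertex order (CW/CCW) and explicit closing
  vertices are normalized away; landmark results do not depend on them.
* Degenerate inputs have defined behavior rather than crashes: empty or
  multi-component masks report the component count; flat chests report
  zero depth and a flag; all-flat stacks raise a "no-depression" error;
  dent-free contours yield CI = 0 and a `no-dent` flag.
* All thresholds that are genuinely conventions — probability 0.5, error
  fraction 0.10, spine window 0.15 — are configuration fields, not
  constants buried in code.

## Problem sizes used in the reference evaluation

The packaged segmentation benchmark trains the compact configuration
(128-pixel inputs, 8 base filters, depth 4, Dice loss, Adam 1e-4, batch 4,
early stopping with patience 5 within at most 20 epochs) on 200 synthetic
slices and scores 50 held-out slices with full post-processing. These
sizes were chosen as the package's standard quick-evaluation protocol: the
phantom task is easier than clinical CT, so mean Dice ≈ 0.95 and IoU ≈ 0.91
comfortably clear the 0.905/0.826 accuracy floor reported for clinical
segmentation, while the whole run stays in the minutes range on a single
CPU. The same numbers are recomputed by `scripts/acceptance.py`.

## Known limitations

* The numpy network trains small models briskly but is not a GPU framework;
  reproducing clinical-scale training (hundreds of 256² slices, 64 base
  filters) is out of scope.
* The phantom's intensity model is three bands + noise; segmentation
  performance on it says nothing about contrast-poor clinical boundaries.
* Landmark definitions assume a single dominant depression; double-dent
  morphologies are measured at their deepest dip only.
* ICC and Bland-Altman summaries assume positive, roughly continuous
  measurements; they are not meaningful for the degenerate flagged cases.
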