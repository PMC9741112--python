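# Methods

`depthprop` re-implements, as a standalone testable library, the
depth-aided stages of an RGB-D green-asparagus detector: ground-plane
pixel classification from a tilted depth camera, a depth filter that
revises region-proposal (anchor) labels, DIoU-based detection losses,
ROI Align, mask+depth cutting-point localisation, and detection
metrics. The convolutional backbone and its training are out of scope;
a synthetic RGB-D scene simulator with a configurable surrogate
classifier stands in for them so every stage can be exercised
end-to-end with known ground truth.

## Camera and ground model

The camera looks forward along its z axis, mounted a distance `h_c`
above a planar loess ground that meets the optical axis at an acute
angle `alpha` (complement `beta = pi/2 - alpha`, always derived). The
machine's sagittal plane is the camera's xCz plane; y points out of it
and is ignored by every ground test. In the camera frame the ground is

    z sin(alpha) - x cos(alpha) = h_c,

with unit normal `n = (-cos(alpha), 0, sin(alpha))`. Depth files store
the camera-frame z coordinate in millimetres (16-bit PNG, 0 = missing);
all computation is in metres. Back-projection is the standard pinhole
model `x = (u - cx) z / fx`, `y = (v - cy) z / fy`.

Note an orientation consequence: because the back-projected x comes
from the image u axis, the sagittal plane maps onto the image's
*horizontal* axis — stalks rise toward +u and the ground recedes along
u. Nothing downstream depends on image orientation (distances, ratios
and boxes are orientation-agnostic), but rendered scenes look rotated
compared with an ordinary landscape photograph.

## Ground-pixel classification

Two dialects are provided, selected by a `dialect` argument:

* `piecewise` — the piecewise trigonometric test. For x >= 0 a
  point is ground iff `(h_c + x cos a)/z` lies in
  `[(1 - t_f) sin a, (1 + t_f) sin a]`; this is algebraically exact on
  the plane. For x < 0 the test compares `z / (|x_g| - |x|)` against
  `[(1 - t_f) tan a, (1 + t_f) tan a]`, with the ground reference
  `x_g = -h_c / cos a` (the z = 0 intercept of the sagittal ground
  line, the only intercept consistent with the x >= 0 plane;
  overridable). The two branches are *not* mutually consistent: an
  exactly on-plane point with x < 0 produces the ratio `cot a`, not
  `tan a`, so for small `t_f` the x < 0 half-space is classified
  non-ground unless `a = 45°`. The branch is kept verbatim as the
  documented construction; users wanting a single consistent rule use
  the second dialect.
* `plane_distance` — ground iff the perpendicular distance to the plane
  is at most `t_f · h_c`. Self-consistent in both half-spaces; this is
  what the pipeline and the packaged experiments use.

Band endpoints are inclusive so `t_f = 0` accepts exactly-on-band
points; under continuous depth noise the `t_f = 0` ground set has
measure zero and ground recall grows monotonically with `t_f` (tested).
Default `t_f = 0.1` for anchor-level classification; the cutting-point
stage uses the stricter `t_f / 2`. A consequence worth knowing: with
`t_f = 0.1` and `h_c = 0.45 m` the plane band is ±45 mm, so the bottom
~45 mm of every stalk is itself classified "ground". That is inherent
to a tolerance-band ground test and is what makes the strict tolerance
necessary for cutting points.

## Anchor pyramid and depth filter

Five anchor areas {16², 32², 64², 128², 256²} map one-to-one onto
pyramid levels P2–P6 (strides 4–64); each combines with aspect ratios
{1:1, 1:2, 2:1}, giving 15 shapes. Widths/heights are kept real-valued
(`w = sqrt(a r)`, `h = sqrt(a / r)`, area preserved); rounding happens
only at rasterisation, where boxes are half-open `[x1, x2) x [y1, y2)`
and a pixel with integer index (r, c) is inside iff `x1 <= c < x2`,
`y1 <= r < y2`.

The depth filter computes `R_p`, the fraction of ground-classified
pixels among valid pixels in the (image-clipped) box — implemented with
summed-area tables for whole pyramids, with a per-box loop kept as the
test oracle — and sets the final anchor label from `R_p` against a
threshold `t_d` (default 0.5, configurable; never stated in the source
work). Two rules exist because the printed revision formula and its
prose disagree:

* `text_consistent` (default): final label 1 iff `R_p < t_d` — a stalk
  anchor should *not* be ground-dominated;
* `eq7_literal`: final label 1 iff `R_p > t_d`, the formula as printed.

Both override the softmax label; a `revised` flag records disagreement.
Anchors with undefined `R_p` (no valid pixels) pass through unchanged.
In the end-to-end pipeline the filter is applied as a *re-check of the
classifier's positives* (only positives ever reach a proposal layer),
so the negative-to-positive rescue direction exists in the API and is
unit-tested but does not flood the pipeline with geometry-only
positives.

## Losses

`iou`, `diou_loss = 1 - IoU + rho²/d²` (centre distance over enclosing
diagonal), `smooth_l1`, clamped binary `cross_entropy`
(`eps = 1e-7`), and composite losses: the RPN loss
`(1/N_cls) Σ L_cls + δ (1/N_reg) Σ p* L_diou` and the head loss
`L_cls + δ' [u >= 1] L_diou + L_m`, with `δ = δ' = 1` defaults. The
mask loss `L_m` is the mean per-pixel binary cross-entropy on the mask
of the true class (the published signature `L_m(p, s)` is read as a
typo for the standard class-specific mask loss); it is zero for
background samples, which have no mask. Degenerate (zero-area) boxes
are rejected rather than given IoU 0 so the enclosing diagonal stays
positive. All losses are evaluable functions only — no autograd, no
training loop.

## ROI Align

Pixel (i, j) has its centre at continuous (x = j, y = i). A box is
divided into equal bins; each bin is the mean of `samples_per_bin²`
(default 2²; the source text does not state a count) regularly spaced
bilinear samples, computed from the four nearest pixel centres with no
coordinate rounding. Samples beyond the grid clamp to border values; a
direct `bilinear_sample` call errors outside the half-pixel-padded
domain.

## Cutting point

Given an instance mask, valid mask pixels are ranked by 2D Euclidean
image distance (on pixel centres) to the nearest pixel classified
ground at the strict tolerance `t_f/2`; ties break toward larger row,
then larger column. The cutting point is the component-wise mean 3D
coordinate of the k = 20 nearest pixels (all, with a warning, if fewer
exist — harvesting degrades gracefully rather than failing). "Nearest"
is measured in 2D image pixels, not 3D metres, following the
in-the-image phrasing of the procedure; a 3D variant is deliberately
not implemented. Detections of small stalks can be dropped by mask
area and/or estimated height (`filter_small_stalks`); the thresholds
are configuration only.

The estimator has a small systematic bias: the selected pixels lie on
the *front surface* of the stalk (≈ one radius toward the camera) and
up to the strict band above the base. At 12–16 mm radii and depths up
to 1.5 m this totals ~1.9 cm mean 3D error against the true base
centre, which the recovery experiment measures.

## Synthetic scenes

`simulate_scene` ray-casts the ground plane and finite cylindrical
stalks (axis = plane normal, nearest-hit occlusion) into 640 x 480
RGB-D with per-pixel true ground labels, instance masks, tight boxes
and true cutting points (base centres). Depth noise is Gaussian in mm,
clipped at ±3σ so the rendered ground provably stays within 3σ of the
plane. Colour statistics follow five capture conditions — sunny (S),
sunny-but-overshadowed (O, adds a multiplicative shadow band), cloudy
(C), greenhouse daytime (D) and nighttime (N, dim) — as simulator
conventions: S/O reduce the loess/stalk colour separation that
motivates the depth filter. Everything is deterministic given the seed.

Default study conditions, chosen once: camera fx = fy = 570 px,
640 x 480, `h_c = 0.45 m`, `alpha = 35°` (the whole image is below the
ground horizon; ground depths span ≈ 0.45–4 m); stalk height
0.15–0.25 m, radius 12–16 mm (thick, jumbo-grade spears), bases within
±0.10 z of the sagittal plane (a harvester camera views its crop row
head-on), depth noise σ = 2 mm. `random_scene_config` additionally
avoids mutually occluding placements; explicit `SceneConfig`
construction remains available for occlusion studies.

The surrogate classifier (`ClassifierModel`) replaces the RPN softmax:
anchors with IoU ≥ `iou_positive` against a true box are positive with
probability `tp_rate` (0.95); ground-dominated anchors (true ground
fraction ≥ 0.5) become false positives with probability
`loess_fp_rate` (0.05) — the loess-confusion model; all else with
`other_fp_rate` (0.001). An optional `ref_height_px` models feature
completeness: a stalk is detectable with probability
`min(1, projected_length / ref_height_px)`, drawn once per stalk from
a seed-and-index-keyed stream so the draw is shared across renders of
the same layout at different depths (common random numbers — the
recall-vs-depth sweep is variance-reduced by construction). It is off
by default and enabled (110 px) only in the depth-recall experiment.

### Matching threshold for unregressed anchors

The pipeline evaluates raw anchors: bounding-box regression and NMS
are out of scope. Against a thin stalk box (aspect ≥ 4:1) the best
achievable IoU of any of the 15 anchor shapes is ≈ 0.3–0.45, and
projected stalk diameters of 11–13 px fall *between* the P2 (23 x 11)
and P3 (45 x 23) anchor heights, where the only well-overlapping
anchors are about half ground. The pipeline therefore uses IoU 0.15
both for surrogate-classifier positivity and for detection matching;
at the conventional 0.5 every recall would be identically zero by
construction, and at 0.2 whole stalks are spuriously erased whenever
`R_p` of the best anchor straddles `t_d = 0.5`. The evaluation module
itself defaults to IoU 0.5 for ordinary detector output. Because no
NMS is applied, duplicate anchors per stalk count as false positives
and absolute pipeline precision is heavily deflated; the meaningful
quantities are the before/after-filter deltas.

## Evaluation

Greedy one-to-one matching in descending score order; a prediction is
TP if its IoU with an unmatched truth reaches the threshold, else FP;
unmatched truths are FN. `Pre = TP/(TP+FP)`, `Rec = TP/(TP+FN)`,
`F1 = 2PR/(P+R)`, `Acc = (TP+TN)/total`. Accuracy is only computed
where TN is meaningful (anchor-level classification); zero-denominator
metrics are reported as undefined (`None`), never 0. Comparisons with
printed reference tables round half-up at the printed precision.

## Packaged experiments and problem sizes

* **Filter ablation** — 20 seeded scenes, 3 stalks each, condition S,
  `t_f = 0.1`, `t_d = 0.5`, `text_consistent`, plane-distance dialect:
  per-scene precision/F1 before vs after the filter. The filter removes
  the loess false positives (R_p ≈ 1) and ground-dominated duplicates;
  precision never decreases and F1 rises on average.
* **Cutting-point recovery** — 20 noiseless seeded scenes, 3 stalks at
  0.6–1.5 m: mean 3D error of recovered cutting points vs true bases
  (≈ 1.9 cm, dominated by the front-surface/strict-band bias above).
* **Recall vs depth** — 25 trials x 3 stalks per depth in
  {0.9, 1.1, 1.3, 1.5, 1.7} m, noiseless, perfect classifier except
  `ref_height_px = 110`: pipeline recall declines from ≈ 1.0 at 0.9 m
  monotonically as stalks recede, reproducing the qualitative
  feature-completeness effect. No numeric agreement with any field
  measurement is claimed.

These sizes keep the full suite and the acceptance script each under a
minute on one CPU while leaving the statistical margins comfortable.

## What the simulator does and does not show

The simulator shares its plane model with the classifier under test,
so ground-classification tests validate *consistency*, not robustness
to real terrain: no ruts, slopes, weeds, specular soil, or multi-path
depth artefacts. Stalks are ideal cylinders; real spears bend, taper
and occlude each other. The surrogate classifier's error structure
(loess-confusion false positives, size-driven misses) is a convention,
not a fitted model of any CNN. Passing the packaged experiments
therefore demonstrates that the depth-aided stages behave as designed
under their stated geometry — not that any particular field accuracy
would be achieved.

## Known limitations

* The `piecewise` x < 0 branch is inconsistent with the plane
  (see above); choose `plane_distance` for real use.
* Spears thinner than ~20 mm diameter beyond ~1.3 m drop below the
  anchor pyramid's resolution without box regression: no anchor is both
  well-overlapping and non-ground-dominated, and the filter erases
  them. This is the small-stalk regime that harvesting pipelines
  typically exclude anyway.
* `t_f` couples noise robustness to stalk-bottom leakage through a
  single parameter; scenes with very low camera mounts (small `h_c`)
  may need a larger `t_f` than the default to tolerate the same
  absolute depth noise.
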