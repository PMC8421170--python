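# Methods

## Model and assumptions

The pipeline assumes bright sperm heads on a darker, statistically
stationary background, an effectively fixed field of view, and small
inter-frame displacements relative to the association gates. Only heads
are modelled: tails and midpieces carry most of the shape variation but
little of the kinematic signal, and the head is the brightest structure
in bright-field semen recordings. Immotile cells and debris are treated
as background by construction — a background-subtraction detector can
only ever see movers — so the immotile count of a sample must come from
outside the tracker (ground truth, a manual count, or a static count of
the first frame supplied by the caller).

### Per-pixel mixture background model

Each pixel holds K weighted Gaussians over 8-bit intensity. Per frame:

1. components are ranked by weight/sigma; the leading components whose
   cumulative weight has not yet reached the background ratio `bg_t`
   form the background;
2. the observation matches the first ranked component within
   `match_lambda` standard deviations (zero-weight placeholders never
   match);
3. all weights decay by `1 - alpha` with the matched one reinforced by
   `alpha`; the matched component's mean and variance move toward the
   observation with rate `rho = alpha * exp(-(x-mu)^2 / 2 sigma^2)` —
   the match density scaled to peak at `alpha`. The classical
   density-weighted rate has magnitude ~alpha/sigma/sqrt(2 pi), which for
   8-bit data is so small that means effectively never move; scaling by
   the peak keeps the rate in (0, alpha], preserves the
   "better-matching observations adapt faster" behaviour, and stays
   seed-free and deterministic;
4. if nothing matches, the weakest component is replaced by a fresh one
   centred on the observation with `initial_variance` and `weight_floor`
   weight; weights are renormalized to sum to 1 every frame.

The foreground mask marks pixels that matched no background component.
Defaults: K=3, alpha=0.05, lambda=2.5, initial_variance=225,
variance_floor=4 (intensity² units), weight_floor=0.05, burn-in
30 frames. All are exposed on `BackgroundParams`. The model contains no
randomness: identical input yields bit-identical masks.

### Automatic background ratio

`bg_t` is the one parameter that genuinely varies between samples. The
optimizer sweeps {0.10, 0.20, ..., 1.00}; for each value a fresh model is
trained on the burn-in prefix and the valid-detection count is measured
on the first post-burn-in frame. One evaluation frame suffices because
acquisition conditions are constant within a recording; a short burn-in
is unavoidable since a mixture model with no history cannot separate
anything. The maximal count wins; ties resolve to the smallest ratio
(deterministic). The grid includes 1.00, where every component is
background and only wholly unexplained pixels surface — on clean scenes
this detects nothing, which the sweep exposes naturally.

### Detection

Opening-then-closing with a disk structuring element (radius 3 by
default) removes speckle smaller than the element and fills pits;
disk-shaped elements preserve the rounded head outline where line or
square elements leave ragged structure. Candidates are 8-connected
components. Centroids come from the exact zero/first-order binary
moments; semi-axes from the ellipse with matching second central moments
(pixel-centre convention, identical to standard blob analysis). The
area filter uses the elliptical area pi*a*b with **semi**-axes — with full
axes the same formula would overstate areas fourfold and the canonical
150 px² debris threshold would correspond to implausibly small heads; a
`full` convention switch exists for comparison. The filter boundary is
inclusive: exactly 150 px² is a head.

### Tracking

Greedy nearest-first association, not a global assignment: candidate
pairs passing the 125 px distance gate and the 1.2 size-ratio gate are
consumed in order of distance (ties: smaller size ratio, lower track id,
detection order). This matches a per-sperm closest-and-most-similar
search and is fully deterministic. The 125 px gate is calibrated for the
default 10-frame stride; `scale_gate_with_stride` scales it linearly if
the stride changes, off by default. Lost tracks are never revived: a
sperm leaving and re-entering the field of view becomes a new identity,
which biases per-track statistics conservatively rather than risking a
false merge. The background model consumes every frame; only detection,
association and velocity use the stride.

### Velocity and classification

Step speed is centroid displacement in micrometres over the elapsed time
`stride/fps` seconds; a track's speed is the arithmetic mean of its step
speeds. A literal mode dividing raw pixel displacement by the frame rate
exists for comparison only — its unit (px·s/frame) is not a physical
speed. The WHO fast-progressive boundary is inclusive (v >= 25 um/s);
tracks below 1 um/s (`v_immotile_eps`) are jitter and count as immotile.
The sample-level rule is also boundary-inclusive: motile fraction
>= 0.40 is normal, which is the reading consistent with a published
ten-sample benchmark whose 40.0% sample is called normal (bundled in
`datasets.py`).

The default pixel scale is 0.2 um/px, a plausible value for a x400
bright-field setup; it linearly scales every reported velocity and must
be calibrated per instrument. Frame rate is always taken from the data
or the caller, never assumed.

### Evaluation

Detections are matched to in-frame ground-truth objects greedily within
a 20 px gate (about one head length — no canonical value exists, and the
scoring is insensitive to the gate when objects are separated). Motile
objects are positives; immotile cells and debris are negatives, so a
detection sitting on either of them (or on nothing) is a false positive
and an untouched static object is a true negative. Counts pool across a
sample's evaluated frames by default; per-frame reporting is available.
Cross-sample summaries use the population (divisor-n) standard
deviation, the convention of the bundled benchmark table; `ddof=1` gives
the sample estimate.

## Synthetic data: what it does and does not emulate

The generator draws filled elliptical heads (default semi-axes 8–12 px,
i.e. heads clearly above the 150 px² filter at the default scale) at
`head_level` on a `background_level` field, with additive clipped
Gaussian noise (sigma 5 by default) and optional illumination gradient.
Motile heads follow constant-velocity straight lines, majors aligned with
the heading, with optional heading jitter; borders either swallow objects
permanently (default) or reflect them. Immotile cells and debris are
static; debris specks stay below the area filter by construction. The
ground truth stores every object's continuous centre and rendered pixel
count per frame, and serializes to JSON losslessly.

Not emulated: flagella, collisions and head merging, focus drift, stage
drift, gradual illumination change, and the heavy-tailed debris
morphology of real preparations. Tests passing on this world certify the
pipeline's logic and numerics, not robustness to every artefact of real
semen video.

### The reference benchmark scene

`benchmark_scene` is the fixed end-to-end testbed: 640x480, 300 frames,
50 fps, 0.15 um/px, five motile heads (21, 23.25, 30, 37.5, 42 um/s —
both WHO progressive classes), three immotile cells, twenty debris
specks. Its geometry is deliberate:

- each head swims horizontally in its own lane, lane rows 96 px apart —
  more than twice the largest per-stride displacement, so gated greedy
  association provably cannot confuse identities; starts are staggered
  so all initial pairwise distances exceed 250 px (keeping *every* pair
  beyond 250 px for the whole clip is geometrically impossible: five
  such points in a 640x480 frame form an essentially rigid
  corners-plus-centre packing with ~80 px of slack, while these speeds
  imply hundreds of pixels of relative drift);
- lane bounds make each traverse an exact multiple of ten frames of
  travel, so reflections coincide with sampling instants and every
  sampled chord carries the true speed — the ground truth is exactly
  recoverable by a chord-based velocity measurement;
- pixel speeds stay at or above 2.8 px/frame because below roughly
  2.4 px/frame a pixel dwells under the head longer than the mixture
  model's absorption time and the head starts fading into the
  background. That fade is a real limitation of motion-based detection
  (near-static sperm are invisible to stage 1 by design), so the scene
  keeps its movers inside the detectable regime and the slow-progressive
  speeds (21, 23.25 um/s) are realized at a finer pixel scale.

The seed varies the static scenery and sensor noise; the motile
kinematics are fixed. On this scene the pipeline with automatic BG_T
recovers all five heads as exactly five tracks with sub-0.1% velocity
error and sub-0.2 px RMS centroid error across tested seeds.

## Problem sizes

The default test and reproduction runs use the 300-frame 640x480 scene
for end-to-end recovery, a 60-frame clip for the optimizer cross-check,
and 320x240 scenes for model-level tests — sizes chosen so the full
suite completes in a couple of minutes on one CPU while still exercising
the native 640x480 geometry.

## Known limitations

- Colliding or co-moving sperm merge into one detection and one track;
  no splitting is attempted.
- Sperm slower than the absorption limit (~2.4 px/frame at default
  parameters) fade into the background model and are missed or
  fragmented; they are effectively reclassified as immotile.
- AVI/MP4 reading requires an ffmpeg-capable imageio plugin; the frame
  directory path (PNG/TIFF) is the always-available lossless route.
- The evaluation's true-negative bookkeeping needs ground truth for
  static objects; on real video that means expert annotation.
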