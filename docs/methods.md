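# Methods

`germquant` quantifies fission-yeast spore germination from timelapse
microscopy. This note documents the measurement model, the scoring rules,
the synthetic-data generator that backs the test suite, and the numerical
and design choices a user or maintainer should know about.

## Measurement model

Each segmented object in each frame is summarized by the ellipse with
matching second central moments of its pixel set: axis lengths are
`4·sqrt(λ)` for the two eigenvalues λ of the normalized central-moment
matrix (the regionprops convention), the aspect ratio (AR) is major/minor
(≥ 1 by construction), and area is the pixel count times the squared pixel
size. Centroids use the sub-pixel convention `(index + 0.5)·pixel_size`,
and frame *k* is acquired at time `k·frame_interval` with frame 0 at time
zero. The pixel size is a required calibration input; the default of
0.18 μm/px corresponds to a 60× objective with an 11 μm camera pixel.
Degenerate (collinear) regions get the minor axis floored at one pixel
width and are flagged rather than dropped.

## Scoring rules

All thresholds are strict as stated:

- **Spore gate** — a particle is scored as a spore when its AR at time
  point zero is *less than* 1.4 (circular objects). Particles absent at
  frame 0 (late-appearing debris, division products) are rejected and
  counted separately.
- **First division** — the first frame whose AR *exceeds* 3.0. A crossing
  supported only by an interpolated (gap or focus-loss) frame is shifted to
  the next measured frame, so artifacts cannot create divisions.
- **Germination efficiency** — gated spores that complete a first division
  before the end of the timelapse, over all gated spores. Fewer than 50
  gated spores triggers a warning (the reporting convention is N > 50 per
  sample); zero gated spores is an error, not a silent 0/0.
- **Swelling** — on series smoothed with a centred moving average (default
  window 3 frames), the longest run of frames whose relative area slope
  exceeds 0.01/frame while the absolute AR slope stays within 0.02/frame:
  area rising without departure from circularity. The scan stops at the
  division frame. The endpoints of this window are an operational choice —
  the phenomenon is usually reported with approximate windows — so both
  slope tolerances are exposed in the configuration.
- **Outgrowth phenotype**, evaluated at the frame before the observed
  division split (or the last tracked frame when no split occurred), with
  the spore body defined as the disc of the t0 radius at the t0 centroid
  and per-pole protrusions measured along the mask's principal axis:
  1. *exploded* — the track ends early without a split (fragmentation with
     a large area drop, or outright disappearance);
  2. *bubble* — a split occurs while the parent is still rounder than
     AR 1.6 (division without polarized outgrowth);
  3. *bipolar* — both poles protrude beyond a tube radius + 0.5 μm;
  4. *elongated* — the longer protrusion exceeds 6 μm;
  5. *normal* otherwise.
  The order encodes the bipolar-over-elongated priority: a cell growing
  >6 μm from both poles is scored bipolar, never elongated. The protrusion
  length is always recorded so users can re-bin with another cutoff.
- **Focus QC** — per-frame sharpness is the variance of the gradient
  magnitude; frames below median − 3·MAD are flagged, masked from
  per-track series (linear interpolation across short gaps), and a
  timelapse with *more than* 5 flagged frames is excluded outright.
  Exactly 5 is kept.

## Tracking

Spores germinate trapped under agar and are essentially motionless, so
linking is greedy nearest-centroid per frame pair under a 2 μm maximum
displacement, with ties broken by smallest relative area change and then
lowest label — deterministic without a global assignment step. Tracks
tolerate up to 2 missing frames (interpolated, flagged); flagged focus
frames are skipped entirely and do not count toward the gap limit.

A division appears as one object becoming two touching-then-separating
components whose summed area is within 30% of the parent. Daughter
centroids of a long rod sit up to half the parent's major axis away from
the parent centroid, so split candidates are searched within
`max(max_disp, parent_major/2 + max_disp)` rather than the bare linking
radius. The parent track ends at the split; division metrics are read from
the pre-split object; daughters start new tracks carrying a parent
reference. Lineage is not followed beyond this single split.

## Vacuole partitioning

The second (vacuole dye) channel is quantified at the frame immediately
before the first division — the last frame on which the cell is a single
object. The spore body is the disc of the particle's t0 radius placed
internally tangent at the pole opposite the outgrowth tip, intersected
with the cell mask; the outgrowth is the remainder, so the two fractions
sum to one exactly. The retained fraction is the sum of
background-subtracted channel-2 intensities (per-frame median outside all
masks; negative pixels clamped to zero) in the body over the whole cell.
Background subtraction can be disabled by passing a zero background.
Channels are assumed co-registered (single-camera acquisition). The
measure is invariant to any positive scaling of the channel, so display
normalization does not matter; computation always uses raw intensities.

## Synthetic timelapse generator

The generator produces scenes with complete ground truth so every stage of
the pipeline is testable without external data. Cells are mirror-symmetric
unions of a circular body and capsule-shaped germ tubes; all truth
kinematics (division frames, outgrowth lengths, analytic AR) come from 1-D
Simpson quadrature of the exact width profile, never from the renderer.
Rendering uses signed-distance functions with a one-pixel soft edge,
Gaussian blur (σ 0.7 px), and additive Gaussian noise on a bright-on-dark
uint16 scale; masks are center-of-pixel rasterizations of the same
geometry.

Study-condition defaults: spore radius 1.55 ± 0.1 μm (area ≈ 7.6 μm²,
within the 7–9 μm² range of real dormant spores), gamma-distributed
dormancy lag (mean 240 min, shape 16), 60 min of isotropic swelling,
10 min frame interval over 1,000 min, and no cell motion (agar-trapped).
Division is rendered as a septum gap from two frames after the AR
crossing, with daughters receding slightly so connected components
separate robustly.

**Geometry calibration.** Real germlings show ~4.5 μm outgrowths just
before a first division that is called at moment-ellipse AR > 3, and spore
bodies of 7–9 μm². These three facts over-determine the shape model: with
a +40% swollen body no tube width makes the moment AR reach 3.0 by 4.5 μm
of outgrowth. The generator therefore uses a +25% swelling gain and a tube
width of 1.766 μm, solved so the analytic AR of the mean cell crosses 3.0
at 4.45 μm of outgrowth; across the radius distribution, cells divide at
3.97–5.31 μm — safely inside "~4.5 μm" and below the 6 μm elongated
cutoff. The calibration is verified by a test that re-derives it from the
quadrature.

Phenotype kinematics: *normal* cells split two frames after the AR
crossing; *elongated* cells keep growing and split only at a drawn length
of 6.5–20 μm (their AR crossing — what division *timing* measures — still
happens near 4.5 μm, as for normal cells); *bubble* cells grow isotropically
(+2% area/frame) and split through the middle at 1.6× the swollen area,
while still circular; *bipolar* cells grow equal tubes from both poles and
cross AR 3 at ≈2.5 μm per side; *exploded* cells fragment into 3–5
sub-resolution pieces at 0.5–2.5 μm of outgrowth and vanish two frames
later; *dead* spores never change. Ground truth records both the AR-crossing
frame (`division_frame`) and the rendered split frame (`split_frame`);
for bubble cells, which divide without ever crossing AR 3, the division
frame is the split itself.

Scenes are laid out by rejection sampling of non-overlapping positions
(largest objects first) at a target packing fraction of 0.3, sized from
each cell's final extent. Per-cell random draws come from one stream
consumed in cell-ID order, so editing unrelated scenario fields does not
reshuffle cells; placement and noise use separate spawned streams.

The vacuole channel distributes a fixed per-cell total intensity so that
the body region (the same t0-radius tangent disc the analysis uses) holds
exactly the configured fraction before blur and noise, both of which
preserve the expectation.

The CFU generator draws replicate counts as survival(t) × starting CFU ×
log-normal noise, with exponential (default) or biphasic survival. Day 0
is required, as normalization is defined against it.

**What the generator does not emulate:** bright-halo/dark-interior
transmitted-light contrast (cells are smooth bright objects; the pipeline's
contract is shape-based and contrast polarity is configurable), uneven
illumination, stage drift, cell crowding and touching at t0, debris
morphology beyond simple capsule blobs, second divisions, and dye-uptake
kinetics. Passing tests therefore demonstrate correctness of the
measurement and scoring logic under the stated geometry and noise, not
robustness to every real-world imaging artifact — for real data the
learned-segmenter adapter (`load_external_masks`) is the intended entry
point, and downstream behaviour is identical for either mask source.

## Statistics

Longevity curves are normalized to day 0, summarized per replicate by the
trapezoidal AUC in days, and compared between conditions with a two-sided
two-sample t test on per-replicate AUCs (Student by default, Welch by
flag; both-groups-degenerate variance is handled explicitly: equal means
give t=0, p=1, unequal means p=0). Fisher's exact test uses the two-sided
probability-ordering convention — the sum of hypergeometric probabilities
of all tables at the observed margins no more probable than the observed
one, with a 1e-12 relative tie slack — implemented as an explicit
enumeration and checked in the tests against an independent `math.comb`
enumeration over every table with margins ≤ 30, and against scipy.
Division times are compared by classical one-way ANOVA (all-identical
values return F=0, p=1, flagged). Stress survival is 100 × treated/control
CFU per paired replicate, summarized as mean ± sd. No multiple-testing
correction is applied by default (per-comparison reporting); Bonferroni
and Benjamini–Hochberg are available.

## Numerical choices and degenerate inputs

- Quadrature step 0.002 μm; bisection tolerances 1e-5–1e-6 μm.
- Strict inequalities at every printed threshold (1.4, 3.0, 6 μm, 5
  frames).
- Otsu thresholding on a constant frame returns an empty labelling, not an
  error; components are 4-connected so a one-pixel diagonal septum still
  separates daughters.
- The optional watershed split of touching objects is off by default: the
  septum gap already yields separate components, and distance-transform
  watersheds oversegment rods. Mask erosion to counter systematic mask
  inflation is likewise exposed but off — areas are reported as measured.
- Standard error with n=1 is reported as 0 with n recorded.
- CSV floats are written at 9 significant digits; all tables round-trip.

## Validation problem sizes

The validation suite (`germquant.validation`, reported by
`scripts/acceptance.py`) uses: a 200-cell mixed scene for division-call
recovery; 60 spores + 40 debris for gate fidelity; 20 × 300-cell scenes
(70% viable, 800 min) for efficiency recovery against the exact binomial
interval; 5 × 50 cells for balanced phenotype classification; 100
two-channel cells for vacuole recovery; 200 and 1,000 simulations for the
power and size of the AUC t test; and the full margins ≤ 30 Fisher sweep
(162,315 tables). Scene durations and counts were chosen as the smallest
sizes at which the binomial/Monte-Carlo tolerances are meaningful.
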