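# Methods

## The measurement problem

The Modified Jebsen Test of Hand Function (MJT) is a timed tabletop test of
gross dexterity used with stroke patients: turning five cards, moving five
beans into a can with a teaspoon ("simulated feeding"), and stacking four
checkers. The clinically reported quantity is the completion time of each
subtest, conventionally taken by a therapist with a stopwatch. Stopwatch
times carry the reaction times of both the examiner and the subject, which
biases and blurs the measurement. This package implements an automated timer
that reads the start, end and total time of each subtest directly from a
top-down RGB-D recording (8-bit RGB + 16-bit depth in millimetres, 30 fps,
sensor ≈1200 mm above the table), together with the statistics used to judge
agreement between timing methods.

## Scene model

All detectors work in (row, col) image coordinates with the subject at the
bottom of the image ("proximal" = larger row index). A single planar scale
`mm_per_px` at the table plane converts between pixels and millimetres; at a
1200 mm mounting height a fixed scale is an adequate approximation of the
perspective projection, and every threshold the detectors use is stated in
millimetres.

**Table.** The tabletop depth is the median over all depth pixels (the table
dominates the view, so the median tolerates any object covering less than
half the image). A binary table/off-table split then locates the front edge:
a pixel is table-side when its depth lies strictly within 300 mm of the
tabletop plane, and the edge row is the per-column first table→off-table
transition in the bottom half of the image, summarised by the median across
columns. The one-sided split threshold ("300 mm below the surface") is
ambiguous about direction in a top-down view — the subject's body is nearer
than the table, the floor beyond the edge is farther — so the implementation
uses the symmetric band, which handles both. The edge row is the first
off-table row; a hand pixel at the edge row is at 0 mm.

**Board and ridge.** Pixels more than 50 mm above the tabletop are grouped
4-connected; a group whose longest bounding-box extent falls within ±20%
(inclusive) of the 508 mm ridge length is the ridge. Zero candidates is a
"ridge not found" error; two or more is an "ambiguous ridge" error rather
than a guess, because a silent misdetection would corrupt every downstream
time. The board footprint is reconstructed geometrically — a rectangle along
the ridge's principal axis extended half of the 286 mm board width to each
side — because the board top is only 19 mm above the table, near the noise
floor of a consumer depth sensor. The board surface depth is measured from
footprint pixels when enough are clearly above the table, otherwise the
nominal 19 mm offset is used.

**Open can.** The can is found once, in the first frame, by the Circle Hough
Transform (scikit-image's gradient accumulator) over a configurable radius
window inside a 300×300 mm search window in front of the board. Among the
candidate circles the one whose diameter is closest to the 100 mm can
diameter wins; ties go to the stronger accumulator vote. The default radius
window is 10–80 px so that the 25 px radius of the can at the default
2 mm/px scale lies inside it.

**Depth reference.** For the stacking subtest a per-pixel mean over the
first 15 frames serves as the static background; elevation is measured as
(reference − current depth).

## Hand tracking

The hand is any 4-connected group of ≥50 pixels (inclusive) more than 30 mm
nearer to the sensor than the surface directly beneath each pixel — table
top, board top or ridge top depending on the pixel's region — and inside the
table region. If several groups qualify (e.g. a forearm split by occlusion)
the largest is taken and a diagnostic logged. All timing uses the *distal
centroid*: the centroid of the hand pixels within 10 mm (along the row axis)
of the hand pixel farthest from the front edge. Frames without a qualifying
group are explicit gaps; gaps up to 5 frames are linearly interpolated in
distance series, longer gaps are an error.

## Event detection

**Cards.** Marker-side-down cards show a green marker only after being
flipped. Green pixels (R and B strictly below G), a 5×5 median filter,
4-connected groups of ≥10 pixels, and exclusion of groups whose centroid
lies within 10 mm of any hand pixel yield per-frame marker centroids.
Centroids within 5 mm join the nearest track; tracks whose running-mean
centroids drift to within 5 mm of each other are merged (centroids that
close are one card, and unmerged duplicates — easily seeded by a partially
occluded marker — would split the support count between them). A track seen
in ≥15 distinct frames is a confirmed turned card. Tracks are never deleted,
so the count is absorbing.

**Beans.** Consecutive RGB frames are converted to grayscale (unweighted
channel mean), differenced, and thresholded at 10% of the 0–255 range
(strictly above 25.5); hand pixels are removed from the mask (the hand would
dwarf any bean in the difference image, so it must not count). Groups whose centroids are within 5 mm are merged. A bean drop is
a merged group of 5–50 pixels, shorter than 15 mm, centred inside the can
rim, while the hand is within 50 mm of the rim. After a drop the detector
disarms and re-arms only when the hand returns to within 30 mm of the ridge,
enforcing one detection per bean.

**Checkers.** Inside the board footprint, pixels elevated more than 5 mm
above the depth reference are grouped; groups with extent between 0.5 and 2
checker diameters (15–60 mm, inclusive), centroid on the board, and more
than 30 mm from every hand pixel are logged with their mean height above the
board surface. A height h maps to a stack count n ∈ {1..4} by the intervals
(D ± 0.5·D)·n with D = 6 mm checker height; these intervals overlap for
n ≥ 2, so among the intervals containing h the n with expected height D·n
nearest to h wins, ties to the smaller n. Heights outside every interval are
ignored.

## Start and finish rules

All three subtests share one movement-onset rule: find the first frame c at
which the hand's distance to a subtest-specific reference satisfies the
crossing condition, then walk backwards through the contiguous run of frames
whose per-frame displacement toward the target is ≥3 mm/frame (inclusive);
the earliest frame of that run is the start. Crossings: card turning —
distance to the table edge exceeds 127 mm (the proximal card edge); feeding
— exceeds 147 mm (20 mm past the proximal board edge); stacking — distance
to a point 15 mm in front of the middle of the board's proximal edge falls
below 63.5 mm.

Finishes: card turning ends when the fifth marker track reaches 15
supporting frames (an optional `end_latency_frames` back-dates the
confirmation latency; default 0, and the simulator's ground truth uses the
same confirmation semantics, so the two agree); feeding ends at the first
frame with five recorded drops *and* the hand more than 20 mm outside the
rim; stacking ends at the fifth consecutive frame with a fourth-interval
detection. A recording that ends before the finish condition is "subtest
incomplete", never a guessed time.

## Synthetic scenes and ground truth

There are no public recordings of this instrument, so the package ships a
simulator that renders the standard layout at a scripted frame rate and
scale: cards 127 mm wide with 51 mm gaps, 127 mm from the edge; the board
127 mm from the edge with the 508×13×51 mm ridge at its middle; the 100 mm
can centrally in front of the board; four 30 mm checkers in a row touching
the board. The hand is a rigid 80×120 mm ellipse whose distal tip follows
interpolated waypoints at a scripted height — every detector uses only
connected-pixel geometry, so articulation adds nothing. Events are scripted:
card flips swap the card face to the marker face, bean drops flash a small
bright blob inside the (dark) can opening for one frame, checker placements
raise a 30 mm disc on the board by 6 mm per checker and remove one source
checker. Depth noise is iid Gaussian (default σ = 2 mm, clamped at 0) and
RGB noise iid Gaussian (default σ = 3) per channel.

Simplifications a real recording would not share: the can contributes no
depth structure (only its dark opening in RGB), the hand is rigid and always
above its own surroundings, surfaces are uniform Lambertian colors, and
noise is white rather than the structured speckle of a structured-light
sensor. Neutral surfaces are warm-tinted (R > G > B) as real wood and
cardboard are; an exactly channel-equal gray would let iid noise flip
isolated pixels into the strict green mask at high rates, which says more
about the noise model than about the detector. Passing the recovery tests
therefore demonstrates the correctness of the detection logic and its
robustness to sensor-scale white noise — not photometric robustness to
shadows, lighting changes or occlusion by the therapist.

Ground truth is computed from the script alone, mirroring the detection
rules on the scripted geometry (the same onset rule on the
noiseless trajectory; marker-visibility confirmation from hand–marker
clearance; rim-retreat and stack-clearance conditions); rendered pixels
never feed back into it, so end-to-end tests are not circular. Fixture
recordings default to 320×240 at 4 mm/px, 150–260 frames, which keeps a full
three-subtest sweep of 60 recordings within a few minutes on one CPU;
640×480 at 2 mm/px is supported and used for the geometry self-consistency
test.

## Agreement statistics

Two timing methods are compared with Bland–Altman limits of agreement for
repeated measures in which the measurand itself changes between repetitions
(a practice effect). Differences d are grouped by subject and decomposed by
one-way ANOVA with subject as the factor:

    sd² = MS_within + max(0, (MS_between − MS_within)/m0),
    m0 = (N² − Σnᵢ²)/((a−1)·N),

bias = mean of d, LoA = bias ± 1.96·sd. With one observation per subject
this reduces exactly to the classic formula. Negative between-subject
component estimates are truncated at zero. Bias significance is a one-sample
t test on per-subject mean differences; variance equality is classic
(mean-centred) Levene; test–retest change is the Wilcoxon signed-rank test
reported as median (IQR). For n ≤ 25 the signed-rank null distribution is
computed exactly by dynamic programming over doubled midranks (zeros
dropped), because the common normal approximation is poor at the n = 11 of a
typical clinical sample; above 25 a normal approximation is used. All p
values are Bonferroni-adjusted; the family size defaults to 3 (the three
method pairs, or the three subtests for retest comparisons) and is a
parameter, since the convention is not fixed by the analysis itself.

The synthetic timing panel draws subject-level true times (SD 1 s around an
8 s base, −1 s for the less affected hand, minus a practice effect on the
second repetition) and adds per-method bias, a subject-specific method
offset (between-subject SD) and observation noise (within-subject SD); the
automatic method's default bias is +0.2 s and the therapist's −0.35 s, a
typical human reaction time. Parameter recovery on 200 subjects checks the
ANOVA decomposition against the injected components.

## Numerical choices

- Group "length" is the longest bounding-box side times `mm_per_px`, so an
  N-pixel axis-aligned bar measures N·mm_per_px; the ridge acceptance band
  is inclusive with a 10⁻⁶ mm guard against floating-point boundary error.
- All size thresholds are inclusive at the printed number (50 hand pixels,
  10 marker pixels, 5–50 bean pixels, 15 support frames); "less/more than"
  thresholds are strict (30 mm elevation, 25.5 gray levels, 15 mm bean
  length, 5 mm checker elevation, 30 mm hand clearance).
- Millimetre-to-pixel counts round half-up.
- Identical inputs produce bit-identical outputs: no unseeded randomness
  anywhere in the pipeline.

## Known limitations

- A fixed planar pixel scale ignores perspective: objects 100 mm above the
  table are magnified by ~9% at a 1200 mm mounting height. The thresholds
  tolerate this, but a per-pixel depth projection would be needed for
  sub-millimetre geometry.
- The edge detector assumes a roughly horizontal front edge; a strongly
  rotated camera would need rectification first.
- The card-confirmation latency (≥15 frames ≈ 0.5 s after the physical
  flip) is inherent to the confirmation rule; both the detector and the
  simulator's ground truth include it, but against a human-annotated "card
  placed on table" time it appears as a positive end-time bias unless
  `end_latency_frames` is used.
- The simulator does not model occlusion by a second person, specular
  highlights, or depth shadows.
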