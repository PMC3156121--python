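# Methods

## The body model and synthetic kinematics

The larva is a chain of 11 segments (T1–T3, A1–A8), each described per
frame by a centerline length and a heading turn. Defaults: body length
2 mm, 11 equal rest segments, maximum width 0.35 mm with the half-width
tapering as `0.5·w·sqrt(sin(pi·u))` in the rest arc-length fraction `u`
from the head — a rounded (roughly parabolic) tip at both ends, like the
animal, which the curvature-based head/tail detector needs and which keeps
the near-triangular shape of T1 and A8. Each segment is subdivided four
times; left/right boundaries are normal offsets of the subdivided
centerline. The plane is y-up millimetres; leftward turns are positive.

**Peristalsis.** A contraction pulse (raised cosine, half-width 2 segments
of the tail-based body coordinate) travels from the tail tip (x = 0) to the
head tip (x = 11) once per cycle; wave rate defaults to 1.2 cycles/s.
Segment lengths scale by `1 − 0.15·pulse`. The wave rate is a free choice:
it is picked so that forward speed = displacement/wave × body length × wave
rate ≈ 0.31 mm/s, the reported scale of run speed; the displacement per
wave, 0.13 body lengths, is applied as a constant tail translation per
cycle, so completed cycles displace exactly 0.13 BL regardless of frame
quantization.

**Fluorophore conservation.** Rendered quadrant intensity is
`calibration × rest area / current area`, so segment contraction brightens
(~18% at the default 15% contraction) and total signal per quadrant is
constant — the property that makes mean intensity a contraction readout.
Rendering adds Gaussian noise with sd 2% of the calibration level
(cameras differ; this is a plausible CCD regime) and re-centres each frame
on the body centroid, recording the stage position, as a tracking stage
would.

**Head sweeps.** A sweep distributes a total bend over the pivot segments
with a raised-cosine profile centred on A1 (half-width 2.3 segments, which
keeps measurable asymmetry within T3–A3 with its peak on A1). The profile
half-width widens smoothly to 3.5 segments for total bends above ~86°,
because a narrow profile would demand per-segment turns that exceed the
geometric limit (inner boundary length reaching zero) at large amplitudes.
The bend amplitude is solved numerically (bracketed root find) so that the
*operational* bend angle θ — computed from the synthetic centerline with
exactly the construction the vision stage uses — reaches the commanded
sweep amplitude; sweep ramps are cosine, 1 s rise, 0.25 s hold.

**Straightening.** After the accepted sweep the bend amplitude is held
fixed while the profile's centre slides tail-ward by 2 segments per
peristalsis wave; normalization uses the full (unbounded) profile mass, so
the on-body bend decays naturally as the bend is carried off the tail —
this is what produces the retrograde progression of the asymmetric region
seen in the kymographs, at the configured 2 segments/wave. Waves resume at
the tail for sweeps below 90° and inside the asymmetric region (0.7
half-widths posterior of the pivot centre, where the asymmetry is still
well above the detection threshold) for larger sweeps; a wave initiated
within the bend does not actuate segments posterior of its start. During
straightening the head direction is held fixed and the tail-base heading
rotates to meet it, so the run resumes along the direction the head chose.
The final relax phase (0.75 s) ramps any residual bend to zero.

Because θ is an operational quantity (accurate only while the bend lies
between the midpoint and ¾-point), it slightly overshoots the commanded
amplitude early in straightening and under-reports posterior bends late in
straightening; straightening (sustained |θ| < 20° for 1 s) is therefore
typically reached in 3 waves for small sweeps and 3–5 for large ones.

**Behavior statistics.** Turn onsets are an inhomogeneous Poisson process:
rate 3.2/min while dT/dt > 0 and 3.8/min while dT/dt < 0 by default (the
wild-type temporal-gradient values). An onset arriving during a maneuver
is deferred to the maneuver's end plus a 1.5 s straightened gap — counts
per unit total time are preserved, at the cost of a slight blurring of
phase attribution near warming/cooling boundaries (a few percent on the
recovered rates). Onsets snap to the next peristalsis-cycle boundary, so
head sweeping always follows the completion of the running wave. Sweep
amplitudes come from a normal with phase-specific mean (warming 53°,
cooling 60° by default; sd 10°) truncated to [45°, 150°], with the
location parameter solved so the truncated mean equals the configured
mean. The lower cut reflects the operational definition of a reorientation
maneuver: events are defined by the 40° flag, so modeled maneuvers are the
flagged ones, with a margin that keeps them reliably detectable. Each
non-final sweep is "rejected" with probability logistic in −dT/dt
(baseline 0.2; cooling raises rejection), and rejected sweeps transition
directly into the next sweep without an intervening wave.

Event-level track synthesis (for run-speed and thermotaxis statistics)
moves a centroid at the run speed along a persistent heading, turns it by
the accepted sweep angle after each maneuver, and adds 1 µm measurement
jitter; population gradient tracks drift at the configured speed until a
plateau (preferred temperature reached) with independent position jitter.

## The vision stage

Per frame: Otsu threshold (or fixed), one erosion + one dilation with a
radius-2 disk, largest connected component, boundary resampled to 800
vertices at equal arc length and smoothed with a circular Gaussian of sd
0.5% of the vertex count. Curvature is the turning of the tangent angle
across a centred window spanning 20% of the boundary length, positive for
convex protrusions.

At this window size each tip appears as a broad curvature *plateau* (the
window integrates the tip's whole turning), and a strongly bent body adds
a comparable maximum on the bend's outer side. Head/tail localization
therefore works in three steps: (1) candidate tips are all local maxima of
the wide-window curvature plus two candidates seeded at the contour points
nearest the predicted previous-frame tip positions (constant-velocity
prediction — the head moves several px/frame mid-sweep); (2) each
candidate is refined to the maximum of a fine-scale (2.5% window)
curvature nearby, then to the cap-top centroid of the unsmoothed contour
(robust to the pixelated cap's orientation; the unsmoothed contour is used
because Gaussian smoothing recedes the tips); (3) the head/tail pair is
the candidate pair, separated by ≥ 25% of the perimeter, minimizing summed
distance to the predicted priors. On forward crawling this tracks both
tips to ~0.3 px; in mid-maneuver postures errors of several px occur when
the bend's bulge abuts a tip.

The centerline splits the outline at head and tail, resamples both arcs to
101 equal-arc-length points and takes pairwise midpoints. θ uses fractional
positions measured from the tail (the ¾-point is anterior), after flipping
to a y-up frame so leftward is positive. Sweeps are flagged at |θ| ≥ 40°
with hysteresis release at 20° (the flag threshold alone would chatter);
an event also ends when θ changes sign. The event's `peak_frame` is the
*first* frame near the peak, because θ plateaus at its maximum while
straightening already shifts the asymmetric region.

## Segment metrics

The 20 annotated boundary points (ground truth standing in for the
hand-clicked points; automatic boundary detection is out of scope) are
projected onto the outline polygon with a continuous arc coordinate
(vertex-snapping alone would inject several percent error into ~18 px
segment arcs); ordering along each side is validated with a 2%-of-perimeter
slack for projection jitter, and grossly shuffled or >5 px misregistered
annotations are rejected. "Boundary length" is the outline arc length of
each segment's side between its bounding points — the quantity entering
a = ln(L_R/L_L). Quadrants split each segment polygon by the chord between
the side-arc midpoints and by the local midline (chord midpoints); means
are over enclosed pixels, with a vertex-pixel fallback for sub-pixel tip
quadrants.

Kymographs use frame 0 as the reference on a first pass; after wave
detection the reference is re-chosen as the inter-wave frame minimizing
total |fractional length change| and metrics are recomputed once. On
noiseless mid-body segments (T2–A7) measured lengths and quadrant means
match truth to well under 2%; T1 and A8 are systematically less reliable
because small tip-localization errors are a large fraction of their short,
strongly tapered sides — the same artifact the intensity/length
correlation shows at the body ends.

## Events

Waves are chains of per-segment contraction peaks (fractional length
negated, or fractional intensity) moving strictly head-ward. At 8 Hz with
1.2 cycles/s the true inter-segment lag is ~0.6 frames, so the chaining
window is [0, 3] frames per step (one missing segment may be skipped with
a doubled window) and chains need ≥ 4 segments. Per-wave displacement is
the tail displacement projected on the mean body axis from one wave's
onset to the *next* wave's onset: waves run back to back and chains can
terminate at T2, so peak-to-peak spans undercount the cycle. Displacement
is normalized by the nominal body length from the configuration (known
experiment metadata); the video-derived estimate is also computed but runs
~3% short because smoothing recedes the tips.

The asymmetric region is the contiguous run of segments with |a| ≥ 0.05 at
the sweep's peak frame; its posterior extent, re-measured after each
straightening wave, yields the segments-carried-per-wave estimate.
Maneuvers group consecutive sweeps not separated by a sustained
straightened interval (|θ| < 20° for ≥ 1 s); `waves_to_straighten` counts
waves initiated between the accepted sweep's peak and the first sustained
straightened frame (counting from the sweep's *offset* would always give
zero, since the event only releases once the body is nearly straight).
Initiation is classed `tail` for A7/A8, `within_bend` inside the region,
`ambiguous` otherwise.

## Statistics

Simple OLS is closed-form; the slope standard error is
`sqrt(SSE/(n−2)) / sqrt(Sxx)` and the implementation is tested for exact
agreement with statsmodels. Thermal phases use dT/dt of the boxcar-smoothed
(1 s) temperature against ±0.001 °C/s; the labels partition the trace
exactly. Turn frequency is count per phase-minute with Poisson SE;
first-sweep size is the mean peak |θ| of each maneuver's first sweep with
SE = sd/√n (per-event, not per-animal). Binned initiation probabilities
use m/n with the binomial SE and 30° bins by default, ambiguous cases
excluded and counted separately. Forward speed averages frame-to-frame
centroid speed outside maneuver intervals. Thermotaxis speed fits the
population-mean gradient position by OLS, truncated at the start of the
first window (60 s) whose drift falls below 10% of the initial drift. The
unnamed phase-comparison test is Welch's unequal-variance t-test by
default, with a permutation alternative.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analysis exploits — conserved
fluorophore, back-to-back tail-to-head waves, an A1-centred pivot, the
retrograde march of the asymmetric region, phase-biased turn statistics —
with clean geometry, additive Gaussian noise, and no occlusions, debris,
uneven illumination, body rolling, or self-overlap. Passing tests
therefore validate the algorithms and their statistical estimators, not
robustness to real-video nuisances; the 20-point annotation is exact where
a human clicker is ~1–2 px noisy. Problem sizes in the test-suite and the
reproduction script (a 5-minute run video, ~8 simulated hours of
event-level behavior, 10 rendered maneuvers, 20 population tracks) were
chosen so sampling error sits well below the effects being recovered.

## Known limitations

- T1/A8 boundary lengths inherit tip-localization error (acknowledged
  artifact of triangular end segments).
- Tip tracking degrades to a few px when a tight bend abuts a tip; frames
  whose annotation cannot be registered are dropped from the metrics.
- θ is operational: it saturates for bends near the tail, which compresses
  the spread of `waves_to_straighten` between small and large sweeps.
- Turn-rate recovery carries a small (few percent) phase-boundary blur
  from the maneuver refractory period.
- Self-overlapping (curled) postures and multi-animal scenes are out of
  scope; the centerline stage signals arcs of grossly unequal length
  instead of guessing.
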