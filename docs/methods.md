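# Methods

This note documents the models and procedures flywalk implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Arena, epochs and units

Coordinates are arena-centered Cartesian cm; time is 0-based seconds at a
uniform frame rate (30 frames/s by default); intervals are half-open
[start, end). The arena is a disc of radius 3.2 cm with a nominal odor-zone
radius of 1.2 cm; a conservative odor-boundary radius of 1.9 cm can be
configured for undiluted attractant, where flies stop short of the nominal
rim. The *before* epoch is [0, 180) s. The *during* epoch is
entry-conditioned: if the fly is inside the odor zone when the odor switches
on at 180 s it starts at 185 s (5 s delivery latency); otherwise it starts
at the fly's first subsequent zone entry, and a fly that never enters is
excluded with a logged reason. *During* ends at 360 s; any remainder is
*after*.

## Tracking

The background is the pixel-wise mean frame; subtraction leaves the fly as
the only bright object. Per frame we threshold (Otsu by default, fixed
override available), keep the largest connected bright component, and take
its intensity-weighted centroid. A frame is *missing* when nothing stands
out from the robust noise floor (brightest pixel < 6 MAD-sigma); more than
20% missing frames aborts the track. Frames whose implied speed from the
last accepted position exceeds `jump_limit` are flagged as misassignments
and repaired by linear interpolation between accepted anchors.

`jump_limit` defaults to 3 cm/s. The printed error rule for this assay
("instantaneous velocity exceeded 3 mm/s") cannot be taken at face value —
ordinary runs exceed 3 mm/s — and is most plausibly a per-frame displacement
of 3 mm, i.e. 9 cm/s at 30 frames/s; the parameter is exposed in the
configuration rather than silently reinterpreted.

Mean-frame backgrounds assume the fly moves; on clips in which the fly is
stationary for most of the recording the background absorbs the fly and
tracking degrades. This is intrinsic to the method, not a defect of this
implementation; tests use clips long enough for normal locomotion.

## Smoothing and kinematics

Positions are smoothed with a centered moving average, 10 frames (0.33 s)
by default. An even-length boxcar centered on a sample has an inherent
half-frame lag; we therefore use the exact centered form (kernel of length
window + 1 with half-weight endpoints), which passes linear motion through
unchanged. Edges use shrunken windows.

Speed is the displacement between consecutive smoothed positions times the
frame rate. Heading is the direction of that displacement; below the
angular-validity floor (0.2 cm/s) the heading *carries over* from the last
valid frame and the angular speed is reported as NaN. When the fly speeds
up again, the first valid frame's angular increment is the net heading
change across the slow gap. This bridging matters: at a sharp corner the
smoothed speed dips, and discarding those frames' rotation outright would
make precisely the largest turns invisible to the detector.

## Run/stop segmentation (Schmidt trigger)

Two thresholds on speed: strictly below 0.05 cm/s ⇒ stop, strictly above
0.1 cm/s ⇒ run, in between the previous state continues; leading dead-band
frames take the first decisive state. The implementation is a vectorized
forward-fill/backfill over decisive frames and is verified against a
brute-force per-frame state machine on every 3-level sequence up to length
12 (~8·10⁵ cases).

Known, accepted biases (shared with any implementation of this recipe):
stops shorter than ~3 frames go undetected, and detected episode boundaries
lag the true ones by 1–2 frames. Because the walker accelerates and
decelerates over ~10 frames rather than stepping, these lags are nearly
equal at episode starts and ends and episode *durations* are close to
unbiased (see "Recovery" below).

## Turn classification

For each frame we take S = |net angular displacement| over the 5-frame
window ending at that frame (angular displacement = angular speed / frame
rate, NaN ⇒ 0, which together with heading bridging makes S the net
rotation across the window). S > 0.3 rad marks a turning frame, S > 1.3 rad
a sharp frame; contiguous sharp frames — and sharp segments separated by
less than one window, which share rotation from the same maneuver — merge
into one event placed at the frame of maximum S. Only run frames carry turn
labels. The signed-sum form (rather than the sum of magnitudes) is chosen
so left/right symmetry holds exactly and diffusion jitter cancels; the
window slides every frame.

Geometry constrains what is detectable: a single-frame heading jump of θ,
after 10-frame smoothing, yields a maximal 5-frame net rotation of roughly
0.6–0.7·θ, so jumps below ≈ 2 rad cannot cross the 1.3 rad threshold, and
turns executed while walking slower than the 2 mm/s floor are invisible by
definition. The generator's default sharp-turn angle (2.6 rad ≈ 150°, a
border re-entry turn) and the placement of turn events in the cruising
phase of runs reflect this: sharp turns are discrete reorientations of
steady walking. Recovery tests score events away from wall contacts (a
wall reflection turns the path without a discrete labeled event) and treat
true events closer than 10 frames as one maneuver, since a net-rotation
statistic cannot resolve — or even see, if they cancel — back-to-back
jumps.

## The 17 motor parameters

Per fly: attraction index; time inside per transit; time to return; radial
density shift; speed inside; speed outside; speed crossing inside; speed
crossing outside; run duration; stop duration; run probability in; run
probability out; angular speed inside; angular speed outside; smooth turns
in; smooth turns out; sharp turns at boundary.

Definitions and conventions:

- Change-type parameters are (during − before)/before per fly; run/stop
  statistics are during/before ratios; turn fractions are during-only
  (smooth-turn frames / run frames, inside and outside; sharp turns within
  the 2 mm border ring / all sharp turns). A zero or missing before-period
  baseline makes the parameter NaN with a recorded reason; flies are never
  imputed, and group tests handle NaNs pairwise-complete.
- The attraction index uses **raw time** inside the zone per period, not
  fractional occupancy. With the entry-conditioned during start this is the
  self-consistent choice: the guaranteed entry dwell at the start of
  *during* is offset by the period being shorter, and null cohorts center
  on 0; fractional occupancy would carry a positive bias of order
  dwell/period.
- Time inside per transit and time to return are medians over complete
  transits/outside intervals within the period; transits use a 2-frame
  debounce against single-frame boundary chatter.
- Crossing speeds average speed in the 1–2 s window after each crossing,
  as the mean of per-crossing means.
- Run/stop durations are medians of episodes clipped to the period. Median
  episode durations measured in a finite window are mildly biased low for
  heavy-tailed episode laws (long episodes are preferentially truncated);
  at the default scales this bias is ≲ 8% and is part of what the recovery
  tests measure.
- The radial-density scalar in the 17-vector is the normalized change in
  mean radial distance; the full 12-bin area-normalized radial profile is
  attached to the feature vector as auxiliary output (the 17-vector must be
  scalar-valued for PCA/CVA).

Auxiliary profiles: before-subtracted crossing-aligned speed traces in
160 ms bins over ±3 s; cohort occupancy time courses in 5 s bins (transit
statistics in 15 s bins); and for the point-source assay (10 cm arena) the
per-fly max-normalized mean speed in 10 concentric bins.

## Statistics

- **Rank-sum panel**: two-sided Wilcoxon rank-sum per parameter
  (exact for small tie-free samples), flagged at the Bonferroni cutoff
  α/m = 0.05/17 ≈ 0.003. Fully tied degenerate data reports p = 1.
- **Correlation screen**: Pearson r for all 136 unordered pairs,
  pairwise-complete; the significance criterion defaults to unadjusted
  α = 0.05 (switchable to Bonferroni across pairs) — under the null this
  flags ≈ 0.05·136 ≈ 7 pairs.
- **PCA**: eigendecomposition of the covariance of complete-case rows,
  z-scored by default since the 17 parameters mix ratios and normalized
  changes on different scales.
- **CVA**: W = pooled within-group covariance, B = group-size-weighted
  between-group covariance of group means about the grand mean. Axes solve
  the symmetric generalized problem B a = λ (W + ridge·I) a — numerically
  equivalent to eigendecomposing W⁻¹B but immune to spurious complex
  eigenvalues — normalized to unit within-group variance. For g groups
  there are g − 1 canonical dimensions. If W is singular a minimal ridge is
  applied automatically and recorded on the results.
- **Permutation test**: group labels are shuffled (multiset preserved),
  the CVA refitted per shuffle with the same ridge as the observed fit, and
  the CV1 median group distance recorded. The primary p is the fraction of
  shuffled distances *strictly greater* than the observed one (ties count
  as non-exceeding); the (k+1)/(n+1) convention is reported alongside, and
  seed and shuffle count are always logged. The default is 50,000 shuffles;
  calibration suites use 1,000 per dataset across 200 null datasets, which
  bounds the rejection rate tightly enough at far lower cost. With fewer
  complete rows than parameters the observed and shuffled fits are equally
  overfit and the test remains calibrated, but axes are not interpretable.

## The synthetic walker

A semi-Markov run/stop process: alternating episodes with log-normal
durations parameterized by their configured median and shape σ_log = 0.8
(heavy right tails — occasional runs and stops far longer than the median,
as real records show; only medians are constrained, so the law itself is a
modeling choice). Within runs, a per-episode cruising speed is drawn
log-normally (median = configured run speed, σ = 0.3) and approached
through linear 10-frame accelerate/decelerate ramps; heading diffuses with
variance `heading_diffusion`/frame-rate per frame; sharp-turn events fire
as a Poisson process during the cruising phase, jumping the heading by
±`sharp_turn_angle`, with an inward-directed event drawn once per entry
into the border ring when `boundary_turn_bias` applies. At the wall the
heading reflects about the tangent, or aligns with it with probability
`wall_attraction`, which also damps heading diffusion within a 1 mm
boundary layer (wall-following). Parameters switch instantaneously between
the four contexts {before, during} × {inside, outside}; a context switch
resamples the remaining episode only when the parameter block actually
differs (identical blocks are one behavioral context — resampling across a
boundary between equal blocks would fragment episodes and bias measured
durations).

Defaults are the assay's scales: before-period run median 4.81 s, stop
median 0.67 s, run speed 0.57 cm/s; the attractant-like during-inside block
uses run 1.0 s, stop 0.3 s, speed 0.18 cm/s, more frequent sharp turns, and
a border-turn bias of 0.35. `wall_attraction` = 0.8 reproduces
edge-dwelling (radial density maximal in the outermost bins before odor)
while leaving zone visits frequent enough that every fly accrues transits
in both periods. Chosen once, these defaults are the study conditions for
all tests.

What the generator does **not** emulate: no plume structure (odor is a
binary zone), no anemotaxis, no body orientation or pose (the walker is a
point), no multi-fly interaction, no inter-fly parameter heterogeneity
beyond sampling noise, no tracking dropouts other than rendered noise.
Passing recovery tests therefore show that the pipeline measures what this
class of walker generates at realistic scales — not that real flies obey a
semi-Markov model (a hidden-state generative fit is explicitly a
non-goal).

Note a deliberate asymmetry of scope: the attractant-like during-inside
speed (0.18 cm/s) sits *below* the 0.2 cm/s angular floor, so turns inside
the zone during odor are largely invisible to the turn detector. This
mirrors the measurement physics of the assay itself; turn-recovery
properties are therefore stated for cohorts walking at the before-period
speed.

## Video rendering

The fly is a Gaussian blob (e-folding radius 1.5 px, peak 1.0) on a static
textured background (0.1 ± 0.02) plus i.i.d. Gaussian noise (σ = 0.02),
72×72 px at 1 mm/px by default — small enough to keep test videos cheap,
large enough that the 6.4 cm arena fits with margin. Round-trip accuracy at
these defaults is ~0.07 px RMS, comfortably under the 0.5 px requirement.

## Problem sizes in the test suite

Suites run on synthetic cohorts of 30 flies × 3 seeds for recovery
properties, 200 replicate datasets × 1,000 shuffles for permutation
calibration, exhaustive 3-level sequences to length 12 for the trigger
oracle, 100 random instances for the CVA oracle, and 10 rendered 30 s clips
for the tracking round trip; these sizes give comfortable statistical
margins for every stated tolerance. The acceptance script uses the same
sizes with seeds derived from its `--seed`.

## Known limitations

- Episode-duration medians in finite epochs are biased low by truncation
  (≲ 8% at default scales); ratios cancel most but not all of it.
- Per-fly ratio parameters are noisy (tens of episodes per period); cohort
  medians of ~90 flies carry a few-percent standard error, so recovery
  checks quote 15% tolerances.
- The tracker is single-animal and centroid-only by design; identity
  maintenance, pose and multi-camera stitching are out of scope.
- CVA axes with fewer complete rows than parameters are regularized and
  not interpretable; the permutation p remains valid.
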