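# Methods

## Pipeline

A recording is an array of 3-D joint positions (meters) over frames at a
fixed rate `fps`, covering a 17-joint upper-body skeleton (spine base,
spine mid, spine shoulder, neck, head; shoulder, elbow, wrist, hand,
hand tip and thumb per side). Frame `i` covers the half-open time
interval `[i/fps, (i+1)/fps)`; act windows are half-open in seconds and
convert to frames by `floor(t · fps)`, so adjacent acts never share a
frame.

Processing order: (1) smooth every coordinate of the whole recording,
(2) cut out each act, (3) compute features per act. Smoothing precedes
segmentation so act boundaries stay aligned with the video frames and
every act sees the same filtered signal.

### Smoothing

A Savitzky–Golay filter with a 15-frame window and a degree-5 local
polynomial, applied independently per coordinate. The filter passes any
polynomial trajectory of degree ≤ 5 unchanged at frames where the
window does not touch the edges, which is what makes the synthetic
ground truth exactly recoverable (minimum-jerk segments are quintics).
Edges use mirror padding: the output keeps the input length, at the cost
of biased estimates within 7 frames of either end. Missing (untracked)
samples are a hard error here rather than being interpolated — filtering
across a tracking gap would invent positions; callers must trim or fill
gaps explicitly first.

### Speed

Per-joint scalar speed is the Euclidean norm of the central-difference
derivative of the smoothed positions (one-sided at the two boundary
frames), in m/s. Central differences are symmetric and second-order
accurate; their residual bias at a velocity peak is about
`2.7 · v_peak / n²` for an `n`-frame bell, under 1% for strokes of 17
frames or more.

## Features and their parameters

All thresholds live in one `FeatureConfig` (flat key-value YAML from the
CLI). Defaults:

| parameter | default | meaning |
|---|---|---|
| `submovement_min_peak` | 0.2 m/s | minimum velocity-peak height (inclusive) |
| `submovement_min_separation` | 8 frames | minimum distance between retained peaks (inclusive) |
| `boundary_speed` | 0.05 m/s | near-zero threshold for submovement on/offsets |
| `hold_max_displacement` | 0.01 m/frame | per-frame stillness threshold |
| `hold_min_duration` | 0.300 s | minimum hold length |
| `velocity_bins` | 7 | dataset-relative peak-velocity categories |
| `dominant_hand` | R | hand used for amplitude and peak velocity |

**Submovements.** Candidate peaks are strict local maxima of one hand's
speed series. Those at or above `submovement_min_peak` are retained
greedily in descending height — an earlier peak wins an exact height
tie — subject to every retained pair being at least
`submovement_min_separation` frames apart. Each retained peak's onset
and offset are found by scanning outward to the first frame below
`boundary_speed` or the first deceleration-to-acceleration reversal
(local speed minimum). The detector is checked against an independent
brute-force enumeration on random series; both thresholds are read as
inclusive ("minimum height", "at least 8 frames").

**Holds.** A consecutive-frame displacement is *still* when every hold
joint (hand, thumb, elbow, shoulder × both sides) moved less than
`hold_max_displacement`. A maximal run of `k` still displacements spans
`k + 1` frames; runs spanning at least `ceil(hold_min_duration · fps)`
frames (9 at 30 fps) are holds. Counting the frames spanned — rather
than the displacements — is what makes nine stationary frames at 30 fps
exactly one 300 ms hold and eight stationary frames none. Stillness is
judged per consecutive frame, not cumulatively over a window, so the
9-frame arithmetic is exact.

**Vertical amplitude.** Per frame the dominant hand's height is
compared with the spine-mid, neck and head landmark heights of the same
frame (category 1 below spine-mid, 2 below neck, 3 below head, 4 at or
above head); the act's value is the frame-wise maximum, so a leaning
trunk is handled. If the landmarks are out of vertical order in more
than half the frames a posture warning is issued but the value is still
returned. The head landmark is the joint center; a crown offset can be
emulated by raising the configured landmark.

**Peak velocity and binning.** The act's peak velocity is the maximum
of the dominant hand's speed series. Binning into `velocity_bins`
categories is dataset-relative equal-frequency (quantile) binning over
all acts in the table — category `ceil(rank · k / n)` with minimum
ranks, so exact ties share the lower bin; an equal-width mode over the
observed range is available as a config alternative. Bins are assigned
only when a table holds at least two acts, since a dataset-relative
rating of a single act is meaningless.

**Distance.** The summed frame-to-frame displacement of both hands;
per-hand distances are emitted as auxiliary columns. Note that distance
accumulates |noise| and therefore rises systematically with sensor
jitter; it is the one feature whose absolute value should only be
compared between recordings of similar noise level.

## Agreement statistics

`spearman_rho` is the rank correlation with midranks for ties; p-values
come from the t-distribution approximation, which is appropriate at the
sample sizes of typical validation sets (dozens to hundreds of acts),
with a seeded permutation mode for small n. `cohens_kappa` is
unweighted, `(p_o − p_e)/(1 − p_e)` with expected agreement from the
marginal products, computed over a declared category scale; values
outside the scale are rejected. `compare_tables` joins two feature
tables on act label, reports ρ, raw and Bonferroni-corrected p
(`min(1, p · m)` for `m` features) per feature, and κ for the features
on fixed scales (vertical amplitude 1–4, binned peak velocity 1–7) —
counts with unbounded range admit no κ.

## The synthetic generator

The generator emulates the three ingredients the features respond to.

*Strokes* are straight-line minimum-jerk segments,
`x(τ) = x₀ + (x₁ − x₀)(10τ³ − 15τ⁴ + 6τ⁵)`, the standard model of
ballistic reaching: a single velocity bell with zero velocity and
acceleration at both ends and peak speed `1.875 · D / T`. The wrist,
hand tip and thumb ride rigidly with the hand; the elbow moves half as
far. Because the profile is a quintic, the degree-5 smoothing filter
reproduces it exactly away from segment junctions, which is what lets
extraction recover the designed peak speeds to a fraction of a percent.

*Sway* is a slow circular weight-shifting drift of shoulders and elbows
(tangential speed 0.9 m/s, period 0.8 s, a weak restoring leak bounding
the drift). It exists because the stillness criterion would otherwise
fire in every pause between strokes: with sway on, every frame outside
a scheduled hold displaces those joints by ≈ 0.03 m — three times the
stillness threshold — so stillness occurs only where scheduled. The
sway is generated as a gated *velocity* field rather than an
amplitude-modulated position, so the approach to a freeze crosses the
0.01 m threshold within a fraction of a frame and raw and smoothed data
agree on hold boundaries to ±1 frame.

*Holds* ramp the sway gate smoothly to zero (0.2 s minimum-jerk ramps)
and freeze every joint. A smooth stop necessarily spends 1–2 frames
inside the sub-threshold band before full stillness, so the realized
still interval slightly exceeds the scheduled freeze window. The ground
truth therefore annotates holds from the generator's own raw noise-free
trajectory (a vectorized run-length scan, deliberately a separate code
path from the detector), while submovement counts, peak speeds,
amplitude categories and distances are annotated analytically from the
stroke arithmetic. Jitter — i.i.d. Gaussian noise per coordinate per
frame — is added *after* truth computation, so truth always describes
the noise-free motion.

The standard battery (`generate_dataset`) cycles acts through 0–5
dominant-hand submovements, 0–2 holds and the four amplitude
categories, with left-hand stroke pairs on every third act. Counted
strokes last 18 frames out / 23 frames back: long enough for the
15-frame filter to pass the velocity bell undistorted, short enough
that millimeter jitter cannot split the bell into two ≥ 8-frame-apart
peaks. Out-stroke peak speeds are category-dependent (reaching higher in
0.6 s requires moving faster) and staggered per act so all battery
peaks are pairwise distinct, making quantile binning well defined.
Zero-submovement acts contain a slow sub-threshold out-and-back
(≤ 0.1 m/s) rather than no motion. Acts ending away from rest get a
return stroke in the inter-act padding, outside their windows.

What the generator does *not* emulate: bone-length rigidity and
joint-angle constraints, tracking dropouts and outlier spikes (as
opposed to Gaussian jitter), trunk lean affecting the landmarks, and
co-articulated multi-joint reaching. Passing the recovery battery
therefore shows that the pipeline implements its definitions exactly
and is stable under millimeter Gaussian noise — not that it is robust
to every artifact of real depth-sensor data.

## Numerical choices and degenerate inputs

- Time-to-frame conversion adds 1e-9 before flooring, so products like
  `0.3 · 30` land on the intended frame despite binary rounding; the
  minimum hold span subtracts the same tolerance before the ceiling.
- An empty speed series yields zero submovements (not an error); peak
  velocity of an empty act is an error.
- Fewer distinct peak values than bins produces a warning and empty
  bins; all-equal values all fall in bin 1.
- A per-act data-quality problem (missing joint samples in-window, a
  window past the end of the recording) is recorded in that act's row
  and processing continues; nothing is imputed.
- Plot annotations are generated from the same feature objects written
  to the feature table, and every figure carries a JSON manifest so
  checks read annotations, not pixels.

## Problem sizes used in the test battery

The standard recovery battery is 20 acts (~2 minutes of recording at
30 fps, ≈ 3,700 frames × 17 joints); oracle-equivalence checks use
1,000 random series of up to 300 frames; the kappa cross-check
enumerates all 2×2 contingency tables with cell counts below 8. These
sizes exercise every code path while keeping the full suite and the
acceptance script each under a minute of compute.
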