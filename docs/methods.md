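# Methods

## The measurement and its unit of analysis

A photosensitive-seizure trial places one larva per well of a 48- or
96-well plate and delivers five 1 s light flashes separated by 49 s of
darkness after a lights-on acclimation.  The unit of analysis is the
**flash response**: the 2 s of centroid trajectory following each flash.
Each response is summarized by seven kinematic variables — maximum
velocity (mm/s), maximum acceleration (mm/s²), number of turns, percent
mobility, and the cumulative durations (s) of the immobile, mobile and
highly mobile states — plus angular velocity (deg/s), which is computed
but not part of the default classifier set.  Responses, not larvae, are
the sampling unit for all proportion statistics; the five responses of
one larva are treated as independent trials even though they are not
(see Limitations).

## Kinematics

All quantities derive from forward differences of the centroid track at
the acquisition rate (default 25 Hz; the rate is configurable and all
results are expressed in physical units):

* speed = step displacement × rate; acceleration = first difference of
  speed × rate; an optional 3-point smoother is off by default;
* heading = direction of the step vector, defined only for steps of at
  least 0.05 mm (a jitter guard — sub-floor steps carry no orientation
  information); heading changes are wrapped to (−180°, 180°];
* a **turn** is a maximal run of consecutive same-sign heading changes
  whose summed magnitude reaches 90° (configurable).  Runs broken by a
  sign flip or a sub-floor step count separately.  This definition is
  robust to frame jitter and is invariant under rigid motions of the
  coordinate frame;
* **mobility states** are a centroid proxy for tracker-defined mobility
  (which is pixel-based and not recoverable from centroids): per-frame
  displacement as a percentage of a 4 mm reference body length, labelled
  immobile below 20%, highly mobile above 60%, mobile between.  The three
  state durations partition each window exactly.

Tracking dropout is linearly interpolated when at most 5 consecutive
frames are missing; longer gaps are flagged, and any response window
containing more than 5 flagged frames is excluded from the feature
matrix.  Subjects with more than 20% dropout are excluded from
whole-trial assays.

## The classifier

Responses from all groups, plates and replicates are pooled into one
observation × feature matrix; the same fitted model then scores every
group, so group proportions are comparable.

1. **Moving filter.**  A movement score per response (quantile rank of
   maximum velocity) removes observations below a configurable quantile;
   the default quantile 0 removes only responses with literally zero
   movement.  The cutoff is a free knob because no principled value
   exists without reference data.
2. **Standardization** to per-column mean 0, SD 1 (population scaling).
   Constant columns are dropped with a warning.
3. **PCA, two passes.**  A first 2-component PCA on all variables yields
   each variable's cos² — its summed squared correlation with the
   retained components, computed analytically as
   (loading × √λ)² so degenerate components contribute exactly zero.
   Variables with cos² ≤ 0.75 are dropped and the PCA is refit on the
   survivors; if fewer than two survive, the all-variable model is kept
   with a warning (this happens for isotropic data, where each of 7
   variables carries ≈ 2/7 of two components).  Refitting after variable
   selection is a design choice; selecting without refitting would leave
   the scores influenced by the discarded variables.
4. **Mahalanobis distance** from the pooled centre in the PC subspace:
   MD² = Σₖ sₖ²/λₖ with λₖ the component variances of the fitting sample
   (ddof = 1, hence the fitting-sample identity mean MD² = d(n−1)/n).
   Because PC scores are uncorrelated this equals the full
   inverse-covariance Mahalanobis distance in score space.
5. **Calibration and call.**  p = P(χ²₂ ≥ MD²) = exp(−MD²/2).  A response
   is **high activity** when MD > 2.5 and p < 0.1 (the region used for
   the published group table; the alternative convention MD > 2,
   p < 0.15 is available through the same two knobs, and the report
   always states the thresholds used).  Note P(χ²₂ ≥ 2.5²) ≈ 0.044, so
   with the default pair the MD threshold is binding and roughly 4.4% of
   a well-calibrated bulk is labelled high by construction — specificity
   against true-normal responses is bounded near 95.6%.

## Group-level statistics

* **Univariate assays** (locomotion total distance, PTZ maximum velocity,
  flash-mean velocity/turns) are compared within plates only: classical
  one-way ANOVA across the groups sharing a plate, or a two-sample t-test
  when exactly two groups are present (Welch by default — the unequal-
  variance form is the safer default when group variances differ; the
  pooled form, for which F = t² holds exactly, is a flag away).  Each
  plate carries its own scrambled control, the structural guard against
  batch effects; cross-plate comparisons are not expressible in the API.
* **Proportion tests** compare each group's high-activity count to a
  reference group.  When every expected cell of the 2×2 table is at
  least 5, an exact binomial test against the reference proportion
  (treated as fixed) is used; otherwise Fisher's exact test.  The
  expected-cell cutoff of 5 makes the "smallest sample sizes" rule
  concrete.  Alternatives are one-sided by design: *greater* for
  crispant-vs-control (seizure enrichment), *less* for treated-vs-vehicle
  (protection); two-sided is available.  Treating the reference
  proportion as fixed ignores its sampling error and is slightly
  anticonservative when the reference arm is small; in screening use the
  reference (pooled scrambled responses) is the largest arm, which keeps
  the distortion small.  No multiple-testing correction is applied in
  this arm.

## The simulator

The simulator emulates what the analysis consumes — a centroid track per
well — not video.  Locomotion is discrete beat-and-glide: bout onsets are
a discretized Poisson process (per-frame Bernoulli with rate × dt), with
separate rates in darkness and light (defaults 1.6 and 0.8 bouts/s,
darkness higher, reproducing the stereotyped dark/light locomotion
pattern); per-bout speed is a zero-truncated normal (default 25 ± 6 mm/s
burst speed, 0.2 s per bout); heading performs a random walk updated at
each bout (SD 35°).  The well wall (default radius 5.5 mm) is a
reflective boundary, which both confines the track and produces the
wall-following look of normal larvae.  Positions are integrated
sequentially (numba-jitted, with a pure-Python fallback).

Each flash draws Bernoulli(p_seizure) per larva.  A normal response is a
startle: an immediate bout with speed scaled by `startle_gain` (default
1.8) and in-window bouts amplified.  A seizure-like response holds a high
sustained speed (default 70 ± 10 mm/s — the scale of maximum velocities
observed in chemoconvulsant trials) with heading reversals of 120–180° at
4/s for 2 s, matching the analysis window.  A dose → activity-gain map
scales bout rate and speed for chemoconvulsant (PTZ) trials.  Per-well
random streams are keyed on (master seed, CRC32 of well id), so plates
are reproducible and independent of well processing order.

The simulator's magnitudes are free parameters, not calibrated to any
real acquisition: no published frame rate, well geometry or velocity
distribution accompanies the assay this emulates.  Consequently the
synthetic tests demonstrate *pipeline correctness and statistical
behavior* (recovery of known seizure probabilities, calibration of the
tests), not agreement with any real effect size.  Real features the
simulator does not reproduce: pixel-based mobility (our mobility states
are a displacement proxy), tail-beat posture, tracker segmentation noise,
and within-larva correlation of flash responses.

## Study conditions used by the recovery analyses

The synthetic recovery study uses a 96-well plate with 84 control wells
(p_seizure = 0.05) and 12 crispant wells (p_seizure = 0.30), five flashes
each: a pooled seizure burden of ≈ 8%, comparable to the pooled
high-activity fraction observed in real screens of this design.  The
pooled burden matters intrinsically: with the model fitted on pooled data,
an outlier cluster forming a fraction ε of observations cannot exceed a
Mahalanobis distance of about √((1−ε)/ε) along its own direction
(the cluster inflates the very variance it is scored against), so the
fixed MD > 2.5 region only separates well when ε ≲ 0.10.  This is a
property of the method, not of the simulator; screens relying on the
pooled fit should keep the expected outlier burden low, e.g. by pooling
crispant groups with a large shared control arm.  Under these conditions
the pipeline recovers the proportion ordering in 100/100 seeded
replicates with pooled label sensitivity ≈ 0.99 and specificity ≈ 0.99
against simulated ground truth (see `scripts/acceptance.py`).

Problem sizes for the stochastic checks — 100 replicate plates for
recovery, 200 count-level replicates for the protection-power estimate,
1000–2000 replicates for the type-I bands — were chosen so Monte-Carlo
error is small relative to the asserted margins.

## Known limitations

* Flash responses of one larva are correlated; counting responses as
  independent trials overstates the effective sample size.  A
  larva-level or mixed-effects analysis would be more conservative; the
  response-level convention is kept because it is the screening
  convention this package implements, and it is flagged here.
* The chi-squared calibration assumes an approximately normal pooled
  bulk in PC space; heavy-tailed bulks inflate the high-activity rate of
  true normals.
* cos² selection is computed for variables, not observations; the
  observation-level reading of the same threshold is not implemented.
* Mobility states are a centroid-displacement proxy with configurable
  cuts (20%/60% of a 4 mm body length per frame); absolute mobility
  percentages are not comparable to pixel-based tracker output.
* No robust (e.g. MCD) covariance: a heavily contaminated pool shrinks
  all distances, as quantified above.
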