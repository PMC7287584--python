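# Methods

This note records the measurement model behind `gaitvar`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
generator does and does not establish about real data.

## Measurement model

A session is one continuous ~3-minute walk recorded simultaneously by a
summed force-plate array (vertical + two horizontal force channels, 1000 Hz,
with the participant's body weight known) and two IMUs (±16 g accelerometer,
±2000 °/s gyroscope, 400 Hz) worn at the waist (L4, mid-line of the back)
and above the right lateral malleolus. Devices are synchronized by a 1.5 V
square pulse on each device's auxiliary channel near the end of the
recording; alignment uses the first rising edge above 0.75 V with no
sub-sample interpolation (only the relative offset matters, and the error is
bounded by one sample period of the coarser device).

### Force-plate heel-strike detection

1. All maximal runs of vertical force above 1.1 × body weight lasting at
   least 2.5 ms are found.
2. In a 50 ms window backwards from each run's force maximum, the peak
   positive jerk (central-difference dF/dt, no pre-smoothing) is a
   heel-strike candidate. Windows reaching before the start of the
   recording are truncated rather than rejected.
3. Candidates closer than 250 ms keep only the higher jerk. 250 ms is
   safely below any plausible step time, so the two load humps of one
   stance cannot both survive; the threshold is not otherwise sensitive.
4. Candidates with jerk below 0.3 × the *mean of the 50 highest candidate
   jerks* are discarded. The filter statistic ("the value of the 50 highest
   candidates") admits more than one reading; the mean is used as the
   natural scalar summary of a set, and a rank-statistic variant can be
   obtained by passing `top_n=1`-style configurations of
   `filter_false_candidates`.
5. Feet are assigned from the mean mediolateral force over the 150 ms after
   each candidate; a positive mean marks a right-foot strike by default
   (`right_fy_positive`). The axis/window/sign conventions are package
   choices — instrumentation differs — and alternation violations are
   logged rather than corrected.

Right-foot heel-strike to next right-foot heel-strike defines a stride.

### Ankle and waist event detection

The ankle detector anchors on mid-swing positive peaks of the sagittal
angular velocity (default threshold 100 °/s, minimum separation 500 ms) and
takes the deepest minimum within 0.4 s after the peak as heel-strike and
within 0.4 s before it as toe-off, each refined by the vertex of a parabola
fitted to ±2 samples around the minimum (the refinement is clamped to the
fit window). The 0.4 s windows and the swing threshold are this package's
defaults, validated against synthetic truth only. Merged HS/TO sequences
are reduced so labels strictly alternate, keeping the earliest event of any
same-label run.

The waist detector convolves the earth-frame vertical acceleration with a
Ricker wavelet whose spectral peak is 16 Hz (per-participant fallback, e.g.
8 Hz, is a plain parameter), σ = 1/(π·f·√2), sampled on ±4σ with the
truncation residual removed so the kernel sums exactly to zero. The
convolved signal is low-pass filtered by a 2nd-order Butterworth applied
forward and backward — the conventional reading of "4th-order zero-lag" —
and local maxima with prominence above 0.5 × the 80th percentile of all
maxima *prominences* mark heel-strikes. Prominences (rather than raw
heights) are the quantity the relative threshold multiplies; this makes the
detector exactly invariant to amplitude rescaling. Since waist heel-strikes
carry no foot label, strides span the current to current + 2 heel-strike.

Orientation comes from the Madgwick gradient-descent filter (IMU variant;
the magnetometer is unused — extracting the vertical requires only the
gravity direction). The gain β = 0.1 (the filter's conventional default; no
study-specific value exists) balances gyro drift against acceleration
disturbance; with β = 0 the filter reduces to pure gyro integration. A
warm start runs the filter over the opening 5 s of the stream and uses the
final quaternion to seed the full pass, so initial-alignment transients do
not reach event detection. Quaternions are renormalized every step.

### Stride outcomes

Strides within a two-sided multiplicative band of the median duration
(median/1.25 … median × 1.25, median computed once over all candidates, not
iterated) are retained. IMU-derived strides are matched to force-plate
strides by greedy one-to-one nearest-neighbour matching within 0.2 s —
optimal in the gait regime, where events are separated by more than twice
the tolerance. Outcomes are the stride count, mean duration, sample SD
(n−1; the convention of reliability practice), and CV% = SD/mean × 100.
Reported IMU outcomes depend on the concurrent force plate through the
matching step; `standalone=True` skips matching for field use, at the cost
of retaining any false detections.

### Multiscale entropy

The resultant (Euclidean norm, gravity included, mounting-invariant) waist
acceleration is divided into non-overlapping 1-min epochs; a remainder
shorter than 1 min is discarded. For each epoch and each coarseness scale
τ = 1…80, the series is reduced to non-overlapping means of τ samples at
each of the τ possible offsets.

* **RCME** — sample entropy with template length m = 4, Chebyshev distance,
  unordered template pairs i < j over the common range of L−m start points,
  self-matches excluded. The tolerance R = 0.3 × SD of the *un-coarsened*
  epoch is computed once and reused at every scale, making the profile
  invariant to affine transforms of the signal; the per-epoch (rather than
  pooled-session) SD accommodates amplitude differences between bouts.
  Match counts are summed over all τ offsets before RCME(τ) = −ln(ΣA/ΣB);
  a zero pooled count yields NaN ("undefined"), never infinity.
* **RMPE** — ordinal patterns of m = 4 consecutive coarse-grained samples
  (delay 1; ties broken by index order, which has measure zero for
  continuous signals), relative frequencies averaged over the τ offsets,
  Shannon entropy in nats (unnormalized; `normalize=True` divides by
  ln 24). RMPE is invariant to any strictly monotone amplitude transform at
  τ = 1 and to affine transforms at all scales — block averaging does not
  commute with nonlinear maps, so the stronger claim holds only at τ = 1.

Session values are the arithmetic mean over the session's epochs (2–3 full
minutes in a 3-min protocol), with NaN scales excluded pairwise. The O(n²)
match counting is a numba kernel; one 24 000-sample epoch over all 80 scales
takes ~15 s on one CPU, well inside the 5-minute envelope the analysis is
designed for.

### Agreement statistics

The absolute-agreement intra-class correlation is ICC(A,1): two-way
random-effects, single measures, computed from the ANOVA mean squares, with
the F-based (McGraw–Wong, Satterthwaite df) 95% CI. The two-way
consistency variant ICC(3,1) is available (`variant="C1"`) for sensitivity.
Categories: poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤ excellent.
Bland–Altman limits of agreement use bias ± 1.96 × sample SD of the paired
differences (the conventional normal multiplier, not t-based). CV%RMS is
the root-mean-square over subjects of the per-subject two-value CV
(SD = |a−b|/√2). Per-scale correlations between entropy and a reference
variability outcome report one Pearson r and p per scale with no
multiple-testing correction across the 80 scales (α = 0.05 convention); a
Holm adjustment can be applied downstream if desired.

## Synthetic generator

The generator emulates the measurement setup, not gait biomechanics. Right
stride durations follow a stationary AR(1) process
d_k = μ + φ(d_{k−1} − μ) + ε, ε ~ N(0, σ²(1−φ²)) with defaults
μ = 1040 ms, σ = 19.6 ms, φ = 0 — the stride statistics of healthy
community-dwelling older adults; φ is exposed to probe the entropy
measures' sensitivity to temporal structure. Left heel-strikes trail by
half a stride ± 5 ms jitter; toe-offs fall at 62% of the stride (mid-range
double-support walking) after the same-foot heel-strike.

The vertical force is a 0.75 × BW support baseline plus two raised-cosine
humps per step (peaks ≈ 1.2 × BW) and a 30 ms impact transient
(350 N default) starting exactly at each heel-strike; hump areas make the
time-averaged force ≈ body weight. The transient merges with the first
hump's supra-threshold run, so the run's force peak lies within ~10 ms of
the heel-strike and the jerk maximum falls at the true event; the second
hump forms a separate low-jerk run that the 0.3 × top-50 jerk filter
removes — the same role that filter plays on real signals. The
mediolateral force carries a front-loaded per-stance lobe whose sign codes
the foot. Waist vertical acceleration is a per-step sinusoid plus a sharp
Gaussian peak (σ = 10 ms) at each heel-strike, observed by a sensor tilted
about x with a slow 2° sway whose exact angular rate drives the gyroscope;
the ankle sagittal gyro is a mid-swing raised-cosine lobe (300 °/s) with
Gaussian troughs (σ = 12 ms) exactly at heel-strike and toe-off. Gaussian
sensor noise defaults: 5 N (force), 0.02 g / 0.2–1 °/s (IMU).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: soft-tissue artefact, turning segments at
track ends (the stream is turn-free straight gait), inter-subject waveform
morphology, drift or calibration error in the IMUs, and pathological gait.
Detector recovery on these signals demonstrates algorithmic correctness
(the chain finds events its model class generates, exactly and
deterministically), not clinical validity.

Same seed ⇒ bit-identical output; per-signal noise streams are derived from
independent seed sequences so enabling one signal's noise never perturbs
another.

## Cohort simulation

`simulate_cohort_outcomes` draws persistent per-subject traits
(mean ~ N(1040, 100²) ms, SD ~ N(19.6, 7.5²) ms clipped at 3 ms, matching
the cohort dispersion the defaults target) and re-samples each session's
walk, computing outcomes from the plan's true stride durations so large
cohorts stay cheap. With persistent traits, the between-subject variance
dominates the within-session sampling error of an SD estimate
(≈ σ/√(2n) ≈ 1 ms at n ≈ 170 strides), driving the test–retest ICC toward
1; `subject_effects=False` redraws traits every session (exchangeable
sessions, expected ICC 0); `session_sd_jitter_ms` adds week-to-week
physiological wobble between those extremes.

## Numerical conventions and edge cases

* Jerk: central difference (one-sided at edges) at the recording rate.
* Epoch SD for the entropy tolerance: population (ddof 0) SD; immaterial at
  N = 24 000 but fixed for determinism.
* Degenerate inputs: constant epochs give zero entropy at every scale;
  zero-variance paired samples give NaN ICC with a warning; fewer than two
  strides give NaN SD/CV with a warning; an all-zero mediolateral force
  assigns 'left' everywhere and logs an alternation warning.
* Matching ties: the earlier reference event claims a shared candidate.
* JSON reports are serialized with sorted keys so identical configurations
  produce byte-identical files.

## Problem sizes

The default test suite exercises 60 s walks and 2000–6000-sample epochs;
the acceptance script uses full 180 s walks, 24 000-sample epochs over all
80 scales, five-walk outcome averages, and ten 27-subject two-session
cohorts. These sizes were chosen so a complete validation runs in a few
minutes on a single CPU while keeping every estimate's Monte-Carlo error
well below the tolerances asserted.

## Known limitations

* The force-plate foot-assignment convention is a stand-in for whatever
  lateral-force signature a given plate array produces; real deployments
  should verify the sign convention against a labelled trial.
* The waist stride construction (current → current + 2 heel-strike)
  produces overlapping strides at twice the single-foot rate; its SD is not
  numerically identical to the right-foot-only SD even on perfect data.
* Entropy values are reported unnormalized in nats; comparisons across
  template lengths m require care.
* The ankle detector assumes a right-leg mounting with the sagittal axis on
  gyro y (sign configurable); arbitrary mounting needs the axis/sign
  configuration.
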