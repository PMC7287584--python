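# gaitvar

Gait variability and complexity from force plates and wearable inertial
measurement units (IMUs).

Stride-to-stride variation in gait timing is a marker of motor control in
older adults: an elevated stride-duration standard deviation predicts falls
and other adverse outcomes. Measuring it outside the laboratory requires
wearable sensors, which raises two questions this package's tool-chain is
built around: can heel-strike events — and hence stride durations — be
recovered from a waist- or ankle-worn IMU as reliably as from a force plate,
and can event-free *complexity* measures of the raw acceleration signal
(multiscale entropy) stand in for event-based variability?

`gaitvar` implements the full measurement chain for a continuous ~3-minute
walk recorded simultaneously by a summed force-plate array (1000 Hz) and
waist/ankle IMUs (400 Hz):

* **Force-plate heel-strikes** — continuous runs of the vertical force above
  1.1 × body weight lasting ≥ 2.5 ms; within a 50 ms window backwards from
  each run's force peak, the maximum positive jerk dF/dt marks a heel-strike
  candidate; candidates with jerk below 0.3 × the mean of the 50 highest are
  discarded; feet are assigned from the mediolateral force. Right
  heel-strike → next right heel-strike defines a stride.
* **Ankle IMU events** — mid-swing peaks of the sagittal angular velocity
  anchor troughs located after (heel-strike) and before (toe-off) each peak,
  refined by a fitted parabola vertex; events are reduced to a strictly
  alternating HS/TO sequence.
* **Waist IMU heel-strikes** — Madgwick gradient-descent fusion yields the
  earth-frame vertical acceleration, which is convolved with a 16 Hz Ricker
  wavelet, low-pass filtered (4th-order zero-lag Butterworth, 6 Hz), and
  peak-picked with a relative prominence threshold (0.5 × the 80th
  percentile of all maxima prominences). Strides span the current to
  current + 2 heel-strike.
* **Outcomes** — strides within a 1.25 ratio of the median duration are
  kept; IMU strides are matched to force-plate strides within 0.2 s; the
  mean, sample SD, and CV% (SD/mean × 100) of stride duration are reported.
* **Multiscale entropy** — the resultant waist acceleration, in
  non-overlapping 1-min epochs, is analysed over coarseness scales
  τ = 1…80 (non-overlapping means of τ samples). Refined composite
  multiscale entropy (RCME: sample entropy with m = 4, Chebyshev distance,
  tolerance R = 0.3 × the epoch's resultant SD, match counts pooled over all
  τ coarse-graining offsets) and refined multiscale permutation entropy
  (RMPE: Shannon entropy of pooled ordinal-pattern frequencies, m = 4) are
  averaged over the epochs of a session.
* **Agreement statistics** — absolute-agreement ICC(A,1) with F-based 95%
  CI and the poor/fair/good/excellent categories (0.40/0.60/0.75),
  Bland–Altman bias and 95% limits of agreement with a paired t-test,
  Pearson r/r², CV%RMS, and per-scale entropy-vs-variability correlations.

Because raw recordings of this kind are rarely shared, the package includes
a synthetic gait generator (`gaitvar.synthetic`) that emits mutually
consistent force-plate and IMU streams with known ground-truth events and
stride statistics (defaults: 1040 ms mean, 19.6 ms SD), so every detector
can be validated against truth.

## Worked example

```python
from gaitvar import GaitSimParams, SessionConfig, run_session

params = GaitSimParams(seed=7)          # 3-min walk, 1040 +/- 19.6 ms strides
result = run_session(SessionConfig(simulate=params))

for src, o in result.outcomes.items():
    print(f"{src:>5}: n={o.n_strides:3d}  mean={o.mean_ms:7.1f} ms  "
          f"SD={o.sd_ms:5.2f} ms  CV={o.cv_pct:4.2f}%")
rcme = result.entropy["RCME"]
rmpe = result.entropy["RMPE"]
print(f"RCME tau=1: {rcme.values[0]:.3f}  tau=40: {rcme.values[39]:.3f} nats "
      f"({rcme.n_epochs_averaged} epochs)")
print(f"RMPE tau=1: {rmpe.values[0]:.3f}  tau=40: {rmpe.values[39]:.3f} nats")
```

prints

```
force: n=172  mean= 1036.6 ms  SD=17.29 ms  CV=1.67%
ankle: n=171  mean= 1036.6 ms  SD=17.37 ms  CV=1.68%
waist: n=343  mean= 1036.6 ms  SD=15.72 ms  CV=1.52%
RCME tau=1: 0.404  tau=40: 0.103 nats (3 epochs)
RMPE tau=1: 3.159  tau=40: 2.499 nats
```

All three instruments recover this walk's true mean stride duration
(1036.6 ms for this seed) exactly, and the stride-duration SD to within
sampling error; the waist source counts ~2× strides because the
current→current+2 construction yields one (overlapping) stride per step.
The entropy profiles decline with coarseness scale, as expected for a
signal dominated by within-stride structure.

The same chain runs from the shell:

```sh
gaitvar simulate --out walk/ --seed 7
gaitvar detect-force --in walk/force.csv --mass 70 --out events.csv
gaitvar strides --events events.csv --step 1 --foot right --out strides.csv
gaitvar entropy --in walk/waist.csv --out entropy.csv
```

and `gaitvar run --config study.yaml` executes a whole session from a YAML
config. Recordings are plain CSV (`t,fx,fy,fz[,aux]` for force;
`t,ax..az,gx..gz[,mx..mz][,aux]` for IMUs) and concurrently recorded devices
are aligned via the 1.5 V sync pulse on the aux channel (`gaitvar align`).

## Documentation

See `docs/methods.md` for the measurement model, parameter choices,
numerical conventions, what the synthetic generator does and does not
emulate, and known limitations.
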