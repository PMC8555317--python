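# Methods

## Problem and model

Syringe and volumetric infusion pumps detect line occlusions by alarming
when the internally sensed line pressure P(t) exceeds a fixed threshold
(400 mmHg is a common ward setting). Because a stalled syringe pressurizes
the compliant tubing slowly at low flow, the alarm delay of that rule grows
roughly as (threshold − baseline)/slope, reaching tens of minutes at
1 ml/h. pumpwatch implements three streaming detectors that act on the
*shape* of the pressure signal instead of its absolute level, all evaluated
once per 2-s tick:

1. **Regression detector.** A binary logistic model of occlusion
   probability from the administration rate Q (ml/h) and the mean pressure
   P̄ (mmHg) over the last 60 s:

       p = 1 / (1 + exp(−(−1.345 − 0.177·Q + 0.040·P̄)))

   gated on a positive ordinary-least-squares pressure slope over the last
   30 s. `p ≥ 0.5` is a preliminary occlusion call. The shipped
   coefficients were trained on bench occlusion runs; `fit_logistic`
   supports retraining (unregularized MLE, with a ridge fallback under
   perfect separation).

2. **SD detector.** During stable infusion, pressures are approximately
   normal around a rate-dependent mean, so ~95% of samples lie within 2 SD.
   The detector compares the sample SD of the last 30 samples (60 s)
   against a per-rate reference SD measured during non-occluded infusion;
   a positive 30-s slope together with window SD > 2 × reference SD is a
   preliminary call. Because only dispersion matters, the rule is
   insensitive to the absolute baseline pressure level.

3. **Correlation (co-occlusion) detector.** When several pumps share
   tubing, a blockage in the shared segment couples their pressures almost
   instantaneously (Pascal's law in the closed fluid column). After any
   pump's SD detector makes a final positive classification, the trigger
   pump's last 30 pressure samples are Pearson-correlated with each other
   pump's time-aligned window; partners with r > 0.8 (strict) are
   classified as co-occluding. Zero-variance windows give "no decision"
   rather than r = 0, so a stopped pump is never classified.

Preliminary calls from detectors 1–2 are debounced by majority voting: an
actual alarm requires ≥ 6 positive among the 10 most recent preliminary
calls. The voting history starts padded with negatives, so no alarm can
fire before 6 ticks; on a steep ramp where every post-onset tick is
preliminary positive the minimum achievable delay is therefore
6 × 2 s = 12 s = 0.2 min. Alarms are non-latching in the per-tick trace
(the final classification may self-correct after a transient); the
reported alarm time is the first final positive, which is how alarm delay
(minutes from occlusion onset) is measured throughout.

## Synthetic runs

No bench pressure recordings are distributed, so the simulator emulates
the experimental protocol: a 10-min non-occluded phase, then a linear
occlusion ramp until the pressure reaches the conventional 400-mmHg stop
threshold or 10 min elapse. Per pump, pressure is

    P(t) = startup(t) + baseline_mean + slope·max(0, t − onset) + ε(t),

with ε i.i.d. Gaussian per tick and an optional linear start-up rise from
the venous counter pressure (≈5.2 mmHg, a 7-cm water column) to the
working baseline. Linearity of the ramp matches how occlusion-phase
pressure is summarized (an OLS fit of pressure on time). Pumps in one
occlusion group share the identical deterministic ramp with independent
noise. Per-pump noise streams derive from (seed, pump_id), so runs are
bit-reproducible and adding a pump does not perturb the others. The tick
grid is half-open: a 20-min run at dt = 2 has 600 ticks (t = 0 … 1198 s).

**Calibration.** Ramp slopes are backed out of a table of conventional
alarm delays per rate, slope = (400 − baseline)/delay, using the
bench-measured delays (21.9, 10.8, 6.0, 2.7, 1.5, 1.4 min at 1, 2, 4, 8,
16, 32 ml/h) as the default. A noiseless run with a calibrated slope
reproduces the tabulated conventional delay to within one tick (tested for
all six rates). Slopes at unmeasured rates (needed for two-pump combined
rates of 3, 5, 9, 17 and 33 ml/h) are interpolated linearly in rate and
clamped at the extremes.

**Defaults.** Baseline means are 5–25 mmHg, rising with rate from the
~5 mmHg counter pressure; baseline SDs default to 0.5–2 mmHg rising with
rate. Neither is a measured bench value — noise magnitudes were not
reported — so every calibrated evaluation states the SD it uses (the
headline batches use 1 mmHg flat). These are the study conditions; they
are fixed, not tuned.

**What the simulator does not model**, and hence what passing tests do not
establish about physical pumps: syringe/tubing compliance (which makes real
ramps convex early on), stepper-motor pressure fluctuation, autocorrelated
sensor noise, transport artifacts, viscosity, and occlusions at the start
of infusion. Because the synthetic baseline noise is exactly i.i.d.
Gaussian, the SD detector triggers somewhat faster here (overall ≈0.3 min)
than on the bench (0.4 ± 0.2 min), and false-positive rates are
optimistic.

## Baseline characterization

Start-up samples are trimmed by a sliding-window rule of this package's
own definition (no published rule exists): the log is stable from the
first 30-sample window whose OLS slope magnitude is below 0.05 mmHg/s.
The non-occluded segment is summarized by mean, SD (n−1 denominator) and
a Shapiro–Wilk normality p-value (standard choice below n ≈ 5000; pooled
segments are subsampled to 5000 points for the test only). Reference SD
lookup at a rate not in the profile interpolates linearly between
neighbouring rates, clamped at the extremes — the bench profile only
covers measured rates, interpolation makes the detector total. A floor of
0.1 mmHg guards the degenerate zero-noise baseline where the 2×SD rule is
meaningless.

Conventional delays for thresholds 300–800 mmHg are extrapolated from the
occlusion-phase OLS fit with the continuous formula
(threshold − baseline)/slope at a worst-case clinical baseline of
150 mmHg, ignoring the 2-s sampling discretization, and exported as the
rate × threshold `delay_table`. Note the trained logistic model's decision
boundary P* = (1.345 + 0.177·Q)/0.040 sits near 38 mmHg at 1 ml/h, far
below that worst-case baseline, so the regression detector is only
meaningful at low baseline pressures; simulator defaults keep baselines
low for this reason, and the 150-mmHg value is used only for the
extrapolation table.

## Evaluation protocol

`batch_evaluate` simulates a scenario batch (the baseline reference
profile is built from the batch's own trimmed non-occluded phases, pooled
per rate), replays each detector over each pump log, and reports per-run
outcomes: TP (alarm on an occluded pump between onset and the conventional
crossing), FN (not faster than the conventional alarm, mirroring how
misses were scored on the bench), FP (alarm on an unoccluded pump or
before onset), TN. Delay aggregates use TP rows. Algorithm-vs-conventional
delays are compared with paired Student t-tests per rate and overall;
per-rate p-values from simulated replicates are reported but not asserted
anywhere, since they are not comparable to triplicate bench p-values. The
multi-group ANOVA/Bonferroni comparison of the original protocol is
deliberately replaced by pairwise paired t-tests.

The window-size sweep scores per-tick accuracy (final classification vs
phase ground truth: pre-onset negative, post-onset positive) for stat
windows of 4–60 s. Windows below 2 samples are rejected (an SD needs
n ≥ 2 at dt = 2 s).

## Numerical and design choices

- Slope test: OLS slope > 0 (strict) over the 30-s window; more robust to
  single-tick noise than a first difference. Constant windows have slope 0
  and never pass.
- Logistic output ties at exactly 0.5 round up (occlusion); the boundary
  is measure-zero but must be fixed.
- Both windows are evaluated every tick on one shared sample buffer;
  wall-time window lengths convert to sample counts by flooring.
- Window SD uses a two-pass formula with compensated summation; tests
  require agreement with a definitional oracle to 1e-9 (Pearson to 1e-12).
- Simultaneous SD triggers on several pumps each act as a trigger; results
  merge by union of co-occluding sets.
- Paired t-tests on all-zero differences are undefined and reported as
  NaN, never as p = 1 or 0.

## Problem sizes

The headline batches are 6 rates × 30 replicates (single-pump) and
6 combined rates × 30 replicates (two-pump), about 360 simulated runs of
~600–1000 ticks each; the full suite and the acceptance script each run in
well under a minute on one CPU. Thirty replicates put the Monte-Carlo
standard error of the mean delays near 0.01 min, far inside the ±50%
acceptance bands used for the calibrated-simulation checks.

## Known limitations

- The linear-ramp, i.i.d.-noise generator is the main idealization; see
  above for what it omits.
- The regression detector's printed coefficients are taken as given; no
  attempt is made to reconcile the low decision boundary with high
  clinical counter pressures.
- Co-occlusion localization is the shared/not-shared dichotomy only; no
  distance-to-occlusion estimation, and only pairwise correlations with
  the trigger pump are examined.
- Detector warm-up means the first 60 s of a log can never alarm;
  occlusions at the very start of infusion are out of scope.
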