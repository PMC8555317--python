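# pumpwatch

Early detection of intravenous-line occlusions from infusion-pump pressure
logs — and of *co-occlusions*, where one blockage affects several pumps
feeding a shared line.

Conventional pumps alarm when line pressure P(t) crosses a fixed threshold
(typically 400 mmHg). At low administration rates (≤ 1 ml/h) the compliant
tubing pressurizes so slowly that this can take tens of minutes — time in
which a critical drug is not being delivered. pumpwatch implements three
streaming detectors that act on the shape of the pressure signal, sampled
every 2 s, rather than its absolute level:

- **regression** — logistic occlusion probability from the rate Q (ml/h)
  and the 60-s mean pressure, `p = 1/(1 + e^{−(−1.345 − 0.177·Q + 0.040·P̄)})`,
  gated on a positive 30-s pressure slope;
- **sd** — the SD of the last 30 pressure samples compared with 2× a
  per-rate baseline reference SD (during stable infusion ~95% of samples
  lie within 2 SD of the mean), gated on a positive slope;
- **correlation** — after an SD alarm on any pump, Pearson correlation of
  time-aligned 30-sample pressure windows across pumps; partners with
  r > 0.8 are co-occluding, which localizes the blockage to the shared
  tubing segment.

Per-tick preliminary calls are debounced by a 6-of-10 majority vote before
an actual alarm is raised. The package also ships a bench-style multi-pump
pressure simulator (stable noisy baseline, optional start-up transient,
linear occlusion ramp, shared-segment coupling, ramps calibratable to
measured conventional alarm delays), baseline characterization utilities,
and an evaluation harness that scores alarm delay and accuracy against the
conventional threshold alarm. It is aimed at medical-device and
patient-safety informatics work: prototyping occlusion detection on logged
or simulated pump pressure data.

## Worked example

Evaluate all three detectors on a calibrated single-pump batch (rates 1–32
ml/h, ramp slopes backed out of the measured conventional 400-mmHg alarm
delays, baseline SD 1 mmHg, 3 replicates):

```python
import pumpwatch as pw

scenarios = pw.calibrated_scenarios(baseline_sds={1.0: 1.0, 32.0: 1.0})
report = pw.batch_evaluate(scenarios, n_replicates=3, seed=1)
print(report.overall.to_string(index=False))
print(f"SD reduction vs conventional: {report.reduction_vs_conventional('sd'):.1f}%")
print(f"outcomes: {report.outcome_counts().to_dict()}")
```

prints

```
    detector  mean_delay_min  sd_delay_min  n
conventional        7.411111      7.492271 18
  regression        1.433333      0.533211 18
          sd        0.309259      0.105908 18
SD reduction vs conventional: 95.8%
outcomes: {'TP': 54, 'FP': 0, 'FN': 0, 'TN': 0}
```

The conventional alarm needs 7.4 min on average (21.9 min at 1 ml/h, by
construction of the calibration), while the SD detector alarms in ~0.3 min
— a ~96% reduction in alarm delay — and the regression detector in
~1.4 min; every occlusion is caught before the 400-mmHg crossing (no false
negatives) and the non-occluded phases produce no false alarms.

The same workflow is available from the shell:

```sh
pumpwatch simulate --seed 1 --out run.csv        # synthetic run + scenario sidecar
pumpwatch detect run.csv --detector sd           # alarm summary + per-tick trace
pumpwatch co-occlude run.csv                     # SD-triggered correlation records
pumpwatch evaluate --replicates 3 --seed 1 --out-dir report
pumpwatch sweep --out sweep.csv                  # window-size vs accuracy table
```

Log files are plain CSV (`pump_id,t_s,rate_ml_h,event,pressure_mmHg`, one
row per pump per 2-s tick, `event ∈ {none, occlusion}`).

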