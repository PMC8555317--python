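"""Evaluation protocol: alarm delays, outcome classification and paired
comparisons against the conventional threshold alarm.

A batch evaluation simulates (or loads) a set of runs, builds the baseline
reference profile from their non-occluded phases, replays each detector
over each pump log, and aggregates alarm delay (minutes, mean ± SD per
rate and overall) together with run-level outcome counts:

* TP — alarm on an occluded pump, at or after onset and no later than the
  conventional 400-mmHg crossing;
* FN — occluded pump where the algorithm was not faster than the
  conventional alarm (or never fired);
* FP — alarm on an unoccluded pump, or before the occlusion onset;
* TN — no alarm on an unoccluded pump.

Delay differences between an algorithm and the conventional alarm are
tested with paired Student t-tests on runs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import co_occlusion as co
from .baseline import BaselineProfile, build_profile
from .detectors import DetectorConfig, run_detector
from .logio import RunLog
from .simulator import SimConfig, simulate_run

OUTCOMES = ("TP", "FP", "FN", "TN")


def alarm_delay(alarm_t: float, occlusion_onset_t: float) -> float:
    """Alarm delay in minutes from occlusion onset to the alarm."""
    if alarm_t < occlusion_onset_t:
        raise ValueError("alarm precedes onset (false positive, no delay defined)")
    return (alarm_t - occlusion_onset_t) / 60.0


def classify_outcome(
    occluded: bool,
    occlusion_onset_t: float | None,
    alarm_t: float | None,
    conventional_alarm_t: float | None,
) -> str:
    """Run-level outcome of one detector on one pump (see module docstring)."""
    if not occluded:
        return "FP" if alarm_t is not None else "TN"
    if alarm_t is None:
        return "FN"
    if occlusion_onset_t is not None and alarm_t < occlusion_onset_t:
        return "FP"
    if conventional_alarm_t is not None and alarm_t > conventional_alarm_t:
        return "FN"
    return "TP"


def paired_compare(delays_a, delays_b) -> tuple[float, float]:
    """Paired Student t-test on delay differences; (t, two-sided p).

    Returns (nan, nan) when all differences are zero — the statistic is
    undefined there.
    """
    a = np.asarray(delays_a, dtype=float)
    b = np.asarray(delays_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length delay vectors of length >= 2")
    if np.all(a - b == 0):
        return (float("nan"), float("nan"))
    res = stats.ttest_rel(a, b)
    return (float(res.statistic), float(res.pvalue))


def percent_reduction(mean_algorithm: float, mean_conventional: float) -> float:
    """Mean alarm-delay reduction of an algorithm vs the conventional alarm, %."""
    if mean_conventional <= 0:
        raise ValueError("conventional mean delay must be > 0")
    return 100.0 * (1.0 - mean_algorithm / mean_conventional)


def _replicate_seed(seed: int, scenario_idx: int, replicate: int) -> int:
    state = np.random.SeedSequence([seed, scenario_idx, replicate]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def simulate_batch(
    scenarios: list[SimConfig], n_replicates: int, seed: int = 0
) -> list[tuple[int, int, RunLog]]:
    """Simulate every scenario ``n_replicates`` times with per-run seeds
    derived deterministically from (seed, scenario index, replicate)."""
    runs = []
    for i, scenario in enumerate(scenarios):
        for rep in range(n_replicates):
            cfg = dataclasses.replace(scenario, seed=_replicate_seed(seed, i, rep))
            runs.append((i, rep, simulate_run(cfg)))
    return runs


@dataclass
class AlarmReport:
    """Per-(run, pump, detector) results plus batch aggregates."""

    results: pd.DataFrame          # scenario, replicate, pump_id, rate, detector, alarm_t, delay_min, outcome
    per_rate: pd.DataFrame         # rate x detector mean/SD delay and n
    overall: pd.DataFrame          # detector-level mean/SD delay, outcome counts
    paired_p: pd.DataFrame         # paired t-tests of algorithm vs conventional delay

    def outcome_counts(self) -> pd.Series:
        return self.results["outcome"].value_counts().reindex(OUTCOMES, fill_value=0)

    def mean_delay(self, detector: str) -> float:
        sel = self.results[(self.results.detector == detector)
                           & (self.results.outcome == "TP")]
        return float(sel["delay_min"].mean())

    def reduction_vs_conventional(self, detector: str) -> float:
        return percent_reduction(self.mean_delay(detector), self.mean_delay("conventional"))


def batch_evaluate(
    scenarios: list[SimConfig],
    n_replicates: int = 3,
    detectors: tuple[str, ...] = ("conventional", "regression", "sd"),
    baseline: BaselineProfile | None = None,
    config: DetectorConfig | None = None,
    seed: int = 0,
) -> AlarmReport:
    """Simulate a scenario batch and evaluate each detector on every run.

    The baseline reference profile, unless supplied, is built from the
    trimmed non-occluded phases of the batch itself (pooled per rate),
    mirroring how the bench reference set was collected.
    """
    cfg = config or DetectorConfig()
    sims = simulate_batch(scenarios, n_replicates, seed)
    profile = baseline or build_profile([run for _, _, run in sims])

    rows = []
    for i, rep, run in sims:
        onset = run.occlusion_onset_t
        for pid, log in run.pumps.items():
            occluded = log.onset_time() is not None
            conv_alarm, _ = run_detector(log, "conventional", None, cfg)
            conv_t = conv_alarm.alarm_t if conv_alarm else None
            for det in detectors:
                if det == "conventional":
                    alarm = conv_alarm
                else:
                    alarm, _ = run_detector(log, det, profile, cfg)
                alarm_t = alarm.alarm_t if alarm else None
                outcome = classify_outcome(occluded, onset, alarm_t, conv_t)
                delay = (
                    alarm_delay(alarm_t, onset) if outcome == "TP" and onset is not None
                    else float("nan")
                )
                rows.append((i, rep, pid, float(np.median(log.rates())), det,
                             alarm_t, delay, outcome))
    results = pd.DataFrame(
        rows,
        columns=["scenario", "replicate", "pump_id", "rate", "detector",
                 "alarm_t", "delay_min", "outcome"],
    )

    tp = results[results.outcome == "TP"]
    per_rate = (
        tp.groupby(["rate", "detector"])["delay_min"]
        .agg(mean_delay_min="mean", sd_delay_min="std", n="count")
        .reset_index()
    )
    overall = (
        tp.groupby("detector")["delay_min"]
        .agg(mean_delay_min="mean", sd_delay_min="std", n="count")
        .reset_index()
    )

    paired_rows = []
    if "conventional" in detectors:
        key = ["scenario", "replicate", "pump_id"]
        tp_idx = tp.set_index(key)
        conv = tp_idx[tp_idx.detector == "conventional"]["delay_min"].rename("conv")
        for det in detectors:
            if det == "conventional":
                continue
            alg = tp_idx[tp_idx.detector == det][["rate", "delay_min"]].rename(
                columns={"delay_min": "alg"}
            )
            joined = alg.join(conv, how="inner")
            subsets = [("overall", joined)] + list(joined.groupby("rate"))
            for label, sub in subsets:
                if len(sub) < 2:
                    continue
                t_stat, p = paired_compare(sub["alg"], sub["conv"])
                paired_rows.append((det, label, len(sub), t_stat, p))
    paired_p = pd.DataFrame(paired_rows, columns=["detector", "rate", "n", "t", "p"])

    return AlarmReport(results, per_rate, overall, paired_p)


def co_occlusion_batch(
    scenarios: list[SimConfig],
    n_replicates: int = 3,
    config: DetectorConfig | None = None,
    baseline: BaselineProfile | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate multi-pump shared-segment scenarios and run the full
    SD-trigger → correlation pipeline on every run.

    Returns one row per (run, pump) with the SD trigger time, the
    correlation decision delay (minutes) for co-occluding pumps, and the
    partner correlation.
    """
    cfg = config or DetectorConfig()
    sims = simulate_batch(scenarios, n_replicates, seed)
    profile = baseline or build_profile([run for _, _, run in sims])

    rows = []
    for i, rep, run in sims:
        onset = run.occlusion_onset_t
        combined_rate = float(sum(np.median(log.rates()) for log in run.pumps.values()))
        alarms = {}
        for pid, log in run.pumps.items():
            alarm, _ = run_detector(log, "sd", profile, cfg)
            if alarm is not None:
                alarms[pid] = alarm
        if not alarms:
            for pid in run.pump_ids():
                rows.append((i, rep, combined_rate, pid, "none", float("nan"),
                             False, float("nan")))
            continue
        t0 = min(a.alarm_t for a in alarms.values())
        triggers = [a for a in alarms.values() if a.alarm_t == t0]
        results = [co.classify_co_occlusion(run, trig, cfg) for trig in triggers]
        co_pumps = co.merge_results(results)
        delays: dict[int, float] = {}
        corr: dict[int, float | None] = {}
        for res in results:
            if onset is not None and res.decision_t >= onset:
                delays.update(co.alarm_delay_co(run, res))
            for pid, r in res.correlations.items():
                if r is not None:
                    corr[pid] = max(r, corr.get(pid, -math.inf))
        trigger_ids = {t.pump_id for t in triggers}
        for pid in run.pump_ids():
            role = "trigger" if pid in trigger_ids else "partner"
            rows.append((i, rep, combined_rate, pid, role,
                         corr.get(pid, float("nan")),
                         pid in co_pumps, delays.get(pid, float("nan"))))
    return pd.DataFrame(
        rows,
        columns=["scenario", "replicate", "combined_rate", "pump_id", "role",
                 "r", "co_occluding", "delay_min"],
    )


def plot_delays(report: AlarmReport, path: str) -> None:
    """Simple mean ± SD alarm-delay vs rate plot, one line per detector."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for det, sub in report.per_rate.groupby("detector"):
        ax.errorbar(sub["rate"], sub["mean_delay_min"],
                    yerr=sub["sd_delay_min"].fillna(0.0), marker="o",
                    capsize=3, label=det)
    ax.set_xscale("log", base=2)
    ax.set_xlabel("administration rate (ml/h)")
    ax.set_ylabel("alarm delay (min)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
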