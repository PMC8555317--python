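"""Multi-pump co-occlusion detection by pressure correlation.

When a blockage sits in a tubing segment shared by several pumps, Pascal's
law couples their pressures: all pumps feeding the occluded segment see the
same (near-instantaneous) pressure ramp, each on top of its own sensor
noise.  The correlation detector therefore runs only after a pump's SD
detector makes a final positive classification; at that decision tick it
correlates the trigger pump's last 30 pressure samples (60 s) with each
other pump's time-aligned window.  Partners with Pearson r > 0.8 are
classified as co-occluding with the trigger — a blockage in the shared
segment — while low correlation points to a blockage between the trigger
pump and the common line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detectors import AlarmEvent, DetectorConfig
from .logio import RunLog

CORRELATION_THRESHOLD = 0.8
CORRELATION_WINDOW = 30  # samples = 60 s at dt = 2


def pearson(x, y) -> float | None:
    """Pearson product-moment correlation of two equal-length windows.

    Returns None ("no decision") when either window has zero variance —
    a stopped or perfectly stable pump cannot be classified either way.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson needs two equal-length 1-d windows of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class CoOcclusionResult:
    trigger_pump: int
    correlations: dict[int, float | None]  # partner -> r (None = no decision)
    co_occluding: frozenset[int]
    decision_t: float

    def __post_init__(self) -> None:
        if self.trigger_pump in self.correlations:
            raise ValueError("trigger pump must not appear in its own partner map")
        if not self.co_occluding <= set(self.correlations):
            raise ValueError("co-occluding set must be a subset of the partners")


def classify_co_occlusion(
    run: RunLog,
    trigger: AlarmEvent,
    config: DetectorConfig | None = None,
    r_threshold: float = CORRELATION_THRESHOLD,
    window: int = CORRELATION_WINDOW,
) -> CoOcclusionResult:
    """Correlate the trigger pump's pressure window against every partner.

    Windows are time-aligned (same tick times, ending at the trigger's
    alarm tick).  Partners with an incomplete window, or zero variance in
    either window, get r = None and cannot be classified.  The decision is
    strict: co-occluding iff r > ``r_threshold``.
    """
    if trigger.detector != "sd":
        raise ValueError("co-occlusion classification is triggered by the sd detector")
    trig_log = run.pumps[trigger.pump_id]
    times = trig_log.times()
    idx = int(np.searchsorted(times, trigger.alarm_t))
    if idx >= len(times) or times[idx] != trigger.alarm_t:
        raise ValueError(f"trigger time {trigger.alarm_t} not on pump "
                         f"{trigger.pump_id}'s tick grid")
    if idx + 1 < window:
        raise ValueError("trigger pump window incomplete at decision time")
    window_t = times[idx + 1 - window: idx + 1]
    trig_p = trig_log.pressures()[idx + 1 - window: idx + 1]

    correlations: dict[int, float | None] = {}
    co = set()
    for pid, log in run.pumps.items():
        if pid == trigger.pump_id:
            continue
        t = log.times()
        lo = int(np.searchsorted(t, window_t[0]))
        hi = lo + window
        if hi > len(t) or not np.array_equal(t[lo:hi], window_t):
            correlations[pid] = None  # partner window incomplete / misaligned
            continue
        r = pearson(trig_p, log.pressures()[lo:hi])
        correlations[pid] = r
        if r is not None and r > r_threshold:
            co.add(pid)
    return CoOcclusionResult(trigger.pump_id, correlations, frozenset(co),
                             decision_t=trigger.alarm_t)


def merge_results(results: list[CoOcclusionResult]) -> frozenset[int]:
    """Union of co-occluding pumps (triggers included) over simultaneous
    triggers — when several pumps' SD detectors fire in the same tick each
    acts as a trigger."""
    pumps: set[int] = set()
    for res in results:
        if res.co_occluding:
            pumps.add(res.trigger_pump)
            pumps |= res.co_occluding
    return frozenset(pumps)


def alarm_delay_co(run: RunLog, result: CoOcclusionResult) -> dict[int, float]:
    """Alarm delay in minutes, from occlusion onset to the correlation
    decision, for the trigger pump and each co-occluding partner.

    The correlation decision happens at the SD trigger tick whenever the
    partner windows are already complete, so it adds no delay over the SD
    detector itself.
    """
    if run.occlusion_onset_t is None:
        raise ValueError("run has no occlusion onset")
    if result.decision_t < run.occlusion_onset_t:
        raise ValueError("decision precedes occlusion onset (false positive)")
    delay = (result.decision_t - run.occlusion_onset_t) / 60.0
    return {pid: delay for pid in {result.trigger_pump, *result.co_occluding}}
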