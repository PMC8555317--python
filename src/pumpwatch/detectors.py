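"""Streaming single-pump occlusion detectors.

Three detectors, all evaluated once per 2-s tick on the pump's own pressure
stream:

* **conventional** — alarm as soon as pressure reaches a fixed threshold
  (400 mmHg by default).  This is the reference pump behaviour.
* **regression** — a binary logistic model of occlusion probability from
  the administration rate Q (ml/h) and the mean pressure P (mmHg) over the
  most recent 60 s, gated on a positive OLS pressure slope over the most
  recent 30 s.  The default coefficients
  ``p = 1 / (1 + exp(-(-1.345 - 0.177*Q + 0.040*P)))`` were trained on
  bench occlusion runs; ``p >= 0.5`` is a preliminary occlusion call.
* **sd** — compares the SD of the last 30 pressure samples (60 s) against
  a per-rate baseline reference SD; a positive slope together with a
  window SD above twice the baseline SD is a preliminary occlusion call.
  During stable infusion ~95% of pressures lie within 2 SD of the mean, so
  a sustained excess in dispersion marks the start of an occlusion ramp
  regardless of the absolute pressure level.

Preliminary per-tick calls are debounced by majority voting: an actual
alarm (final positive classification) requires at least 6 of the 10 most
recent preliminary calls to be positive.  Voting history starts padded
with negatives, so no alarm is possible before ``vote_k`` ticks.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .baseline import BaselineProfile
from .logio import PressureSample, PumpLog, RunLog

DETECTOR_NAMES = ("conventional", "regression", "sd")


@dataclass(frozen=True)
class DetectorConfig:
    """All window lengths, thresholds and voting parameters.

    Windows are specified in wall time and converted to sample counts via
    ``dt`` (fractional counts rounded down), except ``stat_window`` which
    is a sample count directly (30 samples = 60 s at dt = 2).
    """

    dt: float = 2.0
    slope_window_s: float = 30.0
    stat_window: int = 30
    vote_k: int = 6
    vote_n: int = 10
    sd_multiplier: float = 2.0
    logit_b0: float = -1.345
    logit_bQ: float = -0.177
    logit_bP: float = 0.040
    conventional_threshold: float = 400.0
    sd_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.vote_k > self.vote_n:
            raise ValueError("vote_k must be <= vote_n")
        if self.slope_window_s <= 0 or self.stat_window < 2 or self.dt <= 0:
            raise ValueError("windows and dt must be positive (stat_window >= 2)")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")

    @property
    def slope_window_n(self) -> int:
        return int(self.slope_window_s / self.dt)

    @property
    def warmup_n(self) -> int:
        return max(self.slope_window_n, self.stat_window)


@dataclass(frozen=True)
class AlarmEvent:
    pump_id: int
    detector: str
    alarm_t: float
    kind: str = "single"  # or "co-occlusion"


class DetectorState:
    """Ring buffers of recent samples and preliminary classifications."""

    def __init__(self, config: DetectorConfig):
        self.config = config
        self.pressures: deque[float] = deque(maxlen=config.warmup_n)
        self.prelims: deque[bool] = deque([False] * config.vote_n, maxlen=config.vote_n)
        self.alarm_t: float | None = None
        self.last_t: float | None = None

    def push(self, sample: PressureSample) -> None:
        if self.last_t is not None and sample.t <= self.last_t:
            raise ValueError(f"non-increasing sample time {sample.t}")
        self.last_t = sample.t
        self.pressures.append(sample.pressure_P)

    @property
    def warmed_up(self) -> bool:
        return len(self.pressures) >= self.config.warmup_n

    def record(self, preliminary: bool, t: float) -> bool:
        """Append a preliminary call, vote, and latch the first alarm time."""
        self.prelims.append(preliminary)
        final = vote(self.prelims, self.config)
        if final and self.alarm_t is None:
            self.alarm_t = t
        return final


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def logistic_output(rate_Q: float, mean_P: float, config: DetectorConfig | None = None) -> float:
    """Occlusion probability from the logistic model."""
    cfg = config or DetectorConfig()
    z = cfg.logit_b0 + cfg.logit_bQ * rate_Q + cfg.logit_bP * mean_P
    # guard exp overflow for extreme inputs; the limit is exact there
    if z > 700:
        return 1.0
    if z < -700:
        return 0.0
    return 1.0 / (1.0 + math.exp(-z))


@lru_cache(maxsize=None)
def _slope_weights(n: int, dt: float) -> tuple[float, ...]:
    c = np.arange(n, dtype=float) - (n - 1) / 2.0
    return tuple(c / (dt * np.sum(c * c)))


def window_slope(pressures, dt: float) -> float:
    """OLS slope (mmHg/s) of pressure on time over an evenly spaced window."""
    p = tuple(pressures)
    n = len(p)
    if n < 2:
        raise ValueError("slope window not full")
    w = _slope_weights(n, dt)
    return math.fsum(map(lambda a, b: a * b, p, w))


def window_sd(pressures) -> float:
    """Two-pass sample SD (n−1 denominator) of a pressure window."""
    p = tuple(pressures)
    n = len(p)
    if n < 2:
        raise ValueError("stat window not full")
    m = math.fsum(p) / n
    return math.sqrt(math.fsum((x - m) ** 2 for x in p) / (n - 1))


def vote(prelims, config: DetectorConfig | None = None) -> bool:
    """Final classification: at least ``vote_k`` positives among the last
    ``vote_n`` preliminary classifications (short histories padded with
    negatives)."""
    cfg = config or DetectorConfig()
    recent = list(prelims)[-cfg.vote_n:]
    return sum(recent) >= cfg.vote_k


# ---------------------------------------------------------------------------
# Per-tick detector steps
# ---------------------------------------------------------------------------

def _slope_positive(state: DetectorState) -> bool:
    n = state.config.slope_window_n
    buf = list(state.pressures)
    return window_slope(buf[-n:], state.config.dt) > 0


def regression_step(
    state: DetectorState, sample: PressureSample, config: DetectorConfig | None = None
) -> tuple[bool, bool]:
    """One tick of the logistic-regression detector.

    Preliminary positive iff the 30-s pressure slope is positive *and* the
    logistic output on (rate, 60-s mean pressure) rounds to 1 (ties at
    exactly 0.5 round up).  Returns (preliminary, final).
    """
    cfg = config or state.config
    state.push(sample)
    preliminary = False
    if state.warmed_up and _slope_positive(state):
        buf = list(state.pressures)
        mean_p = math.fsum(buf[-cfg.stat_window:]) / cfg.stat_window
        preliminary = logistic_output(sample.rate_Q, mean_p, cfg) >= 0.5
    final = state.record(preliminary, sample.t)
    return preliminary, final


def sd_step(
    state: DetectorState,
    sample: PressureSample,
    baseline: BaselineProfile,
    config: DetectorConfig | None = None,
) -> tuple[bool, bool]:
    """One tick of the moving-window SD detector.

    Preliminary positive iff the 30-s slope is positive *and* the SD of the
    last ``stat_window`` pressures exceeds ``sd_multiplier`` times the
    baseline SD for the pump's rate.  A small floor guards the degenerate
    zero-noise baseline where any disturbance would otherwise alarm.
    """
    cfg = config or state.config
    state.push(sample)
    preliminary = False
    if state.warmed_up and _slope_positive(state):
        buf = list(state.pressures)
        sd = window_sd(buf[-cfg.stat_window:])
        ref = max(baseline.sd_for_rate(sample.rate_Q), cfg.sd_floor)
        preliminary = sd > cfg.sd_multiplier * ref
    final = state.record(preliminary, sample.t)
    return preliminary, final


def conventional_step(
    state: DetectorState, sample: PressureSample, config: DetectorConfig | None = None
) -> bool:
    """One tick of the conventional threshold alarm (no voting, no warm-up)."""
    cfg = config or state.config
    state.push(sample)
    final = sample.pressure_P >= cfg.conventional_threshold
    if final and state.alarm_t is None:
        state.alarm_t = sample.t
    return final


# ---------------------------------------------------------------------------
# Whole-log replay
# ---------------------------------------------------------------------------

def run_detector(
    log: PumpLog,
    detector: str,
    baseline: BaselineProfile | None = None,
    config: DetectorConfig | None = None,
) -> tuple[AlarmEvent | None, pd.DataFrame]:
    """Replay a streaming detector over a recorded log.

    Returns the first alarm (or None) and the per-tick classification trace
    with columns ``t_s, preliminary, final``.  Alarms are non-latching in
    the trace — the final classification can self-correct back to negative
    after a transient — but the reported alarm time is the first final
    positive, which is how alarm delay is measured.
    """
    if detector not in DETECTOR_NAMES:
        raise ValueError(f"unknown detector {detector!r}; expected one of {DETECTOR_NAMES}")
    if detector == "sd" and baseline is None:
        raise ValueError("sd detector requires a baseline profile")
    cfg = config or DetectorConfig()
    state = DetectorState(cfg)
    ts, prelims, finals = [], [], []
    for sample in log.samples:
        if detector == "conventional":
            final = conventional_step(state, sample, cfg)
            preliminary = final
        elif detector == "regression":
            preliminary, final = regression_step(state, sample, cfg)
        else:
            preliminary, final = sd_step(state, sample, baseline, cfg)
        ts.append(sample.t)
        prelims.append(preliminary)
        finals.append(final)
    trace = pd.DataFrame({"t_s": ts, "preliminary": prelims, "final": finals})
    alarm = None
    if state.alarm_t is not None:
        alarm = AlarmEvent(log.pump_id, detector, state.alarm_t)
    return alarm, trace


# ---------------------------------------------------------------------------
# Model refitting and window-size selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    b0: float
    bQ: float
    bP: float
    se: tuple[float, float, float] | None  # None for the regularized fallback
    regularized: bool


def fit_logistic(labeled) -> LogisticFit:
    """Maximum-likelihood logistic refit from (Q, P, label) training cases.

    The shipped default coefficients come from bench training data; this
    supports retraining on new logs.  Under perfect separation the MLE
    diverges, so a ridge-regularized fit is substituted with a warning.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    arr = np.asarray(list(labeled), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("labeled data must be (Q, P, label) triples")
    y = arr[:, 2]
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("both labels (0 and 1) must be present")
    X = sm.add_constant(arr[:, :2])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings handled below
            res = sm.Logit(y, X).fit(disp=0)
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        ok = bool(res.mle_retvals.get("converged", False))
        if ok and np.all(np.isfinite(bse)) and np.max(np.abs(params)) < 1e3:
            return LogisticFit(*map(float, params), se=tuple(map(float, bse)),
                               regularized=False)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        pass

    warnings.warn("perfect separation in logistic training data; "
                  "falling back to a ridge-regularized fit")
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0).fit(arr[:, :2], y.astype(int))
    return LogisticFit(float(clf.intercept_[0]), float(clf.coef_[0][0]),
                       float(clf.coef_[0][1]), se=None, regularized=True)


def sweep_window_sizes(
    runs: list[RunLog],
    sizes_s,
    baseline: BaselineProfile | None = None,
    config: DetectorConfig | None = None,
    detector: str = "sd",
) -> pd.Series:
    """Per-tick classification accuracy (%) as a function of the statistic
    window size in seconds.

    For each size the detector's stat window is set to ``size/dt`` samples
    and replayed over every run; accuracy is the fraction of ticks whose
    final classification matches the phase ground truth (pre-onset and
    unoccluded pumps negative, post-onset occluded pumps positive).
    """
    cfg = config or DetectorConfig()
    acc = {}
    for size in sizes_s:
        if size < 2 * cfg.dt:
            raise ValueError(f"window size {size}s is below 2 samples at dt={cfg.dt}")
        sized = replace(cfg, stat_window=int(size / cfg.dt))
        correct = total = 0
        for run in runs:
            onset = math.inf if run.occlusion_onset_t is None else run.occlusion_onset_t
            for log in run.pumps.values():
                occluded = log.onset_time() is not None
                _, trace = run_detector(log, detector, baseline, sized)
                truth = occluded & (trace["t_s"].to_numpy() >= onset)
                correct += int(np.sum(trace["final"].to_numpy() == truth))
                total += len(trace)
        acc[float(size)] = 100.0 * correct / total
    out = pd.Series(acc, name="accuracy_pct")
    out.index.name = "window_s"
    return out
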