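"""Data model and CSV I/O for multi-pump infusion pressure logs.

A *run* is a set of synchronized per-pump pressure time series, sampled
nominally every ``dt`` seconds (2 s by default).  Each record carries the
pump identifier, the time in seconds from run start, the administration
rate Q in ml/h, an event code, and the line pressure P in mmHg.  An
``occlusion`` event marks the tick at which the line was occluded.

The CSV dialect is fixed (comma separator, ``.`` decimal, header required)
so that write/read round-trips are lossless.
"""

from __future__ import annotations

import enum
import math
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CSV_COLUMNS = ["pump_id", "t_s", "rate_ml_h", "event", "pressure_mmHg"]

#: Pump occlusion state within a run, used for outcome classification.
TOPOLOGY_LABELS = ("unoccluded", "occluded-alone", "occluded-shared")


class LogParseError(ValueError):
    """A log file row could not be parsed."""


class LogValidationError(ValueError):
    """A parsed log violates a structural invariant."""


class Event(enum.Enum):
    NONE = "none"
    OCCLUSION_ONSET = "occlusion"


@dataclass(frozen=True)
class PressureSample:
    """One pump's reading at one tick."""

    pump_id: int
    t: float
    rate_Q: float
    pressure_P: float
    event: Event = Event.NONE

    def __post_init__(self) -> None:
        if self.t < 0:
            raise LogValidationError(f"negative timestamp t={self.t}")
        if self.rate_Q < 0:
            raise LogValidationError(f"negative rate Q={self.rate_Q}")
        if not math.isfinite(self.pressure_P):
            raise LogValidationError(f"non-finite pressure at t={self.t}")


@dataclass
class PumpLog:
    """Time-ordered samples for one pump over one run.

    Timestamps must be strictly increasing and all samples must carry the
    same ``pump_id``; at most one occlusion-onset event is allowed.
    """

    pump_id: int
    samples: list[PressureSample] = field(default_factory=list)
    dt: float = 2.0

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.pump_id != self.pump_id:
                raise LogValidationError(
                    f"sample pump_id {s.pump_id} != log pump_id {self.pump_id}"
                )
        t = self.times()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise LogValidationError(
                f"pump {self.pump_id}: timestamps not strictly increasing"
            )
        n_onsets = sum(s.event is Event.OCCLUSION_ONSET for s in self.samples)
        if n_onsets > 1:
            raise LogValidationError(
                f"pump {self.pump_id}: {n_onsets} occlusion events (max 1)"
            )

    def __len__(self) -> int:
        return len(self.samples)

    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples], dtype=float)

    def pressures(self) -> np.ndarray:
        return np.array([s.pressure_P for s in self.samples], dtype=float)

    def rates(self) -> np.ndarray:
        return np.array([s.rate_Q for s in self.samples], dtype=float)

    def onset_time(self) -> float | None:
        for s in self.samples:
            if s.event is Event.OCCLUSION_ONSET:
                return s.t
        return None

    def slice_time(self, t_min: float = -math.inf, t_max: float = math.inf) -> "PumpLog":
        """Sub-log with samples in the half-open interval [t_min, t_max)."""
        kept = [s for s in self.samples if t_min <= s.t < t_max]
        return PumpLog(self.pump_id, kept, self.dt)


@dataclass
class RunLog:
    """One multi-pump run: one PumpLog per pump plus ground-truth metadata.

    ``occlusion_onset_t`` is recovered from the event column if not given.
    ``topology`` (per-pump occlusion state, see TOPOLOGY_LABELS) is ground
    truth known only to the simulator / scenario sidecar, never to detectors.
    """

    pumps: dict[int, PumpLog]
    occlusion_onset_t: float | None = None
    topology: dict[int, str] | None = None

    def __post_init__(self) -> None:
        event_ts = {
            log.onset_time() for log in self.pumps.values() if log.onset_time() is not None
        }
        if len(event_ts) > 1:
            raise LogValidationError(f"conflicting occlusion event times: {sorted(event_ts)}")
        if event_ts:
            (t_event,) = event_ts
            if self.occlusion_onset_t is None:
                self.occlusion_onset_t = t_event
            elif not math.isclose(self.occlusion_onset_t, t_event):
                raise LogValidationError(
                    f"occlusion_onset_t={self.occlusion_onset_t} does not match "
                    f"event timestamp {t_event}"
                )
        if self.topology is not None:
            for pid, label in self.topology.items():
                if label not in TOPOLOGY_LABELS:
                    raise LogValidationError(f"unknown topology label {label!r} for pump {pid}")
        spans = {
            (log.samples[0].t, log.samples[-1].t)
            for log in self.pumps.values()
            if len(log) > 0
        }
        if len(spans) > 1:
            raise LogValidationError(f"pump logs cover different time spans: {sorted(spans)}")

    def pump_ids(self) -> list[int]:
        return sorted(self.pumps)


def _atomic_write_text(text: str, path: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_run_log(run: RunLog, path: str) -> None:
    """Write a RunLog as CSV, rows ordered by (t, pump_id)."""
    rows = [
        (s.pump_id, s.t, s.rate_Q, s.event.value, s.pressure_P)
        for log in run.pumps.values()
        for s in log.samples
    ]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df = df.sort_values(["t_s", "pump_id"], kind="stable")
    _atomic_write_text(df.to_csv(index=False), path)


def read_run_log(path: str, dt: float = 2.0) -> RunLog:
    """Read a RunLog CSV written by :func:`write_run_log`.

    Raises LogParseError naming the offending line for malformed rows and
    LogValidationError for structural violations (e.g. non-monotone
    timestamps within a pump).
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # malformed row; pandas names the line
        raise LogParseError(str(exc)) from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise LogParseError(f"{path}: missing columns {missing}")

    event_values = {e.value: e for e in Event}
    samples_by_pump: dict[int, list[PressureSample]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after header
        try:
            pid = int(getattr(row, "pump_id"))
            t = float(getattr(row, "t_s"))
            rate = float(getattr(row, "rate_ml_h"))
            pressure = float(getattr(row, "pressure_mmHg"))
        except ValueError as exc:
            raise LogParseError(f"{path}: line {line_no}: {exc}") from exc
        ev_raw = getattr(row, "event")
        if ev_raw not in event_values:
            raise LogParseError(
                f"{path}: line {line_no}: unknown event {ev_raw!r} "
                f"(expected one of {sorted(event_values)})"
            )
        try:
            sample = PressureSample(pid, t, rate, pressure, event_values[ev_raw])
        except LogValidationError as exc:
            raise LogParseError(f"{path}: line {line_no}: {exc}") from exc
        samples_by_pump.setdefault(pid, []).append(sample)

    pumps = {}
    for pid, samples in samples_by_pump.items():
        samples.sort(key=lambda s: s.t)
        pumps[pid] = PumpLog(pid, samples, dt)
    return RunLog(pumps)
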