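"""Baseline characterization and occlusion-phase regression.

The SD detector needs a *reference set*: for each administration rate, the
mean and SD of line pressure during stable, non-occluded infusion.  Runs
may begin with a start-up transient while the line pressurizes; those
samples are trimmed before characterization.  The occlusion phase is
summarized by an ordinary least-squares fit of pressure on time, whose
slope (mmHg/s) extrapolates conventional threshold-alarm delays for any
threshold and baseline pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .logio import PumpLog, RunLog, _atomic_write_text

#: Default start-up stabilization rule: the log is considered stable from
#: the first 30-sample window whose OLS slope magnitude is below this
#: threshold (mmHg/s).
STABILIZATION_WINDOW = 30
STABILIZATION_SLOPE = 0.05

#: Shapiro–Wilk is only calibrated up to ~5000 points; larger pooled
#: segments are subsampled for the normality p-value (never for mean/SD).
_SHAPIRO_MAX_N = 5000


@dataclass(frozen=True)
class BaselineEntry:
    rate_Q: float
    mean_P: float
    sd_P: float
    n: int
    normality_p: float  # NaN when the test is undefined (e.g. constant data)


@dataclass
class BaselineProfile:
    """Per-rate baseline pressure characteristics (the SD detector's
    reference set).  SD lookup at an unmeasured rate interpolates linearly
    between neighbouring rates, clamped at the extremes."""

    entries: dict[float, BaselineEntry]

    def __post_init__(self) -> None:
        for rate, e in self.entries.items():
            if e.sd_P < 0 or e.n < 2:
                raise ValueError(f"invalid baseline entry for rate {rate}")

    def rates(self) -> list[float]:
        return sorted(self.entries)

    def sd_for_rate(self, rate: float) -> float:
        r = self.rates()
        return float(np.interp(rate, r, [self.entries[k].sd_P for k in r]))

    def mean_for_rate(self, rate: float) -> float:
        r = self.rates()
        return float(np.interp(rate, r, [self.entries[k].mean_P for k in r]))

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame(
            [
                (e.rate_Q, e.mean_P, e.sd_P, e.n, e.normality_p)
                for e in (self.entries[r] for r in self.rates())
            ],
            columns=["rate_ml_h", "mean_mmHg", "sd_mmHg", "n", "normality_p"],
        )
        _atomic_write_text(df.to_csv(index=False), path)

    @classmethod
    def from_csv(cls, path: str) -> "BaselineProfile":
        df = pd.read_csv(path)
        entries = {
            float(r.rate_ml_h): BaselineEntry(
                float(r.rate_ml_h), float(r.mean_mmHg), float(r.sd_mmHg),
                int(r.n), float(r.normality_p),
            )
            for r in df.itertuples(index=False)
        }
        return cls(entries)


@dataclass(frozen=True)
class OcclusionFit:
    """OLS summary of the occlusion-phase pressure ramp."""

    slope: float  # mmHg/s
    intercept: float  # mmHg, at occlusion onset
    r_squared: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValueError("non-finite occlusion fit")


def _window_slopes(pressures: np.ndarray, times: np.ndarray, w: int) -> np.ndarray:
    """OLS slope of pressure on time for every contiguous w-sample window."""
    pw = np.lib.stride_tricks.sliding_window_view(pressures, w)
    tw = np.lib.stride_tricks.sliding_window_view(times, w)
    tc = tw - tw.mean(axis=1, keepdims=True)
    return np.sum(pw * tc, axis=1) / np.sum(tc * tc, axis=1)


def trim_startup(
    log: PumpLog,
    window: int = STABILIZATION_WINDOW,
    slope_threshold: float = STABILIZATION_SLOPE,
) -> PumpLog:
    """Drop leading start-up samples until the pressure has stabilized.

    Stability is declared at the first ``window``-sample sliding window
    whose OLS slope magnitude falls below ``slope_threshold``; the returned
    log is the suffix starting at that window.
    """
    if len(log) < 2 * window:
        raise ValueError(
            f"pump {log.pump_id}: need at least {2 * window} samples to trim start-up"
        )
    slopes = _window_slopes(log.pressures(), log.times(), window)
    stable = np.flatnonzero(np.abs(slopes) < slope_threshold)
    if stable.size == 0:
        raise ValueError(f"pump {log.pump_id}: no stable baseline segment")
    start = int(stable[0])
    return PumpLog(log.pump_id, log.samples[start:], log.dt)


def _normality_p(values: np.ndarray) -> float:
    if np.ptp(values) == 0:
        return float("nan")
    if values.size > _SHAPIRO_MAX_N:
        values = values[:: values.size // _SHAPIRO_MAX_N + 1]
    return float(stats.shapiro(values).pvalue)


def characterize(log: PumpLog, occlusion_onset_t: float | None = None) -> BaselineEntry:
    """Baseline mean, SD (n−1 denominator), n and Shapiro–Wilk normality
    p-value of the non-occluded segment (t < onset) of a trimmed log."""
    onset = math.inf if occlusion_onset_t is None else occlusion_onset_t
    seg = log.slice_time(t_max=onset)
    if len(seg) < 30:
        raise ValueError(
            f"pump {log.pump_id}: insufficient baseline data (n={len(seg)} < 30)"
        )
    p = seg.pressures()
    rate = float(np.median(seg.rates()))
    return BaselineEntry(
        rate_Q=rate,
        mean_P=float(np.mean(p)),
        sd_P=float(np.std(p, ddof=1)),
        n=len(seg),
        normality_p=_normality_p(p),
    )


def build_profile(runs: list[RunLog], trim: bool = True) -> BaselineProfile:
    """Pool non-occluded segments across runs, grouped by rate, into a
    BaselineProfile.  Start-up transients are trimmed per pump first."""
    pooled: dict[float, list[np.ndarray]] = {}
    for run in runs:
        onset = math.inf if run.occlusion_onset_t is None else run.occlusion_onset_t
        for log in run.pumps.values():
            seg = trim_startup(log) if trim else log
            seg = seg.slice_time(t_max=onset)
            if len(seg) == 0:
                continue
            rate = float(np.median(seg.rates()))
            pooled.setdefault(rate, []).append(seg.pressures())
    entries = {}
    for rate, chunks in pooled.items():
        p = np.concatenate(chunks)
        if p.size < 30:
            raise ValueError(f"insufficient pooled baseline data for rate {rate}")
        entries[rate] = BaselineEntry(
            rate, float(np.mean(p)), float(np.std(p, ddof=1)), int(p.size),
            _normality_p(p),
        )
    return BaselineProfile(entries)


def fit_occlusion(log: PumpLog, occlusion_onset_t: float) -> OcclusionFit:
    """OLS of pressure on time over the post-onset segment.

    The intercept is referenced to the onset (time re-zeroed), so it
    estimates the pressure at the start of the occlusion.
    """
    seg = log.slice_time(t_min=occlusion_onset_t)
    if len(seg) < 5:
        raise ValueError(
            f"pump {log.pump_id}: need >= 5 post-onset samples, got {len(seg)}"
        )
    t = seg.times() - occlusion_onset_t
    p = seg.pressures()
    res = stats.linregress(t, p)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0
    return OcclusionFit(float(res.slope), float(res.intercept), r2)


def conventional_delay(threshold: float, baseline_P: float, fit: OcclusionFit) -> float:
    """Extrapolated conventional alarm delay in minutes: the time for the
    fitted ramp to climb from ``baseline_P`` to ``threshold``."""
    if fit.slope <= 0:
        raise ValueError("occlusion never reaches threshold (slope <= 0)")
    if threshold < baseline_P:
        raise ValueError(f"threshold {threshold} below baseline {baseline_P}")
    return (threshold - baseline_P) / fit.slope / 60.0


def delay_table(
    fits: dict[float, OcclusionFit],
    thresholds: tuple[float, ...] = (300, 400, 500, 600, 700, 800),
    baseline_P: float = 150.0,
) -> pd.DataFrame:
    """Matrix of extrapolated conventional delays (minutes), rates as rows
    and alarm thresholds (mmHg) as columns, at a worst-case clinical
    baseline pressure (default 150 mmHg)."""
    rows = {
        rate: {thr: conventional_delay(thr, baseline_P, fit) for thr in thresholds}
        for rate, fit in sorted(fits.items())
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "rate_ml_h"
    df.columns = [f"{int(t)}_mmHg" for t in thresholds]
    return df
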