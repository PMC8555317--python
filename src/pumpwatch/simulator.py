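"""Synthetic multi-pump pressure-log generator.

Emulates the structure of bench occlusion runs on syringe pumps: a stable,
noisy non-occluded baseline (optionally preceded by a start-up pressure
rise from the venous counter pressure up to the working baseline), followed
at a known onset time by a linear occlusion pressure ramp that continues
until a conventional 400-mmHg pump alarm would fire or a maximum duration
elapses.  Pumps that share an occluded tubing segment ("occlusion group")
experience the identical deterministic ramp — fluid pressure equilibrates
essentially instantaneously across a closed fluid column — while keeping
independent per-pump sensor noise.

The ramp slopes can be *calibrated*: given a table of conventional-alarm
delays per administration rate, the slope for each rate is backed out as
(threshold − baseline) / delay, so a simulated conventional alarm
reproduces the tabulated delay.  The default calibration table holds the
bench-measured conventional (400 mmHg) alarm delays per rate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .logio import Event, PressureSample, PumpLog, RunLog, _atomic_write_text

#: 1 cmH2O in mmHg (densities of water and mercury at reference conditions).
CM_H2O_TO_MMHG = 0.7356

#: Bench-measured mean conventional (400 mmHg) alarm delays per rate, minutes.
DEFAULT_CONVENTIONAL_DELAY_MIN: dict[float, float] = {
    1.0: 21.9, 2.0: 10.8, 4.0: 6.0, 8.0: 2.7, 16.0: 1.5, 32.0: 1.4,
}

#: Default non-occluded baseline pressure per rate (mmHg).  Low values,
#: consistent with a ~5 mmHg venous counter pressure; pressure rises mildly
#: with rate through tubing resistance.
DEFAULT_BASELINE_MEAN: dict[float, float] = {
    1.0: 5.0, 2.0: 9.0, 4.0: 13.0, 8.0: 17.0, 16.0: 21.0, 32.0: 25.0,
}

#: Default baseline pressure noise SD per rate (mmHg); stepper and sensor
#: noise grow mildly with rate.
DEFAULT_BASELINE_SD: dict[float, float] = {
    1.0: 0.5, 2.0: 0.8, 4.0: 1.1, 8.0: 1.4, 16.0: 1.7, 32.0: 2.0,
}

DEFAULT_COUNTER_PRESSURE = 5.2  # mmHg, ~7 cm water column


def counter_pressure_mmHg(height_cm: float) -> float:
    """Hydrostatic counter pressure of a water column, in mmHg.

    ``height_cm`` is the submersion depth of the catheter tip in cm of
    water; 7 cm corresponds to about 5.2 mmHg, a normal central venous
    pressure.
    """
    if height_cm < 0:
        raise ValueError(f"negative water-column height: {height_cm}")
    return height_cm * CM_H2O_TO_MMHG


@dataclass
class PumpScenario:
    """Ground-truth generating parameters for one pump in one run."""

    pump_id: int
    rate_Q: float
    baseline_mean: float
    baseline_sd: float = 1.0
    startup_duration: float = 0.0
    occlusion_slope: float = 0.0  # mmHg/s; 0 means unoccluded
    group: str | None = None  # pumps sharing a label co-occlude

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")
        if self.occlusion_slope < 0:
            raise ValueError("occlusion_slope must be >= 0")
        if self.startup_duration < 0:
            raise ValueError("startup_duration must be >= 0")

    @property
    def occluded(self) -> bool:
        return self.occlusion_slope > 0


@dataclass
class SimConfig:
    """Full specification of one simulated run."""

    pumps: list[PumpScenario]
    dt: float = 2.0
    pre_occlusion_duration: float = 600.0
    max_post_duration: float = 600.0
    conventional_stop_threshold: float = 400.0
    counter_pressure: float = DEFAULT_COUNTER_PRESSURE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.pre_occlusion_duration <= 0 or self.max_post_duration <= 0:
            raise ValueError("durations and dt must be positive")
        slopes_by_group: dict[str, set[float]] = {}
        for sc in self.pumps:
            if sc.group is not None and sc.occluded:
                slopes_by_group.setdefault(sc.group, set()).add(sc.occlusion_slope)
        for g, slopes in slopes_by_group.items():
            if len(slopes) > 1:
                raise ValueError(
                    f"occlusion group {g!r} has inconsistent slopes {sorted(slopes)}; "
                    "a shared segment has a single coupled ramp"
                )

    @property
    def occlusion_onset_t(self) -> float:
        return self.pre_occlusion_duration


def _topology(pumps: list[PumpScenario]) -> dict[int, str]:
    group_count: dict[str, int] = {}
    for sc in pumps:
        if sc.occluded and sc.group is not None:
            group_count[sc.group] = group_count.get(sc.group, 0) + 1
    topo = {}
    for sc in pumps:
        if not sc.occluded:
            topo[sc.pump_id] = "unoccluded"
        elif sc.group is not None and group_count.get(sc.group, 0) > 1:
            topo[sc.pump_id] = "occluded-shared"
        else:
            topo[sc.pump_id] = "occluded-alone"
    return topo


def simulate_run(config: SimConfig) -> RunLog:
    """Generate one multi-pump run.

    The tick grid is half-open: t = 0, dt, ..., < onset + max_post_duration,
    truncated at the first tick at which any occluded pump's pressure
    reaches ``conventional_stop_threshold`` (the bench runs stopped at the
    pump's own 400-mmHg alarm).  Fixed seed gives identical output; per-pump
    noise streams are derived from (seed, pump_id) so adding a pump does not
    perturb the others.
    """
    onset = config.occlusion_onset_t
    n_ticks = int(round((onset + config.max_post_duration) / config.dt))
    times = np.arange(n_ticks) * config.dt

    pressures: dict[int, np.ndarray] = {}
    for sc in config.pumps:
        det = np.full(n_ticks, sc.baseline_mean)
        if sc.startup_duration > 0:
            in_startup = times < sc.startup_duration
            det[in_startup] = config.counter_pressure + (
                sc.baseline_mean - config.counter_pressure
            ) * times[in_startup] / sc.startup_duration
        if sc.occluded:
            post = times >= onset
            det[post] += sc.occlusion_slope * (times[post] - onset)
        noise = np.zeros(n_ticks)
        if sc.baseline_sd > 0:
            rng = np.random.default_rng([config.seed, sc.pump_id])
            noise = rng.normal(0.0, sc.baseline_sd, n_ticks)
            noise[times < sc.startup_duration] = 0.0
        pressures[sc.pump_id] = det + noise

    stop = n_ticks - 1
    occluded_ids = [sc.pump_id for sc in config.pumps if sc.occluded]
    if occluded_ids:
        peak = np.max([pressures[pid] for pid in occluded_ids], axis=0)
        crossed = np.flatnonzero((times >= onset) & (peak >= config.conventional_stop_threshold))
        if crossed.size:
            stop = min(stop, int(crossed[0]))

    onset_idx = int(np.searchsorted(times, onset))
    pumps: dict[int, PumpLog] = {}
    for sc in config.pumps:
        samples = []
        for i in range(stop + 1):
            ev = Event.NONE
            if sc.occluded and i == onset_idx:
                ev = Event.OCCLUSION_ONSET
            samples.append(
                PressureSample(sc.pump_id, float(times[i]), sc.rate_Q,
                               float(pressures[sc.pump_id][i]), ev)
            )
        pumps[sc.pump_id] = PumpLog(sc.pump_id, samples, config.dt)

    return RunLog(
        pumps,
        occlusion_onset_t=onset if occluded_ids else None,
        topology=_topology(config.pumps),
    )


# ---------------------------------------------------------------------------
# Calibration: back ramp slopes out of conventional-alarm delays
# ---------------------------------------------------------------------------

def calibrated_slope(
    rate: float,
    delay_table_min: dict[float, float] | None = None,
    threshold: float = 400.0,
    baseline_means: dict[float, float] | None = None,
) -> float:
    """Occlusion ramp slope (mmHg/s) that reproduces the tabulated
    conventional alarm delay at ``rate``.

    slope = (threshold − baseline_mean) / delay.  For rates between table
    rows the slope is interpolated linearly in rate and clamped at the
    extremes.
    """
    table = dict(delay_table_min or DEFAULT_CONVENTIONAL_DELAY_MIN)
    means = dict(baseline_means or DEFAULT_BASELINE_MEAN)
    rates = np.array(sorted(table), dtype=float)
    slopes = []
    for r in rates:
        delay_s = table[r] * 60.0
        if delay_s <= 0:
            raise ValueError(f"non-positive delay for rate {r}")
        baseline = float(np.interp(r, sorted(means), [means[k] for k in sorted(means)]))
        if threshold <= baseline:
            raise ValueError(f"threshold {threshold} must exceed baseline {baseline}")
        slopes.append((threshold - baseline) / delay_s)
    return float(np.interp(rate, rates, slopes))


def calibrated_scenarios(
    delay_table_min: dict[float, float] | None = None,
    threshold: float = 400.0,
    baseline_means: dict[float, float] | None = None,
    baseline_sds: dict[float, float] | None = None,
    dt: float = 2.0,
    pre_occlusion_duration: float = 600.0,
    seed: int = 0,
) -> list[SimConfig]:
    """One single-pump SimConfig per table rate, with the occlusion slope
    calibrated so the simulated conventional alarm reproduces the tabulated
    delay.  ``max_post_duration`` is the calibrated delay plus one minute of
    head-room so the alarm is always reached.
    """
    table = dict(delay_table_min or DEFAULT_CONVENTIONAL_DELAY_MIN)
    means = dict(baseline_means or DEFAULT_BASELINE_MEAN)
    sds = dict(baseline_sds or DEFAULT_BASELINE_SD)
    configs = []
    for rate in sorted(table):
        mean = float(np.interp(rate, sorted(means), [means[k] for k in sorted(means)]))
        sd = float(np.interp(rate, sorted(sds), [sds[k] for k in sorted(sds)]))
        slope = calibrated_slope(rate, table, threshold, means)
        configs.append(
            SimConfig(
                pumps=[PumpScenario(0, rate, mean, sd, occlusion_slope=slope)],
                dt=dt,
                pre_occlusion_duration=pre_occlusion_duration,
                max_post_duration=table[rate] * 60.0 + 60.0,
                conventional_stop_threshold=threshold,
                seed=seed,
            )
        )
    return configs


def co_occlusion_configs(
    secondary_rates: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0),
    primary_rate: float = 1.0,
    baseline_sd: float = 1.0,
    delay_table_min: dict[float, float] | None = None,
    threshold: float = 400.0,
    dt: float = 2.0,
    pre_occlusion_duration: float = 600.0,
    seed: int = 0,
) -> list[SimConfig]:
    """Two-pump shared-segment occlusion scenarios.

    The primary pump runs at ``primary_rate`` in every scenario while the
    secondary rate varies; the shared ramp is calibrated to the *combined*
    rate, since both pumps feed the occluded segment.
    """
    table = dict(delay_table_min or DEFAULT_CONVENTIONAL_DELAY_MIN)
    means = DEFAULT_BASELINE_MEAN
    configs = []
    for rate2 in secondary_rates:
        combined = primary_rate + rate2
        slope = calibrated_slope(combined, table, threshold)
        rates_sorted = sorted(table)
        delay_min = float(np.interp(combined, rates_sorted, [table[r] for r in rates_sorted]))
        pumps = []
        for pid, rate in ((0, primary_rate), (1, rate2)):
            mean = float(np.interp(rate, sorted(means), [means[k] for k in sorted(means)]))
            pumps.append(
                PumpScenario(pid, rate, mean, baseline_sd,
                             occlusion_slope=slope, group="shared")
            )
        configs.append(
            SimConfig(
                pumps=pumps,
                dt=dt,
                pre_occlusion_duration=pre_occlusion_duration,
                max_post_duration=delay_min * 60.0 + 120.0,
                conventional_stop_threshold=threshold,
                seed=seed,
            )
        )
    return configs


# ---------------------------------------------------------------------------
# Scenario sidecar (YAML)
# ---------------------------------------------------------------------------

_SCENARIO_KEYS = {
    "dt", "pre_occlusion_duration", "max_post_duration",
    "conventional_stop_threshold", "counter_pressure", "seed", "pumps",
}
_PUMP_KEYS = {
    "pump_id", "rate_Q", "baseline_mean", "baseline_sd",
    "startup_duration", "occlusion_slope", "group",
}


def write_scenario(config: SimConfig, path: str) -> None:
    """Persist a SimConfig as a flat YAML sidecar next to the log CSV."""
    doc = asdict(config)
    _atomic_write_text(yaml.safe_dump(doc, sort_keys=True), path)


def read_scenario(path: str) -> SimConfig:
    """Load a SimConfig sidecar; unknown keys are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: scenario file must be a mapping")
    unknown = set(doc) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown scenario keys {sorted(unknown)}")
    pumps_doc = doc.pop("pumps", [])
    pumps = []
    for p in pumps_doc:
        bad = set(p) - _PUMP_KEYS
        if bad:
            raise ValueError(f"{path}: unknown pump keys {sorted(bad)}")
        pumps.append(PumpScenario(**p))
    return SimConfig(pumps=pumps, **doc)
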