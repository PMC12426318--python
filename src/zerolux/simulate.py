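"""Seeded synthetic light-logger data with realistic zero inflation.

Emulates a week of concurrent measurements: a stationary rooftop
("environment") sensor seeing the full diurnal daylight curve — zero at
night, up to tens of thousands of lux of melanopic EDI at solar noon —
and a wearable ("participant") sensor whose exposure is driven by a
behavioral schedule: darkness while asleep, a few-hundred-lux indoor
plateau, and an attenuated slice of the outdoor level when outside.
Both sensors share a detection floor: any true illuminance below it is
recorded as exactly 0 lux, which is the zero-inflation mechanism the
modeling strategies have to cope with.

The daylight curve is a powered half-sine between civil dawn and dusk
(solar geometry is deliberately out of scope; dawn and dusk are
configuration inputs), with multiplicative lognormal measurement noise
on the log10 scale.  A separate generator draws compound Poisson–Gamma
noise around an arbitrary smooth mean curve for parameter-recovery
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import LightTimeSeries

__all__ = ["ScheduleEntry", "SimConfig", "simulate_environment",
           "simulate_participant", "simulate_tweedie_series", "diurnal_mu"]


@dataclass(frozen=True)
class ScheduleEntry:
    """One behavioral state: [start, end) clock seconds and a state name."""

    start: float   # seconds from midnight
    end: float
    state: str     # sleep | dark | indoor | outdoor


def _default_schedule() -> list[ScheduleEntry]:
    """A plausible office-worker day with one dark indoor episode.

    Sleep 23:00-07:00, a morning and evening outdoor commute, office
    light otherwise, and a 30-min dark indoor state in the afternoon so
    zeros also occur in daytime (as wearable data show).
    """
    h = 3600.0
    return [
        ScheduleEntry(0 * h, 7 * h, "sleep"),
        ScheduleEntry(7 * h, 8.5 * h, "indoor"),
        ScheduleEntry(8.5 * h, 9 * h, "outdoor"),
        ScheduleEntry(9 * h, 12.5 * h, "indoor"),
        ScheduleEntry(12.5 * h, 13 * h, "outdoor"),
        ScheduleEntry(13 * h, 15 * h, "indoor"),
        ScheduleEntry(15 * h, 15.5 * h, "dark"),
        ScheduleEntry(15.5 * h, 17.5 * h, "indoor"),
        ScheduleEntry(17.5 * h, 18 * h, "outdoor"),
        ScheduleEntry(18 * h, 23 * h, "indoor"),
        ScheduleEntry(23 * h, 24 * h, "sleep"),
    ]


@dataclass
class SimConfig:
    """Scenario parameters for the synthetic light-logger week.

    Defaults describe a temperate-latitude week in late spring: daylight
    from 06:00 civil dawn to 20:00 civil dusk peaking at ``10**4.5``
    (~32 000) lux melanopic EDI, a 250-lux indoor plateau, 30% of ambient
    light reaching the wearable outdoors, a 1-lux detection floor and
    5-minute sampling with lognormal noise of 0.2 decades.
    """

    dawn: float = 6 * 3600.0            # seconds from midnight
    dusk: float = 20 * 3600.0
    peak_env: float = 10 ** 4.5         # lux at solar noon
    indoor_level: float = 250.0         # lux
    outdoor_attenuation: float = 0.3    # fraction of ambient seen outdoors
    detection_floor: float = 1.0        # lux; below -> recorded as 0
    interval: float = 300.0             # seconds
    days: int = 7
    log_noise_sd: float = 0.2           # sd on the log10 scale
    schedule: list[ScheduleEntry] = field(default_factory=_default_schedule)
    seed: int = 0
    start: str = "2024-05-06"           # first midnight of the series

    def __post_init__(self) -> None:
        if not self.peak_env > self.indoor_level > self.detection_floor > 0:
            raise ValueError(
                "require peak_env > indoor_level > detection_floor > 0, got "
                f"{self.peak_env}, {self.indoor_level}, {self.detection_floor}")
        if 86400 % self.interval:
            raise ValueError(f"interval {self.interval} must divide 86400")
        if not self.dawn < self.dusk:
            raise ValueError(f"dusk {self.dusk} must come after dawn {self.dawn}")
        covered = sorted((e.start, e.end) for e in self.schedule)
        pos = 0.0
        for s, e in covered:
            if s != pos:
                raise ValueError(
                    f"schedule must cover the full day contiguously; gap at {pos} s")
            pos = e
        if pos != 86400.0:
            raise ValueError(f"schedule ends at {pos} s, expected 86400")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "schedule" in raw:
            raw["schedule"] = [ScheduleEntry(**e) for e in raw["schedule"]]
        return cls(**raw)

    def timestamps(self) -> pd.DatetimeIndex:
        n = int(self.days * 86400 / self.interval)
        return pd.date_range(self.start, periods=n,
                             freq=pd.Timedelta(seconds=self.interval))


def _quantize(lux: np.ndarray, floor: float) -> np.ndarray:
    """Detection-floor quantization: sub-threshold light reads exactly 0."""
    out = lux.copy()
    out[out < floor] = 0.0
    return out


def _daylight(tod: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Noise-free daylight potential: powered half-sine between dawn and dusk."""
    frac = (tod - cfg.dawn) / (cfg.dusk - cfg.dawn)
    curve = np.zeros_like(tod)
    inside = (frac > 0) & (frac < 1)
    curve[inside] = cfg.peak_env * np.sin(np.pi * frac[inside]) ** 1.5
    return curve


def simulate_environment(config: SimConfig) -> LightTimeSeries:
    """Rooftop ambient melanopic EDI series: diurnal daylight plus noise.

    Exactly 0 lux outside [dawn, dusk]; inside, the powered half-sine
    with multiplicative lognormal noise (``10**N(0, log_noise_sd)``),
    quantized to 0 below the detection floor.  Deterministic under the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    ts = config.timestamps()
    tod = (ts.hour * 3600 + ts.minute * 60 + ts.second).to_numpy(float)
    curve = _daylight(tod, config)
    noise = 10.0 ** rng.normal(0.0, config.log_noise_sd, size=len(ts))
    lux = _quantize(curve * noise, config.detection_floor)
    return LightTimeSeries(ts, lux, "environment", config.interval)


def simulate_participant(config: SimConfig,
                         environment: LightTimeSeries) -> LightTimeSeries:
    """Wearable melanopic EDI series driven by the behavioral schedule.

    Sleep and dark states record 0 lux; indoor states fluctuate around
    ``indoor_level``; outdoor states see ``outdoor_attenuation`` times
    the concurrent environment value.  All states pass through the
    detection-floor quantization, so nighttime is entirely zero and dark
    indoor episodes add daytime zeros.
    """
    if len(environment) != len(config.timestamps()):
        raise ValueError("environment series does not match the config grid")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ts = environment.timestamps
    tod = (ts.hour * 3600 + ts.minute * 60 + ts.second).to_numpy(float)
    state = np.empty(len(ts), dtype=object)
    for entry in config.schedule:
        m = (tod >= entry.start) & (tod < entry.end)
        state[m] = entry.state
    noise = 10.0 ** rng.normal(0.0, config.log_noise_sd, size=len(ts))
    lux = np.zeros(len(ts))
    lux[state == "indoor"] = config.indoor_level
    outdoor = state == "outdoor"
    lux[outdoor] = config.outdoor_attenuation * environment.medi[outdoor]
    lux *= noise
    lux[(state == "sleep") | (state == "dark")] = 0.0
    lux = _quantize(lux, config.detection_floor)
    return LightTimeSeries(ts, lux, "participant", config.interval)


def simulate_week(config: SimConfig) -> LightTimeSeries:
    """Combined participant + environment series on a shared grid."""
    env = simulate_environment(config)
    part = simulate_participant(config, env)
    ts = env.timestamps.append(part.timestamps)
    return LightTimeSeries(
        ts,
        np.concatenate([env.medi, part.medi]),
        np.concatenate([env.source, part.source]),
        config.interval,
    )


def diurnal_mu(tod, base: float = 5.0, peak: float = 500.0,
               dawn: float = 6 * 3600.0, dusk: float = 20 * 3600.0) -> np.ndarray:
    """A smooth strictly positive diurnal mean curve on the log scale.

    Interpolates from ``base`` lux at night to ``peak`` lux at midday
    with a raised-cosine profile in log10 units — a convenient truth for
    parameter-recovery experiments.
    """
    tod = np.asarray(tod, dtype=float)
    frac = np.clip((tod - dawn) / (dusk - dawn), 0.0, 1.0)
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * frac))   # 0 at night, 1 midday
    return 10.0 ** (np.log10(base) + bump * (np.log10(peak) - np.log10(base)))


def simulate_tweedie_series(mu_curve, p: float, phi: float,
                            config: SimConfig) -> LightTimeSeries:
    """Independent compound Poisson–Gamma draws around a smooth mean curve.

    ``mu_curve`` maps seconds-from-midnight to a strictly positive mean;
    each sample is drawn from Tweedie(mu(t), p, phi), so the series has
    exact zeros with probability ``exp(-lambda(t))``.  Used for
    parameter-recovery studies of the Tweedie modeling machinery.
    """
    if not 1.0 < p < 2.0:
        raise ValueError(f"power must lie in (1, 2), got {p}")
    ts = config.timestamps()
    tod = (ts.hour * 3600 + ts.minute * 60 + ts.second).to_numpy(float)
    mu = np.asarray(mu_curve(tod), dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu_curve must be strictly positive everywhere")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    alpha = (2.0 - p) / (p - 1.0)
    gamma_scale = phi * (p - 1.0) * mu ** (p - 1.0)
    counts = rng.poisson(lam)
    lux = np.zeros(len(ts))
    pos = counts > 0
    lux[pos] = rng.gamma(shape=counts[pos] * alpha, scale=gamma_scale[pos])
    return LightTimeSeries(ts, lux, "participant", config.interval)
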