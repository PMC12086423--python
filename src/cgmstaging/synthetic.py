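"""Synthetic cohort generator.

Emulates the data structure of a CGM study in presymptomatic type 1 diabetes:
three groups (islet-autoantibody-negative controls, stage 1, stage 2), ~10-day
blinded sensor wears at 5-minute cadence, an OGTT panel and HbA1c acquired at
sensor placement, and ~1 year of progression follow-up.

The glucose model is deliberately minimal:

    reading(t) = clip( baseline
                       + circadian(t)                  # single sinusoid
                       + sum of meal excursions(t)     # gamma-shaped pulses
                       + AR(1) noise(t)                # slow biological wander
                       + session offset                # one draw per wear
                       + measurement noise(t),         # white
                       40, 400 )

The per-session *additive* offset is the central sensor-error feature: it
shifts the trace mean, the nocturnal mean and every time-above-range metric,
but leaves the within-trace SD untouched — the signature the downstream
correlation and repeatability analyses look for.  Group differences enter
through the baseline and through a per-participant excursion scale that
multiplies meal amplitudes; the same latent scale stochastically raises the
120-minute OGTT glucose, HbA1c (linear in expected mean glucose) and the
progression hazard.

Default parameter values were calibrated once against the published group
medians for this study design (control mean glucose ~115 mg/dL, SD ~16,
TA140 ~7 %, nocturnal mean ~106; graded increases for stage 1 and stage 2);
see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .data import GlucoseTrace, ParticipantRecord, SENSOR_CEIL, SENSOR_FLOOR

GROUPS = ("control", "stage1", "stage2")

#: gamma-pulse mean lift per meal = amplitude * e * peak_minutes / 1440 (per day)
_PULSE_INTEGRAL = math.e  # integral of (u)e^(1-u) du over [0, inf) times peak time


@dataclass(frozen=True)
class TrueGlycemicState:
    """Latent per-participant glycemic state linking CGM, OGTT and HbA1c."""

    baseline: float            # mg/dL, person-specific fasting-like level
    excursion_scale: float     # dimensionless multiplier on meal amplitudes
    group: str

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.excursion_scale < 0:
            raise ValueError("excursion_scale must be non-negative")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the generator.  Identical config + seed => identical cohort."""

    n_control: int = 33
    n_stage1: int = 46
    n_stage2: int = 18
    baseline_mean_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"control": 109.0, "stage1": 110.5, "stage2": 122.5}
    )
    baseline_sd: float = 6.0               # between-participant, mg/dL
    excursion_sigma: float = 0.2           # lognormal sigma of per-person scale
    baseline_excursion_corr: float = 0.5   # basal level vs excursion size coupling
    ar_level_slope: float = 0.45           # AR stationary SD gain per mg/dL of baseline
    circadian_amplitude: float = 3.2       # mg/dL
    circadian_peak_hour: float = 18.0
    meal_rate: float = 3.2                 # meals/day in the 06:00-22:00 window
    meal_amplitude_by_group: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "control": (25.0, 2.0),
            "stage1": (33.0, 2.0),
            "stage2": (52.0, 2.0),
        }
    )                                      # (mean peak mg/dL, gamma shape)
    meal_peak_minutes: float = 40.0
    meal_window: tuple[float, float] = (6.0, 22.0)   # clock hours
    ar_coefficient: float = 0.93           # per 5-min step
    ar_noise_sd: float = 2.94              # innovation SD => stationary SD ~8
    sensor_offset_sd: float = 8.0          # between-session additive, mg/dL
    sensor_noise_sd: float = 2.0           # within-session white, mg/dL
    wear_days: float = 10.0
    sample_interval: float = 5.0           # minutes
    hazard_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.0, "stage1": 0.07, "stage2": 0.60}
    )                                      # events/year at excursion_scale = 1
    risk_exponent: float = 2.0             # hazard ∝ excursion_scale ** exponent
    censor_time: float = 1.5               # years (maximum follow-up)
    g120_excursion_slope: float = 30.0     # mg/dL per unit excursion scale
    hba1c_intercept: float = 2.0           # %
    hba1c_slope: float = 0.028             # % per mg/dL of expected mean glucose
    hba1c_sd: float = 0.15
    ogtt_by_group: Mapping[str, tuple[float, float, float, float, float, float]] = field(
        default_factory=lambda: {
            #          fasting mean/sd, 30-90 min mean/sd, 120-min mean/sd
            "control": (88.0, 6.0, 125.0, 15.0, 100.0, 12.0),
            "stage1": (96.0, 6.0, 150.0, 18.0, 112.0, 11.0),
            "stage2": (104.0, 7.0, 175.0, 20.0, 150.0, 15.0),
        }
    )
    n_repeat_sessions: int = 0             # aab-positive participants worn twice
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_stage1, self.n_stage2) < 0:
            raise ValueError("group counts must be non-negative")
        for name in ("baseline_sd", "ar_noise_sd", "sensor_offset_sd",
                     "sensor_noise_sd", "hba1c_sd", "excursion_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 <= self.baseline_excursion_corr <= 1.0:
            raise ValueError("baseline_excursion_corr must be in [-1, 1]")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_trace(
    state: TrueGlycemicState,
    config: CohortConfig,
    duration_hours: float,
    seed,
    *,
    participant_id: str = "P0",
    session_id: str = "1",
    lot_id: str = "A",
    start: pd.Timestamp | str = "2023-01-02 10:00:00",
    offset: float | None = None,
) -> GlucoseTrace:
    """Simulate one sensor wear session for ``state``.

    ``offset`` forces the per-session additive sensor offset to a fixed value;
    with the same seed, every other random draw is unchanged, so the forced
    trace differs from the free one by exactly the offset difference at every
    un-clipped sample.
    """
    if duration_hours <= 0:
        raise ValueError("duration must be positive")
    interval = config.sample_interval
    n_float = duration_hours * 60.0 / interval
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9:
        raise ValueError("sample interval must divide the duration evenly")

    rng = _as_rng(seed)
    start = pd.Timestamp(start)
    times = start + pd.to_timedelta(np.arange(n) * interval, unit="m")
    minutes = np.arange(n) * interval  # since trace start
    clock_hours = (start.hour + start.minute / 60.0 + minutes / 60.0) % 24.0

    circ = config.circadian_amplitude * np.cos(
        2.0 * np.pi * (clock_hours - config.circadian_peak_hour) / 24.0
    )

    # gamma-shaped meal pulses at Poisson times in the daytime window
    amp_mean, amp_shape = config.meal_amplitude_by_group[state.group]
    amp_mean = amp_mean * state.excursion_scale
    n_days = duration_hours / 24.0
    k_meals = rng.poisson(config.meal_rate * n_days)
    day_idx = rng.integers(0, max(int(np.ceil(n_days)), 1), size=k_meals)
    lo, hi = config.meal_window
    meal_clock = rng.uniform(lo, hi, size=k_meals)
    # meal wall-clock minute relative to trace start
    start_clock_min = start.hour * 60.0 + start.minute
    meal_min = day_idx * 1440.0 + meal_clock * 60.0 - start_clock_min
    if amp_mean > 0 and amp_shape > 0:
        amps = rng.gamma(amp_shape, amp_mean / amp_shape, size=k_meals)
    else:
        amps = np.zeros(k_meals)
    meals = np.zeros(n)
    tp = config.meal_peak_minutes
    horizon = 8.0 * tp  # pulse support truncated where it is numerically nil
    for m, a in zip(meal_min, amps):
        if m >= minutes[-1] or m + horizon <= 0:
            continue
        i0 = int(np.searchsorted(minutes, m))
        i1 = int(np.searchsorted(minutes, m + horizon))
        u = (minutes[i0:i1] - m) / tp
        meals[i0:i1] += a * u * np.exp(1.0 - u)

    # AR(1) biological wander, stationary start; its amplitude grows with the
    # person's basal level (variability scales with level), floored at 30 %
    phi = config.ar_coefficient
    damp = math.sqrt(1.0 - phi * phi)
    stat_base = config.ar_noise_sd / damp if phi > 0 else config.ar_noise_sd
    level_delta = state.baseline - config.baseline_mean_by_group[state.group]
    stat_sd = max(stat_base + config.ar_level_slope * level_delta, 0.3 * stat_base)
    innov_sd = stat_sd * damp if phi > 0 else stat_sd
    x0 = rng.normal(0.0, stat_sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    ar, _ = lfilter([1.0], [1.0, -phi], eps, zi=[phi * x0])

    noise = rng.normal(0.0, config.sensor_noise_sd, size=n)
    if offset is None:
        offset = rng.normal(0.0, config.sensor_offset_sd)

    glucose = np.clip(
        state.baseline + circ + meals + ar + noise + offset, SENSOR_FLOOR, SENSOR_CEIL
    )
    return GlucoseTrace(
        participant_id=participant_id,
        session_id=session_id,
        lot_id=lot_id,
        times=pd.DatetimeIndex(times),
        glucose=glucose,
    )


def expected_mean_glucose(state: TrueGlycemicState, config: CohortConfig) -> float:
    """Long-run expected sensor-free mean glucose for a latent state."""
    amp_mean, _ = config.meal_amplitude_by_group[state.group]
    meal_lift = (
        config.meal_rate
        * amp_mean
        * state.excursion_scale
        * _PULSE_INTEGRAL
        * config.meal_peak_minutes
        / 1440.0
    )
    return state.baseline + meal_lift


def generate_ogtt_hba1c(
    state: TrueGlycemicState, config: CohortConfig, seed
) -> tuple[tuple[float, float, float, float, float], float]:
    """Draw an OGTT panel (0/30/60/90/120 min, mg/dL) and HbA1c (%).

    The 120-minute value and HbA1c are stochastically increasing in the
    latent excursion scale, so CGM excursions, OGTT dysglycemia and HbA1c
    are positively linked as the staging analysis assumes.
    """
    rng = _as_rng(seed)
    f_mean, f_sd, mid_mean, mid_sd, g120_mean, g120_sd = config.ogtt_by_group[state.group]
    g0 = rng.normal(f_mean, f_sd)
    g30, g60, g90 = rng.normal(mid_mean, mid_sd, size=3)
    g120 = rng.normal(
        g120_mean + config.g120_excursion_slope * (state.excursion_scale - 1.0), g120_sd
    )
    hba1c = rng.normal(
        config.hba1c_intercept + config.hba1c_slope * expected_mean_glucose(state, config),
        config.hba1c_sd,
    )
    panel = tuple(float(max(v, 40.0)) for v in (g0, g30, g60, g90, g120))
    return panel, float(np.clip(hba1c, 3.0, 20.0))


def generate_progression(
    hazard: float, censor_time: float, seed
) -> tuple[float, bool]:
    """Exponential progression time, censored at ``censor_time`` (years)."""
    if hazard < 0:
        raise ValueError("hazard must be non-negative")
    if censor_time <= 0:
        raise ValueError("censor_time must be positive")
    rng = _as_rng(seed)
    t = rng.exponential(1.0 / hazard) if hazard > 0 else math.inf
    if t <= censor_time:
        return float(t), True
    return float(censor_time), False


@dataclass
class Cohort:
    participants: list[ParticipantRecord]
    traces: list[GlucoseTrace]
    states: dict[str, TrueGlycemicState]
    config: CohortConfig


_SEX_P_MALE = {"control": 0.333, "stage1": 0.435, "stage2": 0.50}
_AGE_MEAN = {"control": 11.0, "stage1": 9.0, "stage2": 9.5}
_LOTS = ("A", "B", "C", "D")


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort: participants, wears, outcomes.

    Participants are drawn group by group (controls first).  The first
    ``n_repeat_sessions`` autoantibody-positive participants receive a second
    wear ~6 months later with the same latent state but a fresh sensor
    offset, mirroring a paired-measurement sub-study.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    participants: list[ParticipantRecord] = []
    traces: list[GlucoseTrace] = []
    states: dict[str, TrueGlycemicState] = {}
    duration_hours = config.wear_days * 24.0

    counts = {"control": config.n_control, "stage1": config.n_stage1, "stage2": config.n_stage2}
    # spread repeat wears across the two autoantibody-positive groups
    n_pos = counts["stage1"] + counts["stage2"]
    quota = {"control": 0}
    quota["stage1"] = (
        round(config.n_repeat_sessions * counts["stage1"] / n_pos) if n_pos else 0
    )
    quota["stage2"] = config.n_repeat_sessions - quota["stage1"]
    idx = 0
    for group in GROUPS:
        repeats_left = min(quota[group], counts[group])
        for _ in range(counts[group]):
            idx += 1
            pid = f"P{idx:04d}"
            # correlated basal level and excursion scale: people who run higher
            # also tend to excurse more (keeps CV roughly independent of level)
            z1, z2 = rng.standard_normal(2)
            rho = config.baseline_excursion_corr
            baseline = config.baseline_mean_by_group[group] + config.baseline_sd * z1
            scale = float(
                np.exp(config.excursion_sigma * (rho * z1 + math.sqrt(1 - rho * rho) * z2))
            )
            state = TrueGlycemicState(baseline=max(baseline, 50.0),
                                      excursion_scale=scale, group=group)
            states[pid] = state

            age = float(np.clip(rng.normal(_AGE_MEAN[group], 2.5), 3.0, 17.0))
            sex = "male" if rng.random() < _SEX_P_MALE[group] else "female"
            if group == "control":
                aab = int(rng.random() < 0.10)
            else:
                aab = 2 + int(rng.poisson(1.2))

            start_day = int(rng.integers(0, 365))
            start_min = int(rng.integers(0, 120)) * 5  # 10:00-20:00 grid
            start = pd.Timestamp("2023-01-02") + pd.Timedelta(days=start_day, minutes=600 + start_min)
            lot = _LOTS[int(rng.integers(0, len(_LOTS)))]
            traces.append(
                generate_trace(
                    state, config, duration_hours, rng,
                    participant_id=pid, session_id="1", lot_id=lot, start=start,
                )
            )
            if group != "control" and repeats_left > 0:
                repeats_left -= 1
                lot2 = _LOTS[int(rng.integers(0, len(_LOTS)))]
                traces.append(
                    generate_trace(
                        state, config, duration_hours, rng,
                        participant_id=pid, session_id="2", lot_id=lot2,
                        start=start + pd.Timedelta(days=182),
                    )
                )

            ogtt, hba1c = generate_ogtt_hba1c(state, config, rng)
            followup = float(rng.uniform(min(1.0, config.censor_time), config.censor_time))
            hazard = config.hazard_by_group[group] * scale ** config.risk_exponent
            time, event = generate_progression(hazard, followup, rng)
            participants.append(
                ParticipantRecord(
                    participant_id=pid,
                    age=round(age, 1),
                    sex=sex,
                    aab_count=aab,
                    ogtt=ogtt,
                    hba1c=round(hba1c, 2),
                    followup_years=followup,
                    progressed_stage3=event,
                    progression_time=time,
                )
            )
    return Cohort(participants=participants, traces=traces, states=states, config=config)
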