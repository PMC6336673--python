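"""Lifestyle-disturbance protocol and closed-loop week simulation.

A simulated week couples the virtual patient ODE (:mod:`apadapt.metabolism`)
with the lower-layer dosing algorithms (:mod:`apadapt.control`) under the
study's disturbance protocol: three daily meals with normally distributed
sizes in fixed windows, random meal skipping, inter-day insulin-sensitivity
noise, randomly occurring multi-day sickness, and autocorrelated CGM sensor
noise redrawn each day.  All randomness flows through a single numpy
``Generator`` in a fixed draw order, so a (patient, parameters, config, seed)
tuple reproduces a week bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import metabolism
from .control import (
    BasalProfile,
    CarbRatioProfile,
    ControllerParams,
    CorrectionConfig,
    IOBTracker,
    feedback_dose,
    meal_bolus,
)
from .metabolism import MetabolicState, VirtualPatient, steady_fasting_state, step_metabolism
from .timeutil import MINUTES_PER_DAY, STEP_MIN, STEPS_PER_DAY

CGM_MIN, CGM_MAX = 40.0, 400.0
LOW_GLUCOSE_THRESHOLD = 70.0
LOW_GLUCOSE_MIN_DURATION = 15.0  # minutes

DEFAULT_MEAL_MEANS = (50.0, 75.0, 75.0)
DEFAULT_MEAL_SDS = (3.0, 4.0, 4.0)
DEFAULT_MEAL_WINDOWS = ((420, 540), (660, 780), (1080, 1200))  # 07-09, 11-13, 18-20


@dataclass(frozen=True)
class ScenarioConfig:
    """Study protocol: disturbances, initialization scenario and duration."""

    scenario_id: str = "custom"
    br_init_multiplier: float | str = 1.0  # scalar or "uniform" (per segment)
    cr_init_multiplier: float | str = 1.0
    meal_means: tuple[float, ...] = DEFAULT_MEAL_MEANS
    meal_sds: tuple[float, ...] = DEFAULT_MEAL_SDS
    meal_windows: tuple[tuple[int, int], ...] = DEFAULT_MEAL_WINDOWS
    skip_probability: float = 0.1
    sickness_daily_probability: float = 0.05
    sickness_max_days: int = 5
    sickness_literal: bool = False  # True: "decrease by 100%" zeroes sensitivity
    interday_noise_fraction: float = 0.05
    cgm_noise_sd: float = 7.0
    cgm_noise_rho: float = 0.7
    weeks: int = 24
    days_per_iteration: int = 7
    seed: int = 0
    feedback_enabled: bool = True

    def __post_init__(self):
        for p in (self.skip_probability, self.sickness_daily_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.weeks < 1:
            raise ValueError("at least one week required")
        if self.days_per_iteration < 1:
            raise ValueError("days_per_iteration must be positive")

    @classmethod
    def preset(cls, scenario_id: str, **overrides) -> "ScenarioConfig":
        """Scenario presets: I = CRx2/BRx0.5, II = CRx2/BRx2, III = random
        per-segment multipliers in [0.5, 1.5]."""
        table = {
            "I": dict(br_init_multiplier=0.5, cr_init_multiplier=2.0),
            "II": dict(br_init_multiplier=2.0, cr_init_multiplier=2.0),
            "III": dict(br_init_multiplier="uniform", cr_init_multiplier="uniform"),
        }
        if scenario_id not in table:
            raise ValueError(f"unknown scenario {scenario_id!r}")
        kw = dict(scenario_id=scenario_id, **table[scenario_id])
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class SicknessState:
    days_left: int = 0
    factor: float = 1.0

    @property
    def active(self) -> bool:
        return self.days_left > 0


@dataclass
class DayDisturbances:
    meals: list[tuple[int, float]]      # (time-of-day min on 5-min grid, grams)
    sickness_flag: bool
    sick_factor: float                  # multiplier on sensitivity & dawn
    sensitivity_offset: float           # inter-day fraction, applied as (1+offset)
    sickness: SicknessState             # carry to the next day


def sample_day_disturbances(
    config: ScenarioConfig,
    day_index: int,
    rng: np.random.Generator,
    sickness: SicknessState | None = None,
) -> DayDisturbances:
    """Draw one day's meals, sickness state and inter-day sensitivity noise.

    Sickness persists from the passed-in state; a new illness episode starts
    with the configured daily probability and lasts a uniform 1..max days,
    scaling insulin sensitivity and the dawn parameter by 1.5 or 0.5 (0.0 in
    literal mode) with equal probability throughout the episode.
    """
    sickness = sickness or SicknessState()
    meals: list[tuple[int, float]] = []
    for (w0, w1), mean, sd in zip(config.meal_windows, config.meal_means, config.meal_sds):
        skipped = rng.random() < config.skip_probability
        t = int(rng.uniform(w0, w1) // STEP_MIN) * STEP_MIN
        grams = max(5.0, rng.normal(mean, sd))
        if not skipped:
            meals.append((t, grams))

    if sickness.active:
        sickness = replace(sickness, days_left=sickness.days_left - 1)
        if not sickness.active:
            sickness = SicknessState()
    if not sickness.active and rng.random() < config.sickness_daily_probability:
        duration = int(rng.integers(1, config.sickness_max_days + 1))
        low = 0.0 if config.sickness_literal else 0.5
        factor = 1.5 if rng.random() < 0.5 else low
        sickness = SicknessState(days_left=duration, factor=factor)

    offset = rng.uniform(-config.interday_noise_fraction, config.interday_noise_fraction)
    return DayDisturbances(
        meals=meals,
        sickness_flag=sickness.active,
        sick_factor=sickness.factor if sickness.active else 1.0,
        sensitivity_offset=offset,
        sickness=sickness,
    )


def sample_cgm_noise_day(
    rng: np.random.Generator,
    n: int = STEPS_PER_DAY,
    sd: float = 7.0,
    rho: float = 0.7,
) -> np.ndarray:
    """One day of AR(1) CGM sensor noise with stationary sd ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    z = rng.standard_normal(n)
    e = np.empty(n)
    e[0] = sd * z[0]
    scale = sd * math.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + scale * z[i]
    return e


def cgm_read(true_glucose: float, noise: float = 0.0) -> float:
    """Sensor reading: true glucose plus noise, clipped to [40, 400] mg/dl."""
    if true_glucose <= 0:
        raise ValueError("true glucose must be positive")
    return min(CGM_MAX, max(CGM_MIN, true_glucose + noise))


def detect_low_glucose_events(
    cgm: Sequence[float],
    threshold: float = LOW_GLUCOSE_THRESHOLD,
    min_duration: float = LOW_GLUCOSE_MIN_DURATION,
) -> list[tuple[float, float]]:
    """(start_min, duration_min) runs of CGM below 70 mg/dl lasting >= 15 min."""
    events = []
    run_start = None
    for i, v in enumerate(cgm):
        if v < threshold:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            dur = (i - run_start) * STEP_MIN
            if dur >= min_duration:
                events.append((run_start * STEP_MIN, float(dur)))
            run_start = None
    if run_start is not None:
        dur = (len(cgm) - run_start) * STEP_MIN
        if dur >= min_duration:
            events.append((run_start * STEP_MIN, float(dur)))
    return events


@dataclass
class MealRecord:
    time: int       # minutes from the day's midnight
    grams: float
    bolus: float


@dataclass
class DayLog:
    """One simulated day on the 5-min grid (288 samples)."""

    cgm: np.ndarray
    true_glucose: np.ndarray
    dose_basal: np.ndarray      # scheduled basal component, U per step
    dose_feedback: np.ndarray   # controller deviation from basal, U per step
    dose_bolus: np.ndarray      # meal/correction boluses, U per step
    meal_g: np.ndarray          # consumed grams per step
    meals: list[MealRecord]
    sickness_flag: bool
    sensitivity_offset: float
    low_glucose_events: list[tuple[float, float]]

    @property
    def doses(self) -> np.ndarray:
        """Total delivered insulin per step (basal + feedback + bolus)."""
        return self.dose_basal + self.dose_feedback + self.dose_bolus


@dataclass
class ParamsUsed:
    basal: BasalProfile
    carb_ratio: CarbRatioProfile
    controller: ControllerParams


@dataclass
class WeekCarry:
    """State carried between consecutive simulated weeks."""

    state: MetabolicState
    sickness: SicknessState = field(default_factory=SicknessState)


@dataclass
class WeekLog:
    iteration_index: int
    patient_id: int
    days: list[DayLog]
    parameters_used: ParamsUsed
    carry_out: WeekCarry | None = None

    def all_cgm(self) -> np.ndarray:
        return np.concatenate([d.cgm for d in self.days])

    def all_true_glucose(self) -> np.ndarray:
        return np.concatenate([d.true_glucose for d in self.days])

    def low_glucose_events_abs(self) -> list[tuple[float, float]]:
        """Events as (absolute start minute within the week, duration)."""
        out = []
        for di, day in enumerate(self.days):
            for start, dur in day.low_glucose_events:
                out.append((di * MINUTES_PER_DAY + start, dur))
        return out

    def total_insulin(self) -> float:
        return float(sum(d.doses.sum() for d in self.days))


def _simulate_day(
    patient: VirtualPatient,
    params: ParamsUsed,
    state: MetabolicState,
    dist: DayDisturbances,
    noise: np.ndarray,
    iob: IOBTracker,
    cgm_history: list[float],
    day_offset_min: float,
    feedback_enabled: bool,
) -> tuple[DayLog, MetabolicState]:
    """Closed-loop rollout of one day; mutates ``iob`` and ``cgm_history``."""
    n = STEPS_PER_DAY
    cgm_a = np.empty(n)
    true_a = np.empty(n)
    basal_a = np.empty(n)
    fb_a = np.empty(n)
    bolus_a = np.empty(n)
    meal_a = np.zeros(n)
    meal_at = {t // STEP_MIN: g for t, g in dist.meals}
    meals_out: list[MealRecord] = []

    sens_scale = (1.0 + dist.sensitivity_offset) * dist.sick_factor
    dawn_scale = (1.0 + dist.sensitivity_offset) * dist.sick_factor
    corr = CorrectionConfig(isf=params.controller.isf_est)
    basal_profile = params.basal
    cr_profile = params.carb_ratio
    cparams = params.controller

    for step in range(n):
        t = step * STEP_MIN
        t_abs = day_offset_min + t
        reading = cgm_read(state.g, float(noise[step]))
        cgm_history.append(reading)

        basal_now = basal_profile.value_at(t)
        basal_step = basal_now / 12.0
        if feedback_enabled and len(cgm_history) >= 7:
            cmd = feedback_dose(cgm_history, cparams, basal_now, iob.value(t_abs))
        else:
            cmd = basal_step

        grams = meal_at.get(step, 0.0)
        bolus = 0.0
        if grams > 0.0:
            bolus = meal_bolus(grams, cr_profile, t, reading, corr, iob=iob.value(t_abs))
            meals_out.append(MealRecord(time=t, grams=grams, bolus=bolus))
            meal_a[step] = grams

        iob.add(t_abs, max(0.0, cmd - basal_step) + bolus)
        state = step_metabolism(
            patient, state, cmd + bolus, grams, float(STEP_MIN),
            t_of_day=t, sens_scale=sens_scale, dawn_scale=dawn_scale,
        )

        cgm_a[step] = reading
        true_a[step] = state.g
        basal_a[step] = basal_step
        fb_a[step] = cmd - basal_step
        bolus_a[step] = bolus

    day = DayLog(
        cgm=cgm_a,
        true_glucose=true_a,
        dose_basal=basal_a,
        dose_feedback=fb_a,
        dose_bolus=bolus_a,
        meal_g=meal_a,
        meals=meals_out,
        sickness_flag=dist.sickness_flag,
        sensitivity_offset=dist.sensitivity_offset,
        low_glucose_events=detect_low_glucose_events(cgm_a),
    )
    return day, state


def run_week(
    patient: VirtualPatient,
    params: ParamsUsed,
    config: ScenarioConfig,
    week_index: int,
    rng: np.random.Generator,
    carry: WeekCarry | None = None,
) -> WeekLog:
    """Simulate one closed-loop iteration (7 days) under fixed parameters.

    The controller sees only CGM readings, its own dose history and the
    announced meals; the patient ODE sees the delivered insulin and carbs.
    The returned :class:`WeekLog` carries the end-of-week metabolic and
    sickness state in ``carry_out`` for seamless multi-week studies.
    """
    if carry is None:
        carry = WeekCarry(state=steady_fasting_state(patient, 0.0))
    state = carry.state.copy()
    sickness = carry.sickness

    iob = IOBTracker()
    cgm_history: list[float] = []
    days: list[DayLog] = []
    for d in range(config.days_per_iteration):
        day_index = (week_index - 1) * config.days_per_iteration + d
        dist = sample_day_disturbances(config, day_index, rng, sickness)
        sickness = dist.sickness
        noise = sample_cgm_noise_day(
            rng, STEPS_PER_DAY, config.cgm_noise_sd, config.cgm_noise_rho
        )
        day, state = _simulate_day(
            patient, params, state, dist, noise, iob, cgm_history,
            day_offset_min=d * MINUTES_PER_DAY,
            feedback_enabled=config.feedback_enabled,
        )
        days.append(day)

    return WeekLog(
        iteration_index=week_index,
        patient_id=patient.id,
        days=days,
        parameters_used=params,
        carry_out=WeekCarry(state=state, sickness=sickness),
    )


def week_rng(config_seed: int, patient_id: int, week_index: int) -> np.random.Generator:
    """Deterministic per-(patient, week) random stream."""
    return np.random.default_rng(
        np.random.SeedSequence([config_seed, patient_id, week_index])
    )
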