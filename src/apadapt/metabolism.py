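"""Surrogate glucose–insulin–meal physiology and virtual patients.

The simulator stands in for a full-scale FDA-class metabolic simulator at desk
scale.  Each virtual patient is a minimal-model-class ODE with seven states:

* ``g``   plasma glucose (mg/dl),
* ``x``   insulin action (U/min; a low-pass filtered plasma appearance),
* ``q1, q2`` subcutaneous insulin depot (U, two absorption compartments),
* ``d1, d2`` gut carbohydrate (g, two absorption compartments).

Glucose dynamics::

    dg/dt = EGP(t) - sg*g - si(t)*x + k_carb*kc*d2

where ``EGP`` carries a dawn-phenomenon rise in the early morning and ``si``
carries the 24-h diurnal insulin-sensitivity rhythm.  The patient's "true"
basal-rate and carb-ratio profiles are defined by steady-state balance
against these same parameters, so parameter-recovery tests have an exact
ground truth:

* ``true_basal_need(t) = 60*(EGP(t) - sg*g_target)/si(t)`` holds fasting
  glucose at ``g_target``;
* ``true_carb_factor(t) = si(t)/k_carb`` makes a ``grams/CR`` bolus cancel a
  meal's integrated glucose appearance.

Clinical scales follow the usual 1800/500 rules on total daily insulin (TDI):
the bolus trough sensitivity is 1800/TDI mg/dl per U and the carb ratio is
500/TDI g/U, with at least ±30% inter-patient spread through TDI and weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .control import BR_PERIODS, CR_PERIODS, BasalProfile, CarbRatioProfile
from .timeutil import MINUTES_PER_DAY, STEP_MIN

# Fraction of a bolus's total integrated effect realized at the glucose
# trough for the compartment chain used here; converts the clinical trough
# sensitivity (1800 rule) into the ODE's integral sensitivity.
BOLUS_TROUGH_FRACTION = 0.68

# A carb bolus sized to cancel a meal's *integrated* glucose appearance
# overshoots in practice: insulin action lags gut absorption, so the exact
# integral match drives a late undershoot.  The clinically settled carb ratio
# is therefore more conservative than the integral match by this factor; it
# defines the patient's "true" carb factor.
CR_SAFETY_FACTOR = 1.25

G_FLOOR = 15.0  # numerical floor on plasma glucose, mg/dl

# Counter-regulatory (glucagon-like) response: extra endogenous glucose
# production per mg/dl below this threshold, activating during hypoglycemia.
COUNTERREG_THRESHOLD = 80.0
COUNTERREG_GAIN = 0.04  # (mg/dl/min) per mg/dl below threshold


class MetabolicBlowup(RuntimeError):
    """Raised when the metabolic state stops being finite."""


@dataclass(slots=True)
class MetabolicState:
    g: float
    x: float
    q1: float
    q2: float
    d1: float
    d2: float

    def copy(self) -> "MetabolicState":
        return MetabolicState(self.g, self.x, self.q1, self.q2, self.d1, self.d2)

    def is_finite(self) -> bool:
        return all(
            math.isfinite(v)
            for v in (self.g, self.x, self.q1, self.q2, self.d1, self.d2)
        )


def _dawn_ramp(t: float) -> float:
    """Dawn-phenomenon shape: 0 outside [04:00, 08:00), with 30-min ramps."""
    t = t % MINUTES_PER_DAY
    if t < 240 or t >= 480:
        return 0.0
    if t < 270:
        return (t - 240) / 30.0
    if t >= 450:
        return (480 - t) / 30.0
    return 1.0


@dataclass(frozen=True)
class VirtualPatient:
    """One synthetic adult with type 1 diabetes.

    ``insulin_sensitivity_base`` is the clinical correction factor (mg/dl drop
    at the trough of a 1-U bolus response, at diurnal multiplier 1); the ODE's
    integral sensitivity is ``si_rate_base = insulin_sensitivity_base /
    BOLUS_TROUGH_FRACTION``.
    """

    id: int
    weight: float                      # kg
    tdi: float                         # U/day, sets the clinical scales
    insulin_sensitivity_base: float    # mg/dl per U (trough)
    cr_base: float                     # g/U at diurnal multiplier 1
    g_target: float                    # fasting set point, mg/dl
    diurnal_amp: float                 # amplitude of the 24-h si rhythm
    diurnal_phase: float               # minutes
    dawn_amp: float                    # fractional EGP rise in early morning
    metabolic_constants: dict = field(default_factory=dict)

    # -- derived physiology ------------------------------------------------
    @property
    def si_rate_base(self) -> float:
        """Integral insulin sensitivity of the ODE, mg/dl per U delivered."""
        return self.insulin_sensitivity_base / BOLUS_TROUGH_FRACTION

    @property
    def k_carb(self) -> float:
        """Glucose impact of carbohydrate, mg/dl per g absorbed."""
        return self.si_rate_base / self.cr_base

    @property
    def basal_mean(self) -> float:
        """Basal need (U/hr) at diurnal multiplier 1, no dawn effect."""
        return float(self.metabolic_constants["ub_mean"])

    @property
    def egp0(self) -> float:
        """Baseline endogenous glucose production, mg/dl per min."""
        c = self.metabolic_constants
        return c["sg"] * self.g_target + self.si_rate_base * c["ub_mean"] / 60.0

    def diurnal_sensitivity_multiplier(self, t: float) -> float:
        m = 1.0 + self.diurnal_amp * math.sin(
            2.0 * math.pi * (t - self.diurnal_phase) / MINUTES_PER_DAY
        )
        return min(2.0, max(0.5, m))

    def egp(self, t: float, dawn_scale: float = 1.0) -> float:
        """Endogenous glucose production at clock time ``t``, mg/dl per min.

        The dawn rise in *production* is placed one mean action-lag after the
        canonical [04:00, 08:00) window so that the corresponding rise in the
        delivery-time basal *need* (which anticipates by that same lag) spans
        [04:00, 08:00) — making the 05:00-10:00 basal segment the largest, as
        expected for the dawn phenomenon under a clinician's schedule.
        """
        return self.egp0 * (
            1.0 + self.dawn_amp * dawn_scale * _dawn_ramp(t - self.action_lag_min)
        )

    def si_rate(self, t: float, sens_scale: float = 1.0) -> float:
        return self.si_rate_base * self.diurnal_sensitivity_multiplier(t) * sens_scale

    @property
    def action_lag_min(self) -> float:
        """Mean residence time of the delivery-to-action chain, minutes."""
        c = self.metabolic_constants
        return 2.0 / c["ka"] + 1.0 / c["p2"]

    def true_basal_need(self, t: float) -> float:
        """Basal rate (U/hr) holding fasting glucose near ``g_target`` when
        delivered at time ``t`` under nominal (no sickness, no inter-day
        noise) conditions.

        Because subcutaneous insulin acts with a lag, the need is the
        steady-state balance evaluated one mean action-lag ahead of the
        delivery time: insulin infused now serves the demand it will meet.
        """
        c = self.metabolic_constants
        ta = t + self.action_lag_min
        return 60.0 * (self.egp(ta) - c["sg"] * self.g_target) / self.si_rate(ta)

    def true_carb_factor(self, t: float) -> float:
        """Clinically settled carb ratio (g/U) at time ``t``: the integral
        match ``cr_base`` relaxed by :data:`CR_SAFETY_FACTOR` to absorb the
        insulin-after-carbs timing mismatch."""
        return CR_SAFETY_FACTOR * self.cr_base * self.diurnal_sensitivity_multiplier(t)

    # -- profile ground truth ---------------------------------------------
    def _segment_mean(self, fn, period: tuple[int, int]) -> float:
        s, e = period
        if e <= s:
            e += MINUTES_PER_DAY
        ts = np.arange(s, e, STEP_MIN)
        return float(np.mean([fn(t % MINUTES_PER_DAY) for t in ts]))

    def br_truth(self) -> BasalProfile:
        return BasalProfile(
            tuple(self._segment_mean(self.true_basal_need, p) for p in BR_PERIODS)
        )

    def cr_truth(self) -> CarbRatioProfile:
        return CarbRatioProfile(
            tuple(self._segment_mean(self.true_carb_factor, p) for p in CR_PERIODS)
        )


def steady_fasting_state(patient: VirtualPatient, t: float = 0.0) -> MetabolicState:
    """Fasting steady state at clock time ``t`` under the true basal need."""
    c = patient.metabolic_constants
    r = patient.true_basal_need(t) / 60.0  # U/min
    return MetabolicState(
        g=patient.g_target, x=r, q1=r / c["ka"], q2=r / c["ka"], d1=0.0, d2=0.0
    )


def step_metabolism(
    patient: VirtualPatient,
    state: MetabolicState,
    insulin_U: float,
    carbs_g: float,
    dt_min: float,
    t_of_day: float = 0.0,
    sens_scale: float = 1.0,
    dawn_scale: float = 1.0,
) -> MetabolicState:
    """Advance the metabolic ODE by ``dt_min`` minutes (1-min Euler substeps).

    ``insulin_U`` and ``carbs_g`` are injected into the subcutaneous and gut
    depots at the start of the step.  ``sens_scale``/``dawn_scale`` carry the
    inter-day and sickness multipliers on insulin sensitivity and the dawn
    parameter.  Raises :class:`MetabolicBlowup` on non-finite state.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    if insulin_U < 0 or carbs_g < 0:
        raise ValueError("insulin and carbs must be nonnegative")
    if not state.is_finite():
        raise MetabolicBlowup("non-finite metabolic state")

    c = patient.metabolic_constants
    ka, p2, kc, sg = c["ka"], c["p2"], c["kc"], c["sg"]
    si_base = patient.si_rate_base * sens_scale
    k_carb = patient.k_carb
    egp0 = patient.egp0
    dawn_amp = patient.dawn_amp * dawn_scale
    amp, phase = patient.diurnal_amp, patient.diurnal_phase

    g, x, q1, q2, d1, d2 = state.g, state.x, state.q1, state.q2, state.d1, state.d2
    q1 += insulin_U
    d1 += carbs_g

    n = max(1, round(dt_min))
    dt = dt_min / n
    t = t_of_day
    two_pi_over_day = 2.0 * math.pi / MINUTES_PER_DAY
    for _ in range(n):
        diurnal = 1.0 + amp * math.sin(two_pi_over_day * (t - phase))
        if diurnal < 0.5:
            diurnal = 0.5
        elif diurnal > 2.0:
            diurnal = 2.0
        si = si_base * diurnal
        egp = egp0 * (1.0 + dawn_amp * _dawn_ramp(t))
        if g < COUNTERREG_THRESHOLD:
            egp += COUNTERREG_GAIN * (COUNTERREG_THRESHOLD - g)
        dg = egp - sg * g - si * x + k_carb * kc * d2
        g += dg * dt
        if g < G_FLOOR:
            g = G_FLOOR
        dq1 = -ka * q1
        dq2 = ka * (q1 - q2)
        dx = p2 * (ka * q2 - x)
        dd1 = -kc * d1
        dd2 = kc * (d1 - d2)
        q1 += dq1 * dt
        q2 += dq2 * dt
        x += dx * dt
        d1 += dd1 * dt
        d2 += dd2 * dt
        t += dt

    out = MetabolicState(g, x, q1, q2, d1, d2)
    if not out.is_finite():
        raise MetabolicBlowup("metabolic integration diverged")
    return out


def generate_patient(pid: int, rng: np.random.Generator) -> VirtualPatient:
    weight = rng.uniform(55.0, 95.0)
    tdi = weight * rng.uniform(0.45, 0.75)
    basal_frac = rng.uniform(0.42, 0.55)
    ub_mean = basal_frac * tdi / 24.0
    isf = 1800.0 / tdi
    cr = 500.0 / tdi
    g_target = rng.uniform(105.0, 125.0)
    constants = {
        "sg": rng.uniform(0.0030, 0.0042),
        "ka": 1.0 / rng.uniform(30.0, 42.0),
        "p2": 1.0 / rng.uniform(15.0, 25.0),
        "kc": 1.0 / rng.uniform(34.0, 46.0),
        "ub_mean": ub_mean,
    }
    return VirtualPatient(
        id=pid,
        weight=weight,
        tdi=tdi,
        insulin_sensitivity_base=isf,
        cr_base=cr,
        g_target=g_target,
        diurnal_amp=rng.uniform(0.08, 0.22),
        diurnal_phase=rng.uniform(0.0, MINUTES_PER_DAY),
        dawn_amp=rng.uniform(0.15, 0.30),
        metabolic_constants=constants,
    )


def generate_cohort(n_patients: int, seed: int) -> list[VirtualPatient]:
    """Deterministically generate ``n_patients`` virtual adults.

    Each patient draws from an independent stream of a seed sequence spawned
    from ``seed``, so cohorts of different sizes share their leading patients.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be nonnegative")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_patients)
    return [
        generate_patient(pid, np.random.default_rng(s))
        for pid, s in enumerate(streams)
    ]
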