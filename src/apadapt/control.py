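"""Lower-layer real-time insulin dosing.

This module implements the three real-time dosing components of a hybrid
closed-loop system:

* a feedforward basal calculator reading a piecewise-constant daily basal-rate
  (BR) profile,
* a feedforward meal controller computing carbohydrate and correction boluses
  from a carbohydrate-ratio (CR) profile, and
* a simplified zone model-predictive feedback controller that tops up (or
  withholds) basal delivery based on recent CGM readings.

The feedback controller exposes exactly three tunable parameters that the
upper adaptation layer may touch: ``r_hat`` (penalty on insulin delivery above
basal), ``d_bar`` (upper bound of the glucose band in which a velocity brake
damps dosing while glucose is falling) and ``gamma_iob`` (responsiveness of
the insulin-on-board safety cap).  Their nominal values are configuration, not
physiology; the adaptation layer works with relative changes.

Design notes
------------
The zone MPC is deliberately minimal: glucose is predicted over a 45-min
horizon (9 five-minute steps) from the current CGM value and a damped
least-squares trend; one above-basal adjustment, held over the 5-step control
horizon (move blocking), is chosen by minimizing an asymmetric quadratic zone
cost plus ``r_hat`` times a delivery penalty.  The scalar minimizer has a
closed form, which makes every dosing contract (monotonicity in ``r_hat`` and
``gamma_iob``, basal delivery at rest in the zone, suspension below 70 mg/dl)
exact rather than numerical.  Insulin action accrues as the complement of a
4-h linear insulin-on-board decay, personalized through a 1800-rule correction
factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .timeutil import MINUTES_PER_DAY, STEP_MIN, in_interval, intervals_overlap

# Fixed, clinician-style segment boundaries (minutes from midnight).
BR_PERIODS: tuple[tuple[int, int], ...] = (
    (120, 300),    # [02:00, 05:00)
    (300, 600),    # [05:00, 10:00)
    (600, 960),    # [10:00, 16:00)
    (960, 1260),   # [16:00, 21:00)
    (1260, 120),   # [21:00, 02:00)  wraps midnight
)
CR_PERIODS: tuple[tuple[int, int], ...] = (
    (300, 600),    # [05:00, 10:00)  breakfast
    (600, 960),    # [10:00, 16:00)  lunch
    (960, 1260),   # [16:00, 21:00)  dinner
    (1260, 300),   # [21:00, 05:00)  overnight, not adapted
)
CR_ADAPTABLE: tuple[int, ...] = (0, 1, 2)

IOB_DECAY_MIN = 240.0  # 4-h linear decay of boluses above basal

# Zone-MPC tuning (internal; only r_hat/d_bar/gamma_iob are adaptable).
ZONE_LO = 80.0
ZONE_HI = 160.0
PRED_HORIZON = 9          # 45 min
CTRL_HORIZON = 5          # move-blocked
W_BELOW = 10.0            # asymmetric weight on below-zone excursions
W_ABOVE = 1.0
R_BASE = 7000.0           # delivery-penalty scale multiplied by r_hat
VEL_BRAKE = 0.05          # velocity-penalty gain per mg/dl below d_bar
TREND_DAMP = 0.90
SUSPEND_CGM = 70.0
IOB_CAP_REF = 110.0       # glucose pivot of the IOB cap
IOB_CAP_GAIN = 1.0        # scale of the IOB cap at nominal gamma_iob


def _segment_index(t: float, periods: Sequence[tuple[int, int]]) -> int:
    t = t % MINUTES_PER_DAY
    for i, (s, e) in enumerate(periods):
        if in_interval(t, s, e):
            return i
    raise ValueError(f"time {t} not covered by periods {periods}")  # pragma: no cover


@dataclass(frozen=True)
class BasalProfile:
    """Piecewise-constant daily basal-rate schedule, U/hr per segment."""

    values: tuple[float, ...]
    periods: tuple[tuple[int, int], ...] = BR_PERIODS

    def __post_init__(self):
        if len(self.values) != len(self.periods):
            raise ValueError("one value per period required")
        if any(v <= 0 for v in self.values):
            raise ValueError("basal rates must be positive")

    def segment_index(self, t: float) -> int:
        return _segment_index(t, self.periods)

    def value_at(self, t: float) -> float:
        return self.values[self.segment_index(t)]

    def scaled(self, factor) -> "BasalProfile":
        """Multiply segments by a scalar or per-segment factors."""
        if isinstance(factor, (int, float)):
            factor = [factor] * len(self.values)
        return replace(self, values=tuple(v * f for v, f in zip(self.values, factor)))


@dataclass(frozen=True)
class CarbRatioProfile:
    """Piecewise-constant daily carbohydrate-ratio schedule, g/U per segment.

    Only the meal-time segments listed in ``adaptable`` are touched by the
    adaptation layer; the overnight segment is held at its configured value.
    """

    values: tuple[float, ...]
    periods: tuple[tuple[int, int], ...] = CR_PERIODS
    adaptable: tuple[int, ...] = CR_ADAPTABLE

    def __post_init__(self):
        if len(self.values) != len(self.periods):
            raise ValueError("one value per period required")
        if any(v <= 0 for v in self.values):
            raise ValueError("carb ratios must be positive")

    def segment_index(self, t: float) -> int:
        return _segment_index(t, self.periods)

    def value_at(self, t: float) -> float:
        return self.values[self.segment_index(t)]

    def scaled(self, factor, adaptable_only: bool = True) -> "CarbRatioProfile":
        if isinstance(factor, (int, float)):
            factor = [factor] * len(self.values)
        vals = list(self.values)
        for i, f in enumerate(factor):
            if adaptable_only and i not in self.adaptable:
                continue
            vals[i] = vals[i] * f
        return replace(self, values=tuple(vals))


#: bound fractions (lower, upper) of nominal for each feedback parameter
BOUND_FRACTIONS: dict[str, tuple[float, float]] = {
    "r_hat": (0.50, 1.50),
    "d_bar": (0.89, 1.22),
    "gamma_iob": (0.70, 1.20),
}

#: sign of "more insulin" for each feedback parameter: lowering r_hat or
#: d_bar, or raising gamma_iob, makes the controller dose more aggressively
AGGRESSIVE_DIRECTION: dict[str, int] = {"r_hat": -1, "d_bar": -1, "gamma_iob": +1}

#: sign of d(mean glucose)/d(parameter); the negation of AGGRESSIVE_DIRECTION
OBJECTIVE_SIGN: dict[str, int] = {"r_hat": +1, "d_bar": +1, "gamma_iob": -1}

ADAPTABLE_PARAMS: tuple[str, ...] = ("r_hat", "d_bar", "gamma_iob")


@dataclass(frozen=True)
class ControllerParams:
    """Feedback-controller knobs plus the personalization gain.

    ``isf_est`` is the controller's correction factor (mg/dl per U), set once
    per patient from the 1800 rule on the estimated total daily insulin; it is
    part of the controller's internal model, not an adaptable parameter.
    """

    r_hat: float = 1.0
    d_bar: float = 140.0
    gamma_iob: float = 1.0
    nominal_r_hat: float = 1.0
    nominal_d_bar: float = 140.0
    nominal_gamma_iob: float = 1.0
    isf_est: float = 40.0

    def __post_init__(self):
        for name in ADAPTABLE_PARAMS:
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be positive")
            lo, hi = self.bounds(name)
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")

    def nominal(self, name: str) -> float:
        return getattr(self, f"nominal_{name}")

    def value(self, name: str) -> float:
        return getattr(self, name)

    def bounds(self, name: str) -> tuple[float, float]:
        lo_f, hi_f = BOUND_FRACTIONS[name]
        nom = self.nominal(name)
        return lo_f * nom, hi_f * nom

    def with_value(self, name: str, value: float) -> "ControllerParams":
        return replace(self, **{name: value})


def basal_rate_at(profile: BasalProfile, t: float) -> float:
    """Basal rate (U/hr) scheduled at clock time ``t`` (minutes)."""
    return profile.value_at(t)


@dataclass(frozen=True)
class CorrectionConfig:
    """Correction-bolus settings for the feedforward meal controller."""

    target: float = 150.0
    isf: float = 40.0
    enabled: bool = True


def meal_bolus(
    grams: float,
    profile: CarbRatioProfile,
    t: float,
    cgm: float,
    correction_config: CorrectionConfig | None = None,
    iob: float = 0.0,
) -> float:
    """Feedforward meal + correction bolus (U) for an announced meal.

    The carbohydrate part divides announced grams by the active CR segment;
    the correction part adds insulin only when the CGM reading exceeds the
    correction target, discounted by insulin already on board.
    """
    if grams < 0:
        raise ValueError("grams must be nonnegative")
    cc = correction_config or CorrectionConfig()
    bolus = grams / profile.value_at(t) if grams > 0 else 0.0
    if cc.enabled:
        bolus += max(0.0, (cgm - cc.target) / cc.isf - iob)
    return bolus


def iob_estimate(
    dose_history: Iterable[tuple[float, float]],
    t: float,
    basal_reference: float,
) -> float:
    """Insulin on board (U) at time ``t`` from per-step dose records.

    Doses are ``(time_min, units)`` pairs on the 5-min grid; only the portion
    of each dose above the reference basal (``basal_reference`` U/hr, i.e.
    ``basal_reference/12`` U per step) contributes, decaying linearly to zero
    over 4 h.  Additive in doses, zero for an empty history.
    """
    ref_step = basal_reference / (60.0 / STEP_MIN)
    iob = 0.0
    for ti, units in dose_history:
        lag = t - ti
        if 0 <= lag < IOB_DECAY_MIN:
            extra = units - ref_step
            if extra > 0:
                iob += extra * (1.0 - lag / IOB_DECAY_MIN)
    return iob


class IOBTracker:
    """Incremental above-basal IOB with 4-h linear decay.

    Equivalent to :func:`iob_estimate` over a rolling window, but O(1) per
    step: with linear decay, IOB(t) = S0 - (t*S0 - S1)/240 over the active
    records, where S0/S1 are running sums of extra and extra*time.
    """

    __slots__ = ("_records", "_s0", "_s1", "_head")

    def __init__(self):
        self._records: list[tuple[float, float]] = []
        self._s0 = 0.0
        self._s1 = 0.0
        self._head = 0

    def add(self, t: float, extra_units: float) -> None:
        if extra_units > 0:
            self._records.append((t, extra_units))
            self._s0 += extra_units
            self._s1 += extra_units * t

    def value(self, t: float) -> float:
        recs = self._records
        while self._head < len(recs) and t - recs[self._head][0] >= IOB_DECAY_MIN:
            ti, ui = recs[self._head]
            self._s0 -= ui
            self._s1 -= ui * ti
            self._head += 1
        if self._s0 <= 0.0:
            return 0.0
        return self._s0 - (t * self._s0 - self._s1) / IOB_DECAY_MIN


# Precomputed action fractions: fraction of a dose's glucose-lowering effect
# realized l five-minute steps after delivery (complement of the IOB decay).
_N_DECAY_STEPS = IOB_DECAY_MIN / STEP_MIN
_ACTION = [l / _N_DECAY_STEPS for l in range(PRED_HORIZON + 1)]
# Effect multipliers of the held move on predicted glucose at step j.
_EFFECT = [
    sum(_ACTION[j - i] for i in range(1, min(j, CTRL_HORIZON) + 1))
    for j in range(PRED_HORIZON + 1)
]
_TREND_W = (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0)
_TREND_DEN = 28.0


def cgm_trend(cgm_history: Sequence[float]) -> float:
    """Least-squares CGM slope (mg/dl per 5-min step) over the last 30 min."""
    tail = cgm_history[-7:]
    if len(tail) < 7:
        raise ValueError("at least 30 min (7 samples) of CGM history required")
    return sum(w * y for w, y in zip(_TREND_W, tail)) / _TREND_DEN


def feedback_dose(
    cgm_history: Sequence[float],
    params: ControllerParams,
    basal_now: float,
    iob_now: float,
) -> float:
    """Insulin command (U per 5-min step) of the zone feedback controller.

    The command includes the basal floor: at rest inside the target zone it
    equals ``basal_now/12``; it rises above basal for predicted above-zone
    excursions (capped by the IOB constraint, whose tightness increases as
    ``gamma_iob`` decreases) and falls below basal — down to full suspension —
    for predicted below-zone excursions.  CGM below 70 mg/dl suspends
    delivery outright.
    """
    cgm = cgm_history[-1]
    if cgm < SUSPEND_CGM:
        return 0.0
    basal_step = basal_now / (60.0 / STEP_MIN)
    slope = cgm_trend(cgm_history)
    # predictive low-glucose suspend: projected 45-min-ahead reading below 75
    if cgm + 9.0 * slope < SUSPEND_CGM + 5.0:
        return 0.0

    # Zero-insulin glucose predictions over the horizon (damped trend).
    num = 0.0
    den_g = 0.0
    g_min = cgm
    damp = 1.0
    k = params.isf_est
    for j in range(1, PRED_HORIZON + 1):
        damp *= TREND_DAMP
        g = cgm + slope * j * damp
        if g < g_min:
            g_min = g
        if g > ZONE_HI:
            w, b = W_ABOVE, g - ZONE_HI
        elif g < ZONE_LO:
            w, b = W_BELOW, g - ZONE_LO
        else:
            continue
        e = k * _EFFECT[j]
        num += w * e * b
        den_g += w * e * e

    if num == 0.0 and den_g == 0.0:
        return basal_step  # at rest in the zone

    r_w = params.r_hat * R_BASE
    if num > 0.0 and slope < 0.0 and g_min < params.d_bar:
        # velocity brake: damp above-basal dosing while glucose is falling
        # below d_bar
        r_w *= 1.0 + VEL_BRAKE * (params.d_bar - g_min)
    u = num / (den_g + r_w)

    if u > 0.0:
        cap = max(0.0, IOB_CAP_GAIN * params.gamma_iob * (cgm - IOB_CAP_REF) / k - iob_now)
        if u > cap:
            u = cap
    elif u < -basal_step:
        u = -basal_step
    return basal_step + u


def cr_segments_overlapping_br(br_index: int) -> tuple[int, ...]:
    """Indices of CR segments whose daily period intersects a BR segment's."""
    br_iv = BR_PERIODS[br_index]
    return tuple(
        i for i, cr_iv in enumerate(CR_PERIODS) if intervals_overlap(br_iv, cr_iv)
    )
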