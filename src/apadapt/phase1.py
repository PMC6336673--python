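"""Phase I adaptation: feedforward (basal-rate and carb-ratio) profiles.

Basal-rate (BR) segments update from the feedback controller's own behavior:
the new estimate for a segment is the average non-meal insulin delivery the
closed loop commanded inside that segment's hours (meal-related delivery is
excluded for 3 h after each meal).  Two safety layers temper the estimate:

* a *statistical IOB constraint* — a per-segment database of (IOB, basal,
  1/CR) triples observed in iterations that produced low-glucose events; a
  proposed basal increase must be element-wise dominated by every stored
  risky triple (scaled by 0.95), otherwise the segment is cut to 95% of its
  current value instead;
* a *smoothness constraint* — no segment may exceed 1.3x the smallest of its
  circular neighbors' proposed or current values.

Carb-ratio (CR) segments are driven by a zone objective on postprandial CGM
means (4 h after each meal, truncated at the next meal) through the safe-BO
engine, with a 30% per-iteration rate bound, a 12 mg/dl predicted-change
band and a dynamically rising lower bound fed by hypoglycemia attribution.

A hybrid scheduler alternates the two: BR blocks of fixed length 2, CR
blocks that end on zone success or after 5 iterations, one profile family
per weekly iteration; Phase I ends when the zones still hold right after a
BR block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bo import BOProblem, bo_iterate
from .cohort import WeekLog
from .control import BR_PERIODS, CR_PERIODS, cr_segments_overlapping_br
from .timeutil import MINUTES_PER_DAY, STEP_MIN, in_interval

STEPS_PER_HOUR = 60 // STEP_MIN


@dataclass(frozen=True)
class Phase1Config:
    """Phase-I tuning constants (hours converted to minutes)."""

    tau_m_min: float = 180.0            # non-meal exclusion window after a meal
    lambda_s_beta: float = 1.3          # BR smoothness coefficient
    n_beta: int = 2                     # consecutive BR iterations per block
    n_gamma: int = 5                    # max CR iterations per block
    tau_gamma_min: float = 240.0        # postprandial averaging window
    cr_zones: dict = field(
        default_factory=lambda: {0: (125.0, 155.0), 1: (135.0, 165.0), 2: (125.0, 155.0)}
    )
    lambda_gamma: float = 0.30          # CR rate bound
    delta_y_gamma: float = 12.0         # CR surrogate change band, mg/dl
    iob_pre_window_min: float = 15.0    # averaging window for pre-segment IOB
    iob_reject_mode: str = "all"        # "all" (literal) or "dominating"

    def __post_init__(self):
        for lo, hi in self.cr_zones.values():
            if lo >= hi:
                raise ValueError("zone lower bound must be below upper bound")
        if self.lambda_gamma <= 0 or self.delta_y_gamma <= 0:
            raise ValueError("rate and change bounds must be positive")


# ---------------------------------------------------------------------------
# BR estimation (non-meal deliveries and their average)

def _segment_steps(period: tuple[int, int]) -> list[int]:
    s, e = period
    return [
        step for step in range(MINUTES_PER_DAY // STEP_MIN)
        if in_interval(step * STEP_MIN, s, e)
    ]


def nonmeal_delivery_set(
    week: WeekLog, segment: int, config: Phase1Config
) -> list[tuple[int, int, float]]:
    """Dose records counted as non-meal-related for one BR segment.

    Returns ``(day, time_min, units)`` for every 5-min delivery inside the
    segment's hours that falls at least ``tau_m`` after the previous consumed
    meal of the same day; deliveries before the day's first meal qualify.
    """
    steps = _segment_steps(BR_PERIODS[segment])
    out = []
    for di, day in enumerate(week.days):
        meal_times = sorted(m.time for m in day.meals)
        doses = day.doses
        for step in steps:
            t = step * STEP_MIN
            prev = None
            for mt in meal_times:
                if mt <= t:
                    prev = mt
                else:
                    break
            if prev is not None and t < prev + config.tau_m_min:
                continue
            out.append((di, t, float(doses[step])))
    return out


def br_estimate(week: WeekLog, segment: int, config: Phase1Config) -> float | None:
    """Initial BR estimate (U/hr): mean qualifying per-step dose times 12.

    ``None`` signals an empty qualifying set (the segment iteration is
    skipped and the previous value retained).
    """
    records = nonmeal_delivery_set(week, segment, config)
    if not records:
        return None
    return 12.0 * float(np.mean([u for _, _, u in records]))


# ---------------------------------------------------------------------------
# Statistical IOB constraint

@dataclass
class IOBTripleDB:
    """Per-segment history of (IOB, basal, 1/CR vector) triples that led to
    low-glucose events; the database only grows."""

    triples: dict[int, list[tuple[float, float, tuple[float, ...]]]] = field(
        default_factory=lambda: {n: [] for n in range(len(BR_PERIODS))}
    )

    def add(self, segment: int, iob: float, beta: float, inv_gammas: tuple[float, ...]):
        self.triples[segment].append((float(iob), float(beta), tuple(inv_gammas)))

    def size(self, segment: int) -> int:
        return len(self.triples[segment])


def iob_safety_check(
    candidate: tuple[float, float, tuple[float, ...]],
    db_segment: list[tuple[float, float, tuple[float, ...]]],
    beta_prev: float,
    mode: str = "all",
) -> float:
    """Enforce the statistical IOB constraint on a proposed BR increase.

    ``candidate`` is ``(IOB, beta_bar, inv_gamma_vector)`` for the upcoming
    iteration.  In the literal ``"all"`` mode the candidate must be
    element-wise <= ``(IOB_i, 0.95*beta_i, inv_gamma_i)`` for *every* stored
    risky triple; in ``"dominating"`` mode it is rejected only if it
    element-wise dominates some stored triple.  On rejection the segment
    falls back to ``0.95*beta_prev``.
    """
    iob_k, beta_bar, invg_k = candidate
    for iob_i, beta_i, invg_i in db_segment:
        if len(invg_i) != len(invg_k):
            raise ValueError("inv-gamma vector dimension mismatch")
        below = (
            iob_k <= iob_i
            and beta_bar <= 0.95 * beta_i
            and all(a <= b for a, b in zip(invg_k, invg_i))
        )
        if mode == "all":
            if not below:
                return 0.95 * beta_prev
        elif mode == "dominating":
            dominates = (
                iob_k >= iob_i
                and beta_bar >= 0.95 * beta_i
                and all(a >= b for a, b in zip(invg_k, invg_i))
            )
            if dominates:
                return 0.95 * beta_prev
        else:
            raise ValueError(f"unknown iob_reject_mode {mode!r}")
    return beta_bar


def smoothness_clip(
    beta_bar: list[float], beta_prev: list[float], config: Phase1Config
) -> tuple[float, ...]:
    """Clip each proposed segment to ``lambda * min`` of its circular
    neighbors' proposed and current values."""
    n_seg = len(beta_bar)
    if len(beta_prev) != n_seg:
        raise ValueError("vector length mismatch")
    lam = config.lambda_s_beta
    out = []
    for n in range(n_seg):
        nm, np_ = (n - 1) % n_seg, (n + 1) % n_seg
        cap = lam * min(beta_bar[nm], beta_bar[np_], beta_prev[nm], beta_prev[np_])
        out.append(min(beta_bar[n], cap))
    return tuple(out)


def iob_pre_segment(week: WeekLog, segment: int, config: Phase1Config) -> float:
    """Average IOB (U) over the 15 min preceding the segment's start, across
    the iteration's days — the candidate IOB entering the constraint."""
    start, _ = BR_PERIODS[segment]
    window_steps = int(config.iob_pre_window_min // STEP_MIN)
    decay = 240.0
    samples = []
    # flatten the week's above-basal deliveries once
    extras: list[tuple[float, float]] = []
    for di, day in enumerate(week.days):
        fb = day.dose_feedback
        bol = day.dose_bolus
        for step in range(len(fb)):
            extra = max(0.0, float(fb[step])) + float(bol[step])
            if extra > 0.0:
                extras.append((di * MINUTES_PER_DAY + step * STEP_MIN, extra))
    for di in range(len(week.days)):
        for w in range(1, window_steps + 1):
            t = di * MINUTES_PER_DAY + start - w * STEP_MIN
            if t < 0:
                continue
            iob = 0.0
            for ti, extra in extras:
                lag = t - ti
                if 0 <= lag < decay:
                    iob += extra * (1.0 - lag / decay)
            samples.append(iob)
    return float(np.mean(samples)) if samples else 0.0


def inv_gamma_vector(cr_values: tuple[float, ...], segment: int) -> tuple[float, ...]:
    """1/CR values for the CR segments overlapping a BR segment's hours."""
    return tuple(1.0 / cr_values[j] for j in cr_segments_overlapping_br(segment))


# ---------------------------------------------------------------------------
# CR measurement and adaptation

def postprandial_mean(week: WeekLog, segment: int, config: Phase1Config) -> float | None:
    """Pooled mean CGM over the windows following meals in a CR segment.

    Each consumed meal inside the segment's hours opens a window from the
    meal to ``min(tau_gamma, time to next meal)`` (clipped at the day end);
    samples from all matching meals of the week are pooled.  ``None`` when no
    meal of the week matched (the CR iteration for this segment is skipped).
    """
    s, e = CR_PERIODS[segment]
    values: list[float] = []
    for day in week.days:
        meal_times = sorted(m.time for m in day.meals)
        for mt in meal_times:
            if not in_interval(mt, s, e):
                continue
            nxt = [x for x in meal_times if x > mt]
            end = mt + config.tau_gamma_min
            if nxt:
                end = min(end, nxt[0])
            end = min(end, MINUTES_PER_DAY)
            i0, i1 = mt // STEP_MIN, int(end) // STEP_MIN
            if i1 > i0:
                values.extend(day.cgm[i0:i1])
    if not values:
        return None
    return float(np.mean(values))


@dataclass
class CRLowerBounds:
    """Per-adaptable-segment dynamic lower bounds on the carb ratio: the
    running maximum of values that caused hypoglycemia risk (nondecreasing)."""

    bounds: dict[int, float] = field(default_factory=dict)

    def update(self, segment: int, gamma_risky: float) -> None:
        self.bounds[segment] = max(self.bounds.get(segment, 0.0), float(gamma_risky))

    def get(self, segment: int) -> float:
        return self.bounds.get(segment, 0.0)


def cr_adapt_step(
    problem: BOProblem,
    y: float,
    gamma_bar: float,
    config: Phase1Config,
) -> tuple[float, dict]:
    """One CR iteration for a segment through the safe-BO engine.

    Applies the 30% rate bound, the 12 mg/dl surrogate-change band and the
    dynamic lower bound; returns the next carb ratio and an audit record.
    An infeasible bound set (lower bound above the rate-limited reach) holds
    the current value and flags the iteration.
    """
    gamma_prev = problem.psi
    lo, hi = problem.zone
    if lo <= y <= hi:
        return gamma_prev, {
            "branch": "objective_met", "met": True,
            "psi_prev": gamma_prev, "psi_next": gamma_prev, "y_prev": y,
        }
    if gamma_bar > (1.0 + config.lambda_gamma) * gamma_prev:
        return gamma_prev, {
            "branch": "infeasible_lower_bound", "flag": "hold",
            "psi_prev": gamma_prev, "psi_next": gamma_prev, "y_prev": y,
            "gamma_bar": gamma_bar,
        }
    problem.bounds = [(gamma_bar, float("inf"))] if gamma_bar > 0 else []
    gamma_next, info = bo_iterate(problem, y)
    info["met"] = False
    info["gamma_bar"] = gamma_bar
    return gamma_next, info


# ---------------------------------------------------------------------------
# Scheduling

@dataclass(frozen=True)
class Phase1State:
    """Progress of the alternating BR/CR schedule."""

    mode: str = "BR"          # family adapted by the *next* action
    br_done: int = 0          # BR iterations applied in the current block
    cr_done: int = 0          # CR iterations applied in the current block
    finished: bool = False


def phase1_schedule(
    state: Phase1State, zones_met: bool, config: Phase1Config | None = None
) -> tuple[str, Phase1State]:
    """Next weekly action for Phase I and the updated schedule state.

    Actions: ``"adapt_BR"``, ``"adapt_CR"`` or ``"terminate_phase1"``.
    ``zones_met`` is whether every adaptable CR segment's postprandial mean
    from the latest week sits inside its zone.  Exactly one profile family is
    adapted per iteration; BR blocks have fixed length ``n_beta``; CR blocks
    end early on zone success or at ``n_gamma``; the phase terminates when
    the zones still hold immediately after a BR block.
    """
    config = config or Phase1Config()
    if state.finished:
        return "terminate_phase1", state
    if state.mode == "BR":
        if state.br_done < config.n_beta:
            return "adapt_BR", replace(state, br_done=state.br_done + 1)
        # BR block complete: termination test
        if zones_met:
            return "terminate_phase1", replace(state, finished=True)
        return "adapt_CR", replace(state, mode="CR", cr_done=1, br_done=0)
    # CR mode
    if zones_met or state.cr_done >= config.n_gamma:
        return "adapt_BR", replace(state, mode="BR", br_done=1, cr_done=0)
    return "adapt_CR", replace(state, cr_done=state.cr_done + 1)


# ---------------------------------------------------------------------------
# Hypoglycemia attribution

def attribute_low_glucose_events(
    week: WeekLog, config: Phase1Config
) -> tuple[set[int], set[int]]:
    """Map each low-glucose event to a BR segment and, when postprandial, to
    an adaptable CR segment.

    The BR segment active at the event start is charged; a CR segment is
    charged when the event starts within ``tau_gamma`` after a consumed meal
    in that segment's hours (before the following meal).
    """
    basal = week.parameters_used.basal
    br_hits: set[int] = set()
    cr_hits: set[int] = set()
    for di, day in enumerate(week.days):
        meal_times = sorted(m.time for m in day.meals)
        for start, _dur in day.low_glucose_events:
            br_hits.add(basal.segment_index(start))
            prev = None
            for mt in meal_times:
                if mt <= start:
                    prev = mt
                else:
                    break
            if prev is None:
                continue
            if start - prev < config.tau_gamma_min:
                for seg, (s, e) in enumerate(CR_PERIODS):
                    if seg in week.parameters_used.carb_ratio.adaptable and in_interval(
                        prev, s, e
                    ):
                        cr_hits.add(seg)
    return br_hits, cr_hits
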