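"""Phase II adaptation: feedback-controller parameter selection and tuning.

With the feedforward profiles settled by Phase I, one of the three feedback
parameters (``r_hat``, ``d_bar``, ``gamma_iob``) is selected by an
advisory-mode sensitivity analysis: the dosing algorithm is re-run over the
most recent *recorded* CGM traces (open loop — glucose is not re-simulated)
at each parameter's upper and lower bound, and the parameter moving total
insulin the most (default; the literal arg-min variant is selectable) is
chosen.  The selected parameter is then adapted weekly through the safe-BO
engine toward a mean-glucose target, under a 30% rate bound, a 6 mg/dl
surrogate change band, the static bound fractions and dynamic bounds that
tighten whenever an iteration produces a low-glucose event.  Adaptation ends
when the weekly mean CGM drops below 135 mg/dl or a bound becomes active.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bo import BOProblem, bo_iterate
from .cohort import WeekLog
from .control import (
    ADAPTABLE_PARAMS,
    AGGRESSIVE_DIRECTION,
    OBJECTIVE_SIGN,
    ControllerParams,
    feedback_dose,
)
from .timeutil import MINUTES_PER_DAY, STEP_MIN


@dataclass(frozen=True)
class Phase2Config:
    lambda_phi: float = 0.30          # rate bound on the selected parameter
    delta_y_phi: float = 6.0          # surrogate change band, mg/dl
    terminal_mean_bg: float = 135.0   # stop once weekly mean CGM is below
    selection_rule: str = "max_sensitivity"  # or "min_sensitivity"
    replay_weeks: int = 1             # how many recent weeks feed the replay

    def __post_init__(self):
        if not 70.0 <= self.terminal_mean_bg <= 180.0:
            raise ValueError("terminal mean BG must lie in [70, 180]")
        if self.selection_rule not in ("max_sensitivity", "min_sensitivity"):
            raise ValueError("unknown selection rule")


def advisory_replay(weeks: Sequence[WeekLog], params_variant: ControllerParams) -> float:
    """Total insulin (U) the controller would have commanded over recorded
    CGM traces under a parameter variant.

    Open-loop replay: the recorded CGM sequence is fixed; the feedback dose
    is recomputed step by step with IOB rebuilt from the replayed commands
    plus the recorded meal boluses.  With the recorded parameters the replay
    reproduces the recorded basal+feedback insulin exactly.
    """
    if not weeks:
        warnings.warn("advisory replay invoked with no history", stacklevel=2)
        return 0.0
    from .control import IOBTracker  # same arithmetic as the simulator

    total = 0.0
    for week in weeks:
        basal = week.parameters_used.basal
        history: list[float] = []
        iob = IOBTracker()
        for di, day in enumerate(week.days):
            for step in range(len(day.cgm)):
                t = step * STEP_MIN
                t_abs = di * MINUTES_PER_DAY + t
                history.append(float(day.cgm[step]))
                basal_now = basal.value_at(t)
                basal_step = basal_now / 12.0
                if len(history) >= 7:
                    cmd = feedback_dose(history, params_variant, basal_now, iob.value(t_abs))
                else:
                    cmd = basal_step
                iob.add(t_abs, max(0.0, cmd - basal_step) + float(day.dose_bolus[step]))
                total += cmd
    return total


def select_parameter(
    weeks: Sequence[WeekLog],
    params: ControllerParams,
    config: Phase2Config | None = None,
) -> tuple[str, dict[str, float]]:
    """Advisory-mode sensitivity analysis over the three feedback parameters.

    Replays the recent weeks at each parameter's upper and lower bound (the
    other two held at their current values) and returns the selected
    parameter name plus the |delta insulin| triple.  Ties break by the fixed
    order r_hat, d_bar, gamma_iob.
    """
    config = config or Phase2Config()
    deltas: dict[str, float] = {}
    for name in ADAPTABLE_PARAMS:
        lo, hi = params.bounds(name)
        i_hi = advisory_replay(weeks, params.with_value(name, hi))
        i_lo = advisory_replay(weeks, params.with_value(name, lo))
        deltas[name] = abs(i_hi - i_lo)
    pick = ADAPTABLE_PARAMS[0]
    for name in ADAPTABLE_PARAMS[1:]:
        if config.selection_rule == "max_sensitivity":
            if deltas[name] > deltas[pick]:
                pick = name
        else:
            if deltas[name] < deltas[pick]:
                pick = name
    return pick, deltas


@dataclass
class PhiBounds:
    """Static box (from the bound fractions) plus dynamic bounds accumulated
    from hypoglycemia-risk-causing parameter values; dynamic bounds only
    tighten."""

    static: tuple[float, float]
    dynamic_lo: float = -math.inf
    dynamic_hi: float = math.inf

    def effective(self) -> tuple[float, float]:
        return (max(self.static[0], self.dynamic_lo), min(self.static[1], self.dynamic_hi))

    def update_on_hypo(self, name: str, phi_k: float) -> None:
        """Exclude ``phi_k`` (and beyond) in the more-insulin direction after
        an iteration with a low-glucose event."""
        if AGGRESSIVE_DIRECTION[name] < 0:
            # more insulin = smaller value: raise the dynamic lower bound
            self.dynamic_lo = max(self.dynamic_lo, phi_k)
        else:
            self.dynamic_hi = min(self.dynamic_hi, phi_k)

    def is_active(self, phi: float, tol: float = 1e-9) -> bool:
        lo, hi = self.effective()
        return phi <= lo + tol or phi >= hi - tol


def make_phi_problem(
    name: str, params: ControllerParams, config: Phase2Config | None = None
) -> BOProblem:
    """Safe-BO instance for the selected feedback parameter."""
    config = config or Phase2Config()
    return BOProblem(
        psi=params.value(name),
        delta=config.delta_y_phi,
        objective_sign=OBJECTIVE_SIGN[name],
        zone=(-math.inf, config.terminal_mean_bg),
        rate_limit=config.lambda_phi,
    )


def phi_adapt_step(
    problem: BOProblem,
    y_prev: float,
    bounds: PhiBounds,
    config: Phase2Config | None = None,
) -> tuple[float, bool, dict]:
    """One Phase-II iteration: next parameter value, terminate flag, audit.

    Terminates when the weekly mean glucose is already below the target,
    when the feasible interval collapses, or when the emitted value lands on
    a bound of the feasible box (the controller's performance limit).
    """
    config = config or Phase2Config()
    lo, hi = bounds.effective()
    if y_prev < config.terminal_mean_bg:
        return problem.psi, True, {
            "branch": "objective_met", "psi_prev": problem.psi,
            "psi_next": problem.psi, "y_prev": y_prev, "bounds": (lo, hi),
        }
    if lo > hi:
        return problem.psi, True, {
            "branch": "infeasible_bounds", "flag": "performance_limit",
            "psi_prev": problem.psi, "psi_next": problem.psi,
            "y_prev": y_prev, "bounds": (lo, hi),
        }
    problem.bounds = [(lo, hi)]
    phi_next, info = bo_iterate(problem, y_prev)
    info["bounds"] = (lo, hi)
    terminate = bounds.is_active(phi_next) or info.get("flag") is not None
    if terminate:
        info["flag"] = info.get("flag", "bound_active")
    return phi_next, terminate, info
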