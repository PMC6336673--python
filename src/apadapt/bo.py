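"""Safe sequential optimization with a local linear surrogate.

Shared engine for carb-ratio and feedback-parameter adaptation.  One scalar
tuning parameter psi is driven toward a measurement target through weekly
iterations: while too little comparable history exists the step is a fixed
fractional move along the known search direction; once enough admissible
(psi, y) pairs are available a linear surrogate ``y ~ theta1*psi + theta2``
is fitted by least squares and the next psi minimizes the surrogate subject
to a measurement-change band ``|y_hat - y_prev| <= delta`` and the known
linear safety constraints (rate bound, box bounds, dynamic safety bounds).
A directional consistency check discards surrogate steps that move against
the known sign of d(y)/d(psi), and every emitted value is truncated into the
feasible set.  The engine is deterministic: all randomness lives in the
measurements fed to it.

Admissibility: only iterations recorded under the same "environment" (the
frozen values of every other adaptation parameter) inform the surrogate,
mirroring the requirement that data used for fitting come from iterations
where the same parameter set was adapted while the rest stayed constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

Interval = tuple[float, float]  # (lo, hi); use +-inf for one-sided bounds

#: minimum number of admissible points before the surrogate is trusted; with
#: weekly glucose measurements noisy at the 10-15 mg/dl level, a fit through
#: fewer than 4 points over a narrow parameter range is uninformative and its
#: predicted-change band under-protects
N_BO_DEFAULT = 3
#: fractional heuristic step along the search direction
DELTA_S_DEFAULT = 0.10


class InfeasibleStep(Exception):
    """The intersection of the safety constraints is empty."""


class RankDeficientData(Exception):
    """All admissible psi values coincide; no line can be fitted."""


@dataclass
class BOProblem:
    """State of one safe-BO instance (one tuning parameter).

    ``data`` accumulates every (psi, y) measurement with a hashable ``tag``
    describing its environment; ``current_tag`` selects the admissible subset.
    ``objective_sign`` is the known sign of d(y)/d(psi).  ``zone`` is the
    target band for y: measurements inside it mean "objective met" and the
    caller stops; ``(-inf, upper)`` expresses a one-sided target.
    """

    psi: float
    delta: float
    objective_sign: int
    zone: Interval
    rate_limit: float                   # lambda: |psi' - psi| <= lambda*psi
    bounds: list[Interval] = field(default_factory=list)
    delta_s: float = DELTA_S_DEFAULT
    n_bo: int = N_BO_DEFAULT
    data: list[tuple[float, float]] = field(default_factory=list)
    tags: list[Hashable] = field(default_factory=list)
    current_tag: Hashable = None
    direction: int = 0
    theta: tuple[float, float] | None = None
    iteration: int = 0

    def record(self, psi: float, y: float, tag: Hashable) -> None:
        self.data.append((psi, y))
        self.tags.append(tag)


def update_admissible_set(problem: BOProblem) -> list[int]:
    """Indices of recorded measurements taken in the current environment."""
    return [i for i, t in enumerate(problem.tags) if t == problem.current_tag]


def search_direction(y_prev: float, zone: Interval, objective_sign: int) -> int:
    """Step sign that moves y toward the target zone.

    ``objective_sign`` is the known sign of d(y)/d(psi); y above the zone
    demands a y-decrease, hence a psi-step of ``-objective_sign``, and vice
    versa.  Inside the zone no move is demanded (returns 0).
    """
    lo, hi = zone
    if y_prev > hi:
        return -objective_sign
    if y_prev < lo:
        return objective_sign
    return 0


def heuristic_step(psi_prev: float, direction: int, delta_s: float = DELTA_S_DEFAULT) -> float:
    """Fixed fractional move: psi = (1 + delta_s * S) * psi_prev."""
    return (1.0 + delta_s * direction) * psi_prev


def fit_linear_surrogate(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Ordinary least squares for y = theta1*psi + theta2.

    Raises :class:`RankDeficientData` when fewer than two distinct psi values
    are present (the caller falls back to the heuristic step).
    """
    if len(points) < 2:
        raise RankDeficientData("need at least two points")
    xs = [p for p, _ in points]
    ys = [y for _, y in points]
    n = float(len(xs))
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    if sxx == 0.0:
        if all(y == ys[0] for y in ys):
            return (0.0, ys[0])
        raise RankDeficientData("all psi values identical")
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    th1 = sxy / sxx
    return (th1, my - th1 * mx)


def _intersect(intervals: Sequence[Interval]) -> Interval:
    lo = max((iv[0] for iv in intervals), default=-math.inf)
    hi = min((iv[1] for iv in intervals), default=math.inf)
    if lo > hi:
        raise InfeasibleStep(f"empty feasible interval [{lo}, {hi}]")
    return lo, hi


def rate_interval(psi_prev: float, rate_limit: float) -> Interval:
    """|psi - psi_prev| <= rate_limit * psi_prev as an interval."""
    return (psi_prev * (1.0 - rate_limit), psi_prev * (1.0 + rate_limit))


def solve_constrained_step(
    theta: tuple[float, float],
    y_prev: float,
    delta: float,
    constraints: Sequence[Interval],
    psi_prev: float,
) -> float:
    """Minimize the linear surrogate inside the delta-band and constraints.

    The objective ``theta1*psi + theta2`` is linear, so the optimum sits at a
    vertex of the feasible interval: the band ``|y_hat(psi) - y_prev| <=
    delta`` intersected with the linear constraints.  A flat surrogate
    (theta1 == 0) gives no preferred direction; the step holds position.
    """
    th1, th2 = theta
    if th1 == 0.0:
        return psi_prev
    b1 = (y_prev - delta - th2) / th1
    b2 = (y_prev + delta - th2) / th1
    band = (min(b1, b2), max(b1, b2))
    lo, hi = _intersect([band, *constraints])
    return hi if th1 < 0 else lo


def consistency_check(
    psi_candidate: float,
    psi_prev: float,
    direction: int,
    heuristic_value: float,
) -> float:
    """Replace a surrogate step that moves against the search direction.

    A zero move counts as inconsistent whenever a move is demanded
    (direction != 0).
    """
    if direction == 0:
        return psi_candidate
    diff = psi_candidate - psi_prev
    sign = (diff > 0) - (diff < 0)
    if sign != direction:
        return heuristic_value
    return psi_candidate


def safety_truncate(psi: float, constraints: Sequence[Interval]) -> float:
    """Project psi onto the intersection of interval constraints."""
    lo, hi = _intersect(constraints)
    return min(hi, max(lo, psi))


def bo_iterate(problem: BOProblem, y_prev: float) -> tuple[float, dict]:
    """One pass of the safe-BO loop; returns the next psi and an audit dict.

    Executes: admissible-set update, search-direction update, heuristic or
    surrogate-based step, directional consistency check and safety
    truncation.  The caller implements psi, measures y, and feeds it back via
    :meth:`BOProblem.record`.  Termination is the caller's business (zone
    reached, bound active, iteration cap).
    """
    problem.iteration += 1
    adm = update_admissible_set(problem)
    direction = search_direction(y_prev, problem.zone, problem.objective_sign)
    problem.direction = direction
    info: dict = {
        "iteration": problem.iteration,
        "admissible": list(adm),
        "direction": direction,
        "y_prev": y_prev,
        "psi_prev": problem.psi,
    }
    if direction == 0:
        info["branch"] = "objective_met"
        return problem.psi, info

    constraints = [rate_interval(problem.psi, problem.rate_limit), *problem.bounds]
    heur = heuristic_step(problem.psi, direction, problem.delta_s)

    if len(adm) <= problem.n_bo:
        candidate = heur
        info["branch"] = "heuristic"
        problem.theta = None
    else:
        try:
            theta = fit_linear_surrogate([problem.data[i] for i in adm])
            problem.theta = theta
            candidate = solve_constrained_step(
                theta, y_prev, problem.delta, constraints, problem.psi
            )
            checked = consistency_check(candidate, problem.psi, direction, heur)
            if checked != candidate:
                info["branch"] = "surrogate_consistency_fallback"
            else:
                info["branch"] = "surrogate"
            candidate = checked
            info["theta"] = theta
        except RankDeficientData:
            candidate = heur
            info["branch"] = "heuristic_rank_deficient"
            problem.theta = None
        except InfeasibleStep:
            info["branch"] = "infeasible"
            info["flag"] = "infeasible_step"
            return problem.psi, info

    try:
        psi_next = safety_truncate(candidate, constraints)
    except InfeasibleStep:
        info["branch"] = info.get("branch", "") + "+infeasible_truncate"
        info["flag"] = "infeasible_constraints"
        return problem.psi, info

    info["candidate"] = candidate
    info["psi_next"] = psi_next
    problem.psi = psi_next
    return psi_next, info
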