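"""Study execution, glycemic metrics and cohort statistics.

``run_scenario`` drives the full multi-week protocol for a cohort: week 1
collects data only; from week 2 the Phase-I scheduler alternates basal-rate
and carb-ratio adaptation, and once Phase I terminates the Phase-II
machinery selects and tunes one feedback parameter until its own stopping
rule fires.  Every weekly iteration appends a JSON-serializable audit record
carrying the parameters used, the measurements, each constraint evaluation
and the safety-database snapshots, so that every accepted iterate can be
re-checked against the rate, smoothness, IOB and bound constraints from the
logs alone.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import phase1 as p1
from . import phase2 as p2
from .bo import BOProblem
from .cohort import ParamsUsed, ScenarioConfig, WeekLog, run_week, week_rng
from .control import (
    ADAPTABLE_PARAMS,
    BasalProfile,
    CarbRatioProfile,
    ControllerParams,
)
from .metabolism import VirtualPatient, generate_cohort
from .phase1 import Phase1Config, Phase1State
from .phase2 import Phase2Config, PhiBounds


# ---------------------------------------------------------------------------
# Glycemic metrics

@dataclass(frozen=True)
class GlycemicMetrics:
    """Standard CGM-sample-fraction outcomes for one patient-week."""

    pct_below_54: float
    pct_below_70: float
    pct_in_70_180: float
    pct_above_180: float
    mean_bg: float

    def as_dict(self) -> dict:
        return asdict(self)


def glycemic_metrics(week: WeekLog | np.ndarray) -> GlycemicMetrics:
    """Sample-fraction metrics over all 5-min CGM samples of a week.

    Boundary convention: the 70–180 band is inclusive of both endpoints;
    below-70 and below-54 are strict.
    """
    cgm = week.all_cgm() if isinstance(week, WeekLog) else np.asarray(week, float)
    if cgm.size == 0:
        raise ValueError("empty CGM trace")
    n = cgm.size
    return GlycemicMetrics(
        pct_below_54=100.0 * float(np.sum(cgm < 54.0)) / n,
        pct_below_70=100.0 * float(np.sum(cgm < 70.0)) / n,
        pct_in_70_180=100.0 * float(np.sum((cgm >= 70.0) & (cgm <= 180.0))) / n,
        pct_above_180=100.0 * float(np.sum(cgm > 180.0)) / n,
        mean_bg=float(np.mean(cgm)),
    )


METRIC_NAMES = ("pct_below_54", "pct_below_70", "pct_in_70_180", "pct_above_180", "mean_bg")


@dataclass
class CohortSummary:
    """Median (IQR) per metric at two study weeks plus paired test p-values."""

    weeks_compared: tuple[int, int]
    medians: dict  # metric -> {week: (median, iqr)}
    p_values: dict  # metric -> float
    zero_variance: dict  # metric -> bool

    def table(self) -> pd.DataFrame:
        w1, w2 = self.weeks_compared
        rows = []
        for m in self.medians:
            med1, iqr1 = self.medians[m][w1]
            med2, iqr2 = self.medians[m][w2]
            rows.append(
                {
                    "metric": m,
                    f"week_{w1}": f"{med1:.1f} ({iqr1:.1f})",
                    f"week_{w2}": f"{med2:.1f} ({iqr2:.1f})",
                    "p_value": self.p_values[m],
                }
            )
        return pd.DataFrame(rows)


def cohort_summary(
    frame: pd.DataFrame, weeks_compared: tuple[int, int] | None = None
) -> CohortSummary:
    """Cohort medians/IQRs and Wilcoxon signed-rank tests between two weeks.

    ``frame`` has one row per patient-week with the metric columns.  The IQR
    uses linear interpolation between quartiles; the signed-rank test is
    two-sided with zero differences dropped, exact for small samples.
    """
    if weeks_compared is None:
        weeks_compared = (int(frame["week"].min()), int(frame["week"].max()))
    w1, w2 = weeks_compared
    medians: dict = {}
    p_values: dict = {}
    zero_var: dict = {}
    f1 = frame[frame["week"] == w1].set_index("patient").sort_index()
    f2 = frame[frame["week"] == w2].set_index("patient").sort_index()
    if len(f1) < 5:
        raise ValueError("at least 5 patients required for the paired test")
    for m in METRIC_NAMES:
        medians[m] = {}
        for w, f in ((w1, f1), (w2, f2)):
            vals = f[m].to_numpy()
            q1, q3 = np.percentile(vals, [25, 75])
            medians[m][w] = (float(np.median(vals)), float(q3 - q1))
        d = f2[m].to_numpy() - f1[m].to_numpy()
        if np.all(d == 0.0):
            p_values[m] = 1.0
            zero_var[m] = True
        else:
            res = stats.wilcoxon(
                f1[m].to_numpy(), f2[m].to_numpy(), zero_method="wilcox",
                alternative="two-sided",
            )
            p_values[m] = float(res.pvalue)
            zero_var[m] = False
    return CohortSummary(
        weeks_compared=(w1, w2), medians=medians, p_values=p_values, zero_variance=zero_var
    )


# ---------------------------------------------------------------------------
# Study ledger

@dataclass
class StudyLedger:
    """Per-patient-week audit records of a full adaptation study."""

    scenario: dict
    records: list[dict] = field(default_factory=list)

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"patient": r["patient"], "week": r["week"], **r["metrics"]}
            rows.append(row)
        return pd.DataFrame(rows)

    def weekly_median_frame(self) -> pd.DataFrame:
        f = self.metrics_frame()
        return f.groupby("week")[list(METRIC_NAMES)].median().reset_index()

    def patient_records(self, patient: int) -> list[dict]:
        return [r for r in self.records if r["patient"] == patient]

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"scenario": self.scenario}) + "\n")
            for r in self.records:
                fh.write(json.dumps(r) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "StudyLedger":
        with open(path) as fh:
            header = json.loads(fh.readline())
            records = [json.loads(line) for line in fh if line.strip()]
        return cls(scenario=header["scenario"], records=records)


# ---------------------------------------------------------------------------
# Per-patient adaptation state machine

def initial_params(
    patient: VirtualPatient, scenario: ScenarioConfig
) -> ParamsUsed:
    """Scenario-initialized profiles and nominal controller parameters.

    Basal multipliers apply to all five segments; carb-ratio multipliers to
    the three adaptable meal segments (the overnight segment keeps its
    reference value).  The controller's correction gain comes from the 1800
    rule on the total daily insulin implied by the *initial* basal profile,
    as a clinician would program it.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([scenario.seed, patient.id, 0])
    )
    br_true = patient.br_truth()
    cr_true = patient.cr_truth()
    if scenario.br_init_multiplier == "uniform":
        br_mult = [rng.uniform(0.5, 1.5) for _ in br_true.values]
    else:
        br_mult = float(scenario.br_init_multiplier)
    if scenario.cr_init_multiplier == "uniform":
        cr_mult = [rng.uniform(0.5, 1.5) for _ in cr_true.values]
    else:
        cr_mult = float(scenario.cr_init_multiplier)
    basal = br_true.scaled(br_mult)
    cr = cr_true.scaled(cr_mult)  # adaptable segments only
    daily_basal = sum(
        v * (((e - s) % 1440) / 60.0) for v, (s, e) in zip(basal.values, basal.periods)
    )
    tdi_est = 2.0 * daily_basal
    controller = ControllerParams(isf_est=1800.0 / tdi_est)
    return ParamsUsed(basal=basal, carb_ratio=cr, controller=controller)


class _PatientAdaptation:
    """Weekly decision logic for one patient (internal to run_scenario)."""

    def __init__(
        self,
        patient: VirtualPatient,
        scenario: ScenarioConfig,
        p1cfg: Phase1Config,
        p2cfg: Phase2Config,
    ):
        self.patient = patient
        self.scenario = scenario
        self.p1cfg = p1cfg
        self.p2cfg = p2cfg
        self.params = initial_params(patient, scenario)
        self.phase = 1
        self.p1_state = Phase1State()
        self.iob_db = p1.IOBTripleDB()
        self.cr_bounds = p1.CRLowerBounds()
        self.cr_problems: dict[int, BOProblem] = {
            seg: BOProblem(
                psi=self.params.carb_ratio.values[seg],
                delta=p1cfg.delta_y_gamma,
                objective_sign=+1,  # larger carb ratio -> less insulin -> higher y
                zone=p1cfg.cr_zones[seg],
                rate_limit=p1cfg.lambda_gamma,
            )
            for seg in self.params.carb_ratio.adaptable
        }
        self.phi_name: str | None = None
        self.phi_problem: BOProblem | None = None
        self.phi_bounds: PhiBounds | None = None
        self.phi_deltas: dict[str, float] | None = None
        self.recent_weeks: deque[WeekLog] = deque(maxlen=max(1, p2cfg.replay_weeks))
        self.last_family = "collect"  # what the current week's params reflect

    # -- environment fingerprints ------------------------------------------
    def _cr_tag(self) -> tuple:
        cp = self.params.controller
        return (
            "CR",
            tuple(round(v, 9) for v in self.params.basal.values),
            (cp.r_hat, cp.d_bar, cp.gamma_iob),
        )

    def _phi_tag(self) -> tuple:
        cp = self.params.controller
        frozen = tuple(
            cp.value(n) for n in ADAPTABLE_PARAMS if n != self.phi_name
        )
        return (
            "phi",
            self.phi_name,
            tuple(round(v, 9) for v in self.params.basal.values),
            tuple(round(v, 9) for v in self.params.carb_ratio.values),
            frozen,
        )

    # -- weekly update ------------------------------------------------------
    def observe_and_adapt(self, week: WeekLog, is_last: bool) -> dict:
        """Record week-k data, update safety databases, and (unless the study
        ends) choose and apply the parameters for week k+1."""
        p1cfg = self.p1cfg
        self.recent_weeks.append(week)
        metrics = glycemic_metrics(week)
        mean_bg = metrics.mean_bg
        post = {
            seg: p1.postprandial_mean(week, seg, p1cfg)
            for seg in self.params.carb_ratio.adaptable
        }
        measured = {s: y for s, y in post.items() if y is not None}
        zones_met = bool(measured) and all(
            p1cfg.cr_zones[s][0] <= y <= p1cfg.cr_zones[s][1]
            for s, y in measured.items()
        )

        # safety databases update from this week's events
        br_hits, cr_hits = p1.attribute_low_glucose_events(week, p1cfg)
        events = week.low_glucose_events_abs()
        db_added = []
        for seg in sorted(br_hits):
            triple = (
                p1.iob_pre_segment(week, seg, p1cfg),
                week.parameters_used.basal.values[seg],
                p1.inv_gamma_vector(week.parameters_used.carb_ratio.values, seg),
            )
            self.iob_db.add(seg, *triple)
            db_added.append({"segment": seg, "triple": [triple[0], triple[1], list(triple[2])]})
        for seg in sorted(cr_hits):
            self.cr_bounds.update(seg, week.parameters_used.carb_ratio.values[seg])
        if self.phase == 2 and self.phi_name is not None and events:
            self.phi_bounds.update_on_hypo(
                self.phi_name, week.parameters_used.controller.value(self.phi_name)
            )

        # measurements feed the BO datasets (tagged by adapting family + env)
        cr_tag = self._cr_tag()
        for seg, y in measured.items():
            self.cr_problems[seg].record(
                week.parameters_used.carb_ratio.values[seg],
                y,
                (self.last_family,) + cr_tag[1:],
            )
        if self.phase == 2 and self.phi_problem is not None:
            self.phi_problem.record(
                week.parameters_used.controller.value(self.phi_name),
                mean_bg,
                (self.last_family,) + self._phi_tag()[1:],
            )

        record = {
            "patient": self.patient.id,
            "week": week.iteration_index,
            "phase": self.phase,
            "family": self.last_family,
            "params": _params_dict(week.parameters_used),
            "metrics": metrics.as_dict(),
            "postprandial": {str(s): y for s, y in post.items()},
            "zones_met": zones_met,
            "n_low_events": len(events),
            "db_added": db_added,
            "db_sizes": {str(n): self.iob_db.size(n) for n in range(5)},
            "cr_lower_bounds": {str(s): b for s, b in self.cr_bounds.bounds.items()},
        }
        if week.iteration_index == 1:
            # Data-collection week: personalize the controller gain from the
            # actually delivered total daily insulin (1800 rule) before any
            # adaptation starts.  The initial profile-implied guess can be
            # badly off under a wrong scenario initialization.
            tdi_delivered = week.total_insulin() / len(week.days)
            if tdi_delivered > 0:
                self.params = ParamsUsed(
                    basal=self.params.basal,
                    carb_ratio=self.params.carb_ratio,
                    controller=self.params.controller.__class__(
                        **{
                            **{
                                f: getattr(self.params.controller, f)
                                for f in (
                                    "r_hat", "d_bar", "gamma_iob",
                                    "nominal_r_hat", "nominal_d_bar",
                                    "nominal_gamma_iob",
                                )
                            },
                            "isf_est": 1800.0 / tdi_delivered,
                        }
                    ),
                )
                record["isf_est_personalized"] = 1800.0 / tdi_delivered

        if is_last:
            record["action"] = "end_of_study"
            return record

        if week.iteration_index == 1:
            # week 1 collects data only; adaptation starts from week 2
            action, self.p1_state = p1.phase1_schedule(self.p1_state, zones_met, p1cfg)
        elif self.phase == 1:
            action, self.p1_state = p1.phase1_schedule(self.p1_state, zones_met, p1cfg)
        else:
            action = "phase2" if self.phase == 2 else "frozen"

        if action == "adapt_BR":
            record["action"] = "adapt_BR"
            record["br_update"] = self._adapt_br(week)
            self.last_family = "BR"
        elif action == "adapt_CR":
            record["action"] = "adapt_CR"
            record["cr_update"] = self._adapt_cr(measured)
            self.last_family = "CR"
        elif action == "terminate_phase1":
            self.phase = 2
            record["action"] = "phase2"
            record["phi_update"] = self._adapt_phi(mean_bg)
            self.last_family = "phi"
        elif action == "phase2":
            record["action"] = "phase2"
            record["phi_update"] = self._adapt_phi(mean_bg)
            self.last_family = "phi"
        else:
            record["action"] = "frozen"
            self.last_family = "frozen"
        record["params_next"] = _params_dict(self.params)
        return record

    # -- family-specific updates -------------------------------------------
    def _adapt_br(self, week: WeekLog) -> dict:
        p1cfg = self.p1cfg
        basal = self.params.basal
        beta_prev = list(basal.values)
        cr_vals = self.params.carb_ratio.values
        audit_segments = []
        beta_bar = []
        for n in range(len(beta_prev)):
            raw = p1.br_estimate(week, n, p1cfg)
            seg_audit = {"segment": n, "beta_prev": beta_prev[n], "beta_bar_raw": raw}
            if raw is None:
                beta_bar.append(beta_prev[n])
                seg_audit["skipped"] = True
            elif raw > beta_prev[n]:
                candidate = (
                    p1.iob_pre_segment(week, n, p1cfg),
                    raw,
                    p1.inv_gamma_vector(cr_vals, n),
                )
                checked = p1.iob_safety_check(
                    candidate,
                    self.iob_db.triples[n],
                    beta_prev[n],
                    mode=p1cfg.iob_reject_mode,
                )
                beta_bar.append(checked)
                seg_audit["iob_checked"] = True
                seg_audit["iob_candidate"] = [candidate[0], candidate[1], list(candidate[2])]
                seg_audit["iob_db"] = [
                    [t[0], t[1], list(t[2])] for t in self.iob_db.triples[n]
                ]
                seg_audit["iob_rejected"] = checked != raw
            else:
                beta_bar.append(raw)
                seg_audit["iob_checked"] = False
            audit_segments.append(seg_audit)
        beta_new = p1.smoothness_clip(beta_bar, beta_prev, p1cfg)
        self.params = ParamsUsed(
            basal=BasalProfile(tuple(beta_new)),
            carb_ratio=self.params.carb_ratio,
            controller=self.params.controller,
        )
        return {
            "segments": audit_segments,
            "beta_prev": beta_prev,
            "beta_bar": beta_bar,
            "beta_new": list(beta_new),
            "lambda_s_beta": p1cfg.lambda_s_beta,
        }

    def _adapt_cr(self, measured: dict[int, float]) -> dict:
        p1cfg = self.p1cfg
        cr_vals = list(self.params.carb_ratio.values)
        audit = {}
        tag = self._cr_tag()
        for seg in self.params.carb_ratio.adaptable:
            if seg not in measured:
                audit[str(seg)] = {"branch": "no_measurement", "psi_prev": cr_vals[seg],
                                   "psi_next": cr_vals[seg]}
                continue
            problem = self.cr_problems[seg]
            problem.current_tag = ("CR",) + tag[1:]
            problem.psi = cr_vals[seg]
            gamma_next, info = p1.cr_adapt_step(
                problem, measured[seg], self.cr_bounds.get(seg), p1cfg
            )
            info["gamma_prev"] = cr_vals[seg]
            info["gamma_next"] = gamma_next
            info["rate_limit"] = p1cfg.lambda_gamma
            audit[str(seg)] = _jsonable(info)
            cr_vals[seg] = gamma_next
        self.params = ParamsUsed(
            basal=self.params.basal,
            carb_ratio=CarbRatioProfile(
                tuple(cr_vals), adaptable=self.params.carb_ratio.adaptable
            ),
            controller=self.params.controller,
        )
        return audit

    def _adapt_phi(self, mean_bg: float) -> dict:
        p2cfg = self.p2cfg
        if self.phi_name is None:
            name, deltas = p2.select_parameter(
                list(self.recent_weeks), self.params.controller, p2cfg
            )
            self.phi_name = name
            self.phi_deltas = deltas
            self.phi_problem = p2.make_phi_problem(name, self.params.controller, p2cfg)
            self.phi_bounds = PhiBounds(static=self.params.controller.bounds(name))
        if self.phase != 2:
            self.phase = 2
        self.phi_problem.current_tag = ("phi",) + self._phi_tag()[1:]
        phi_next, terminate, info = p2.phi_adapt_step(
            self.phi_problem, mean_bg, self.phi_bounds, p2cfg
        )
        info["selected"] = self.phi_name
        info["sensitivities"] = self.phi_deltas
        info["rate_limit"] = p2cfg.lambda_phi
        if phi_next != self.params.controller.value(self.phi_name):
            self.params = ParamsUsed(
                basal=self.params.basal,
                carb_ratio=self.params.carb_ratio,
                controller=self.params.controller.with_value(self.phi_name, phi_next),
            )
        if terminate:
            self.phase = "done"
            info["terminated"] = True
        return _jsonable(info)


def _params_dict(params: ParamsUsed) -> dict:
    cp = params.controller
    return {
        "basal": list(params.basal.values),
        "carb_ratio": list(params.carb_ratio.values),
        "r_hat": cp.r_hat,
        "d_bar": cp.d_bar,
        "gamma_iob": cp.gamma_iob,
        "isf_est": cp.isf_est,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


# ---------------------------------------------------------------------------
# Scenario runner

def run_scenario(
    cohort: Sequence[VirtualPatient],
    scenario: ScenarioConfig,
    phase1_config: Phase1Config | None = None,
    phase2_config: Phase2Config | None = None,
) -> StudyLedger:
    """Run the full multi-week adaptation study for every patient.

    Fully reproducible from (cohort, scenario config, seed): each
    (patient, week) pair draws from its own deterministic random stream.
    """
    p1cfg = phase1_config or Phase1Config()
    p2cfg = phase2_config or Phase2Config()
    ledger = StudyLedger(scenario=_scenario_dict(scenario))
    for patient in cohort:
        adapt = _PatientAdaptation(patient, scenario, p1cfg, p2cfg)
        carry = None
        for k in range(1, scenario.weeks + 1):
            week = run_week(
                patient, adapt.params, scenario, k,
                week_rng(scenario.seed, patient.id, k), carry,
            )
            carry = week.carry_out
            record = adapt.observe_and_adapt(week, is_last=(k == scenario.weeks))
            ledger.records.append(_jsonable(record))
    return ledger


def _scenario_dict(scenario: ScenarioConfig) -> dict:
    d = asdict(scenario)
    d["meal_means"] = list(scenario.meal_means)
    d["meal_sds"] = list(scenario.meal_sds)
    d["meal_windows"] = [list(w) for w in scenario.meal_windows]
    return d


# ---------------------------------------------------------------------------
# Constraint audit

def audit_ledger(ledger: StudyLedger, tol: float = 1e-9) -> list[str]:
    """Re-check every accepted iterate against its safety constraints.

    Recomputes, from the records alone: the BR smoothness clip and the
    statistical IOB acceptance (including the 0.95 fallback), the CR rate
    bound, dynamic lower bound and surrogate change band, and the Phase-II
    rate and box bounds.  Also verifies that the IOB triple database only
    grows and the CR lower bounds never decrease.  Returns a list of
    violation descriptions (empty when clean).
    """
    violations: list[str] = []
    last_db: dict[tuple, int] = {}
    last_gbar: dict[tuple, float] = {}
    for r in ledger.records:
        tag = f"patient {r['patient']} week {r['week']}"
        # database monotonicity
        for seg, size in r.get("db_sizes", {}).items():
            key = (r["patient"], seg)
            if size < last_db.get(key, 0):
                violations.append(f"{tag}: IOB db for segment {seg} shrank")
            last_db[key] = size
        for seg, gb in r.get("cr_lower_bounds", {}).items():
            key = (r["patient"], seg)
            if gb < last_gbar.get(key, -math.inf) - tol:
                violations.append(f"{tag}: CR lower bound for segment {seg} decreased")
            last_gbar[key] = gb

        bru = r.get("br_update")
        if bru:
            prev = bru["beta_prev"]
            bar = bru["beta_bar"]
            new = bru["beta_new"]
            lam = bru["lambda_s_beta"]
            nseg = len(prev)
            for n in range(nseg):
                nm, np_ = (n - 1) % nseg, (n + 1) % nseg
                cap = lam * min(bar[nm], bar[np_], prev[nm], prev[np_])
                expect = min(bar[n], cap)
                if abs(new[n] - expect) > tol:
                    violations.append(f"{tag}: smoothness clip mismatch seg {n}")
            for seg_audit in bru["segments"]:
                n = seg_audit["segment"]
                if seg_audit.get("iob_checked"):
                    cand = seg_audit["iob_candidate"]
                    db = [(t[0], t[1], tuple(t[2])) for t in seg_audit["iob_db"]]
                    got = p1.iob_safety_check(
                        (cand[0], cand[1], tuple(cand[2])), db, prev[n]
                    )
                    if abs(got - bar[n]) > tol:
                        violations.append(f"{tag}: IOB check mismatch seg {n}")
                    if seg_audit.get("iob_rejected") and abs(bar[n] - 0.95 * prev[n]) > tol:
                        violations.append(f"{tag}: IOB fallback not 0.95x seg {n}")

        cru = r.get("cr_update")
        if cru:
            for seg, info in cru.items():
                gp = info.get("gamma_prev", info.get("psi_prev"))
                gn = info.get("gamma_next", info.get("psi_next"))
                if gp is None or gn is None:
                    continue
                lam = info.get("rate_limit", 0.30)
                if abs(gn - gp) > lam * gp + tol:
                    violations.append(f"{tag}: CR rate bound violated seg {seg}")
                gbar = info.get("gamma_bar", 0.0)
                if info.get("branch") not in ("infeasible_lower_bound",) and gn < gbar - tol:
                    violations.append(f"{tag}: CR lower bound violated seg {seg}")
                theta = info.get("theta")
                cand = info.get("candidate")
                if (
                    theta
                    and cand is not None
                    and info.get("branch") == "surrogate"
                    and "y_prev" in info
                ):
                    # the band constrains the surrogate-chosen candidate; the
                    # consistency fallback and safety truncation may override
                    yhat = theta[0] * cand + theta[1]
                    if abs(yhat - info["y_prev"]) > 12.0 + 1e-6:
                        violations.append(f"{tag}: CR surrogate band violated seg {seg}")

        phu = r.get("phi_update")
        if phu and "psi_prev" in phu and "psi_next" in phu:
            pp, pn = phu["psi_prev"], phu["psi_next"]
            lam = phu.get("rate_limit", 0.30)
            if abs(pn - pp) > lam * pp + tol:
                violations.append(f"{tag}: phi rate bound violated")
            b = phu.get("bounds")
            if b:
                lo = -math.inf if b[0] == "-inf" else float(b[0])
                hi = math.inf if b[1] == "inf" else float(b[1])
                if lo <= hi and not (lo - tol <= pn <= hi + tol):
                    if phu.get("branch") != "infeasible_bounds":
                        violations.append(f"{tag}: phi bound violated")
    return violations


# ---------------------------------------------------------------------------
# Fixed-protocol single-patient report

FIXED_PROTOCOL_MEALS: tuple[tuple[int, float], ...] = ((480, 50.0), (720, 75.0), (1140, 75.0))


def single_patient_profile_report(
    patient: VirtualPatient,
    snapshots: Sequence[tuple[str, ParamsUsed]],
    protocol_meals: Sequence[tuple[int, float]] = FIXED_PROTOCOL_MEALS,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-simulate a fixed 24-h meal protocol under several parameter
    snapshots with the same sensor-noise sequence.

    Mirrors the intra-patient before/after comparison: a 50 g breakfast at
    08:00 and 75 g lunch/dinner at 12:00/19:00, identical noise across
    snapshots, one row per 5-min step per snapshot.
    """
    from .cohort import (
        DayDisturbances,
        SicknessState,
        _simulate_day,
        sample_cgm_noise_day,
    )
    from .control import IOBTracker
    from .metabolism import steady_fasting_state

    rng = np.random.default_rng(np.random.SeedSequence([seed, patient.id]))
    noise = sample_cgm_noise_day(rng)
    frames = []
    for label, params in snapshots:
        dist = DayDisturbances(
            meals=[(t, g) for t, g in protocol_meals],
            sickness_flag=False,
            sick_factor=1.0,
            sensitivity_offset=0.0,
            sickness=SicknessState(),
        )
        day, _ = _simulate_day(
            patient, params, steady_fasting_state(patient, 0.0), dist, noise,
            IOBTracker(), [], 0.0, feedback_enabled=True,
        )
        n = len(day.cgm)
        frames.append(
            pd.DataFrame(
                {
                    "snapshot": label,
                    "time_min": np.arange(n) * 5,
                    "cgm": day.cgm,
                    "true_glucose": day.true_glucose,
                    "dose_basal": day.dose_basal,
                    "dose_feedback": day.dose_feedback,
                    "dose_bolus": day.dose_bolus,
                    "meal_g": day.meal_g,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def params_from_record(record: dict) -> ParamsUsed:
    """Rebuild a ParamsUsed from a ledger record's parameter dict."""
    p = record["params"]
    return ParamsUsed(
        basal=BasalProfile(tuple(p["basal"])),
        carb_ratio=CarbRatioProfile(tuple(p["carb_ratio"])),
        controller=ControllerParams(
            r_hat=p["r_hat"], d_bar=p["d_bar"], gamma_iob=p["gamma_iob"],
            isf_est=p.get("isf_est", 40.0),
        ),
    )


def build_cohort(n_patients: int, seed: int) -> list[VirtualPatient]:
    """Convenience re-export of the cohort generator."""
    return generate_cohort(n_patients, seed)
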