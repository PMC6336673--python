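"""Phase I: non-meal delivery sets, BR estimation, safety constraints,
CR zone adaptation and the alternating scheduler."""

import math

import numpy as np
import pytest

from apadapt.bo import BOProblem
from apadapt.cohort import DayLog, MealRecord, ParamsUsed, WeekLog
from apadapt.control import BasalProfile, CarbRatioProfile, ControllerParams
from apadapt.phase1 import (
    CRLowerBounds,
    IOBTripleDB,
    Phase1Config,
    Phase1State,
    attribute_low_glucose_events,
    br_estimate,
    cr_adapt_step,
    inv_gamma_vector,
    iob_safety_check,
    nonmeal_delivery_set,
    phase1_schedule,
    postprandial_mean,
    smoothness_clip,
)

CFG = Phase1Config()


def make_day(meal_times=(), dose=0.1, cgm_value=140.0, grams=50.0, events=()):
    n = 288
    cgm = np.full(n, float(cgm_value))
    doses = np.full(n, float(dose))
    meal_g = np.zeros(n)
    meals = []
    for t in meal_times:
        meal_g[t // 5] = grams
        meals.append(MealRecord(time=t, grams=grams, bolus=grams / 10.0))
    return DayLog(
        cgm=cgm,
        true_glucose=cgm.copy(),
        dose_basal=doses,
        dose_feedback=np.zeros(n),
        dose_bolus=np.zeros(n),
        meal_g=meal_g,
        meals=meals,
        sickness_flag=False,
        sensitivity_offset=0.0,
        low_glucose_events=list(events),
    )


def make_week(days, basal=None, cr=None):
    params = ParamsUsed(
        basal=basal or BasalProfile((1.0,) * 5),
        carb_ratio=cr or CarbRatioProfile((10.0,) * 4),
        controller=ControllerParams(),
    )
    return WeekLog(iteration_index=1, patient_id=0, days=days, parameters_used=params)


def minutes(hh, mm=0):
    return hh * 60 + mm


class TestNonmealDeliverySet:
    def test_premeal_doses_qualify_postmeal_excluded(self):
        week = make_week([make_day(meal_times=[minutes(8)])] )
        times = {t for _, t, _ in nonmeal_delivery_set(week, 1, CFG)}  # [05,10)
        assert times == set(range(minutes(5), minutes(8), 5))

    def test_no_meals_all_doses_qualify(self):
        week = make_week([make_day()])
        records = nonmeal_delivery_set(week, 1, CFG)
        assert len(records) == (minutes(10) - minutes(5)) // 5

    def test_exclusion_window_crosses_segment_boundary(self):
        week = make_week([make_day(meal_times=[minutes(9, 30)])])
        times = {t for _, t, _ in nonmeal_delivery_set(week, 2, CFG)}  # [10,16)
        # excluded until 09:30 + 3 h = 12:30
        assert times == set(range(minutes(12, 30), minutes(16), 5))

    def test_wraparound_segment_collects_late_and_early_doses(self):
        week = make_week([make_day(meal_times=[minutes(19)])])
        times = {t for _, t, _ in nonmeal_delivery_set(week, 4, CFG)}  # [21,02)
        expected = set(range(minutes(22), minutes(24), 5)) | set(range(0, minutes(2), 5))
        assert times == expected


class TestBREstimate:
    def test_constant_microboluses_convert_to_rate(self):
        week = make_week([make_day(dose=0.10)])
        assert br_estimate(week, 0, CFG) == pytest.approx(1.2)

    def test_arithmetic_mean_of_unequal_doses(self):
        day = make_day(dose=0.10)
        seg_steps = range(minutes(2) // 5, minutes(5) // 5)
        pattern = [0.05, 0.10, 0.15]
        for i, s in enumerate(seg_steps):
            day.dose_basal[s] = pattern[i % 3]
        week = make_week([day])
        assert br_estimate(week, 0, CFG) == pytest.approx(1.2)

    def test_empty_qualifying_set_signals_skip(self):
        # meals at the very start of every window of the day
        day = make_day(meal_times=[0, minutes(3), minutes(6), minutes(9),
                                   minutes(12), minutes(15)])
        week = make_week([day])
        assert br_estimate(week, 2, CFG) is None


class TestIOBSafetyCheck:
    def test_empty_database_accepts_candidate(self):
        assert iob_safety_check((1.0, 1.5, (0.1,)), [], beta_prev=1.0) == 1.5

    def test_dominated_candidate_accepted(self):
        db = [(2.0, 1.2, (0.10,))]
        got = iob_safety_check((1.5, 1.0, (0.0833,)), db, beta_prev=0.9)
        assert got == 1.0

    def test_violating_candidate_cut_to_95_percent(self):
        db = [(2.0, 1.2, (0.10,))]
        got = iob_safety_check((2.5, 1.0, (0.0833,)), db, beta_prev=0.9)
        assert got == pytest.approx(0.855)

    def test_beta_bar_component_checked_against_095_beta(self):
        db = [(2.0, 1.2, (0.10,))]
        # 1.15 > 0.95*1.2 = 1.14 violates even though IOB and 1/gamma pass
        got = iob_safety_check((1.5, 1.15, (0.0833,)), db, beta_prev=1.0)
        assert got == pytest.approx(0.95)

    def test_all_mode_requires_every_triple(self):
        db = [(2.0, 1.2, (0.10,)), (1.0, 1.2, (0.10,))]
        got = iob_safety_check((1.5, 1.0, (0.0833,)), db, beta_prev=0.9)
        assert got == pytest.approx(0.855)  # violates the second triple

    def test_dominating_mode_rejects_only_dominating(self):
        db = [(2.0, 1.2, (0.10,)), (1.0, 1.2, (0.10,))]
        got = iob_safety_check((1.5, 1.0, (0.0833,)), db, 0.9, mode="dominating")
        assert got == 1.0

    def test_dimension_mismatch_raises(self):
        db = [(2.0, 1.2, (0.10, 0.05))]
        with pytest.raises(ValueError):
            iob_safety_check((1.5, 1.0, (0.0833,)), db, 1.0)


class TestSmoothnessClip:
    def test_constant_profile_is_fixed_point(self):
        out = smoothness_clip([0.8] * 5, [0.8] * 5, CFG)
        assert out == tuple([0.8] * 5)

    def test_spike_clipped_to_lambda_times_smallest_neighbor(self):
        beta_bar = [0.8, 2.0, 0.8, 0.9, 0.9]
        beta_prev = [0.9, 1.0, 0.9, 0.9, 0.9]
        out = smoothness_clip(beta_bar, beta_prev, CFG)
        assert out[1] == pytest.approx(1.3 * 0.8)  # min(2.0, 1.3*0.8) = 1.04

    def test_first_segment_neighbors_wrap(self):
        beta_bar = [2.0, 1.0, 1.0, 1.0, 0.5]
        beta_prev = [1.0, 1.0, 1.0, 1.0, 1.0]
        out = smoothness_clip(beta_bar, beta_prev, CFG)
        assert out[0] == pytest.approx(1.3 * 0.5)  # neighbor 5 limits segment 1

    def test_decreases_never_clipped(self):
        out = smoothness_clip([0.5, 1.0, 1.0, 1.0, 1.0], [1.0] * 5, CFG)
        assert out[0] == 0.5

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            smoothness_clip([1.0] * 5, [1.0] * 4, CFG)


class TestPostprandialMean:
    def test_constant_trace_returns_constant(self):
        week = make_week([make_day(meal_times=[minutes(8)], cgm_value=140.0)])
        assert postprandial_mean(week, 0, CFG) == pytest.approx(140.0)

    def test_window_truncated_at_next_meal(self):
        day = make_day(meal_times=[minutes(12), minutes(14)], cgm_value=150.0)
        # window for the 12:00 meal covers [12:00, 14:00): give it 130,
        # everything after 160
        day.cgm[:] = 160.0
        day.cgm[minutes(12) // 5 : minutes(14) // 5] = 130.0
        week = make_week([day])
        # lunch segment [10:00, 16:00): both meals inside; 14:00 meal window
        # runs 4 h -> [14:00, 18:00) at 160
        y = postprandial_mean(week, 1, CFG)
        pooled = (24 * 130.0 + 48 * 160.0) / 72
        assert y == pytest.approx(pooled)

    def test_two_equal_windows_pool_to_midpoint(self):
        d1 = make_day(meal_times=[minutes(12)], cgm_value=130.0)
        d2 = make_day(meal_times=[minutes(12)], cgm_value=150.0)
        week = make_week([d1, d2])
        assert postprandial_mean(week, 1, CFG) == pytest.approx(140.0)

    def test_no_matching_meal_returns_none(self):
        week = make_week([make_day(meal_times=[minutes(12)])])
        assert postprandial_mean(week, 0, CFG) is None  # breakfast segment


def make_cr_problem(gamma, zone=(125.0, 155.0), data=(), tag="env"):
    problem = BOProblem(
        psi=gamma,
        delta=CFG.delta_y_gamma,
        objective_sign=+1,
        zone=zone,
        rate_limit=CFG.lambda_gamma,
        current_tag=tag,
    )
    for psi, y in data:
        problem.record(psi, y, tag)
    return problem


class TestCRAdaptStep:
    def test_in_zone_holds_with_met_flag(self):
        problem = make_cr_problem(10.0)
        gamma, info = cr_adapt_step(problem, 140.0, 0.0, CFG)
        assert gamma == 10.0
        assert info["met"] is True

    def test_heuristic_step_down_when_above_zone(self):
        problem = make_cr_problem(10.0)
        gamma, info = cr_adapt_step(problem, 170.0, 0.0, CFG)
        assert gamma == pytest.approx(9.0)
        assert info["branch"] == "heuristic"

    def test_heuristic_step_up_when_below_zone(self):
        problem = make_cr_problem(10.0)
        gamma, _ = cr_adapt_step(problem, 110.0, 0.0, CFG)
        assert gamma == pytest.approx(11.0)

    def test_surrogate_step_clipped_by_rate_bound(self):
        # noiseless line y = 3*gamma + 130: surrogate would go to the band
        # edge at gamma = 6, but the 30% rate bound stops it at 7.0
        data = [(12.0, 166.0), (11.0, 163.0), (10.5, 161.5), (10.0, 160.0)]
        problem = make_cr_problem(10.0, data=data)
        gamma, info = cr_adapt_step(problem, 160.0, 0.0, CFG)
        assert info["branch"] == "surrogate"
        assert gamma == pytest.approx(7.0)

    def test_dynamic_lower_bound_projects_candidate(self):
        data = [(12.0, 166.0), (11.0, 163.0), (10.5, 161.5), (10.0, 160.0)]
        problem = make_cr_problem(10.0, data=data)
        gamma, _ = cr_adapt_step(problem, 160.0, 9.5, CFG)
        assert gamma == pytest.approx(9.5)

    def test_infeasible_lower_bound_holds_and_flags(self):
        problem = make_cr_problem(10.0)
        gamma, info = cr_adapt_step(problem, 170.0, 14.0, CFG)
        assert gamma == 10.0
        assert info["flag"] == "hold"


class TestScheduler:
    def test_fresh_state_adapts_br_first(self):
        action, state = phase1_schedule(Phase1State(), zones_met=False)
        assert action == "adapt_BR"
        assert state.br_done == 1

    def test_br_block_has_length_two_then_cr(self):
        state = Phase1State()
        actions = []
        for _ in range(3):
            action, state = phase1_schedule(state, zones_met=False)
            actions.append(action)
        assert actions == ["adapt_BR", "adapt_BR", "adapt_CR"]

    def test_zones_met_after_br_block_terminates(self):
        state = Phase1State(mode="BR", br_done=2)
        action, state = phase1_schedule(state, zones_met=True)
        assert action == "terminate_phase1"
        assert state.finished

    def test_cr_block_ends_early_on_zone_success(self):
        state = Phase1State(mode="CR", cr_done=2)
        action, state = phase1_schedule(state, zones_met=True)
        assert action == "adapt_BR"
        assert state.mode == "BR"

    def test_cr_block_capped_at_n_gamma(self):
        state = Phase1State(mode="CR", cr_done=5)
        action, state = phase1_schedule(state, zones_met=False)
        assert action == "adapt_BR"

    def test_full_alternation_one_family_per_week(self):
        state = Phase1State()
        actions = []
        for _ in range(16):
            action, state = phase1_schedule(state, zones_met=False)
            actions.append(action)
        assert actions == (
            ["adapt_BR"] * 2 + ["adapt_CR"] * 5 + ["adapt_BR"] * 2
            + ["adapt_CR"] * 5 + ["adapt_BR"] * 2
        )


class TestDatabases:
    def test_iob_db_only_grows(self):
        db = IOBTripleDB()
        db.add(0, 1.0, 1.2, (0.1,))
        db.add(0, 0.5, 1.0, (0.1,))
        assert db.size(0) == 2

    def test_cr_lower_bounds_nondecreasing(self):
        bounds = CRLowerBounds()
        bounds.update(0, 9.0)
        bounds.update(0, 8.0)
        assert bounds.get(0) == 9.0
        bounds.update(0, 9.5)
        assert bounds.get(0) == 9.5

    def test_inv_gamma_vector_uses_overlapping_segments(self):
        cr_vals = (10.0, 12.5, 8.0, 20.0)
        assert inv_gamma_vector(cr_vals, 1) == (0.1,)      # [05,10) -> breakfast
        assert inv_gamma_vector(cr_vals, 0) == (0.05,)     # [02,05) -> overnight


class TestAttribution:
    def test_event_charged_to_active_br_segment(self):
        day = make_day(events=[(minutes(3), 20.0)])
        week = make_week([day])
        br_hits, cr_hits = attribute_low_glucose_events(week, CFG)
        assert br_hits == {0}
        assert cr_hits == set()

    def test_postprandial_event_also_charges_cr_segment(self):
        day = make_day(meal_times=[minutes(12)], events=[(minutes(14), 20.0)])
        week = make_week([day])
        br_hits, cr_hits = attribute_low_glucose_events(week, CFG)
        assert 2 in br_hits  # [10,16)
        assert cr_hits == {1}

    def test_event_long_after_meal_spares_cr(self):
        day = make_day(meal_times=[minutes(8)], events=[(minutes(13), 20.0)])
        week = make_week([day])
        _, cr_hits = attribute_low_glucose_events(week, CFG)
        assert cr_hits == set()
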