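# Methods

This note documents the models, algorithms and design choices behind
`apadapt`: what is simulated, what is adapted, which constants matter, and
what the desk-scale experiments do and do not demonstrate.

## Surrogate patient model

Each virtual patient is a seven-state ODE advanced with 1-minute Euler
substeps on a 5-minute dosing/sensing grid:

    q1' = -ka*q1 + delivered insulin      (subcutaneous depot, U)
    q2' =  ka*(q1 - q2)
    x'  =  p2*(ka*q2 - x)                 (insulin action, U/min)
    d1' = -kc*d1 + ingested carbs         (gut, g)
    d2' =  kc*(d1 - d2)
    g'  =  EGP(t) - sg*g - si(t)*x + k_carb*kc*d2

with per-patient constants drawn once from a seeded generator:

| parameter | range / definition | meaning |
|---|---|---|
| weight | U(55, 95) kg | body mass |
| TDI | weight · U(0.45, 0.75) U/day | total daily insulin; sets all clinical scales |
| `insulin_sensitivity_base` | 1800/TDI mg/dl per U | correction factor (trough of a 1-U bolus) |
| `cr_base` | 500/TDI g/U | integral-matched carb ratio |
| 1/ka | U(30, 42) min | SC absorption time constant |
| 1/p2 | U(15, 25) min | action filter time constant |
| 1/kc | U(34, 46) min | gut absorption time constant |
| sg | U(0.0030, 0.0042) /min | glucose effectiveness |
| g_target | U(105, 125) mg/dl | fasting set point |
| diurnal amplitude | U(0.08, 0.22), random phase | 24-h sinusoid on si(t), clipped to [0.5, 2] |
| dawn amplitude | U(0.15, 0.30) | fractional EGP rise in the early morning |

The ODE's integral sensitivity is `si = insulin_sensitivity_base / 0.60`;
the constant 0.60 is the fraction of a bolus's integrated effect realized at
the glucose trough for this compartment chain, measured once on the
calibrated kinetics so that a 1-U bolus dips glucose by approximately the
clinical correction factor (cohort mean within 15%). `EGP0` is derived from
the steady-state balance at `g_target` under the patient's mean basal need,
and `k_carb = si / cr_base`, so the 500-rule bolus cancels a meal's
integrated glucose appearance. A glucagon-like counter-regulatory term adds
`0.04 * (80 - g)` mg/dl/min below 80 mg/dl, bounding hypoglycemia depth the
way a real patient's counter-regulation (and carbohydrate rescue) would.

### Ground truth for recovery tests

* **True basal need** `60*(EGP(t+L) - sg*g_target)/si(t+L)` with
  `L = 2/ka + 1/p2` (the mean delivery-to-action lag): insulin infused now
  serves the demand it will meet one lag later. Under this profile,
  open-loop fasting glucose stays within [90, 160] mg/dl for every patient
  (typically ±12 mg/dl around the set point) — the calibration invariant.
* **Dawn placement.** The EGP dawn window is positioned one action-lag
  after the canonical [04:00, 08:00) interval, so the *need* rise spans
  [04:00, 08:00) and falls mostly inside the 05:00–10:00 basal segment,
  making that segment the largest — the expected clinical pattern. A
  reactive controller can then attribute its dawn corrections to the right
  segment.
* **True carb ratio** is the integral match relaxed by a factor 1.25.
  An exactly integral-matched bolus undershoots late (insulin action lags
  gut absorption), so the clinically settled ratio is more conservative;
  1.25 places truth-profile postprandial means at the upper edge of the
  target zones with essentially zero hypoglycemia.

### Disturbance protocol

Per day: three meals, N(50,3²)/N(75,4²)/N(75,4²) g CHO, times uniform on
[07:00–09:00]/[11:00–13:00]/[18:00–20:00] snapped to the 5-min grid, each
independently skipped with probability 0.1; inter-day sensitivity noise
uniform ±5% (applied to si and the dawn amplitude); a 5% daily chance of
starting a sickness episode of uniform 1–5 days that multiplies si and the
dawn amplitude by 1.5 or 0.5 (coin flip; a literal mode replacing 0.5 by
0.0 — fully insulin-resistant — is available via `sickness_literal`, since
"decrease by 100%" admits that degenerate reading). Sensor noise is AR(1)
per 5-min step with stationary sd 7 mg/dl and correlation 0.7, re-drawn
each day, readings clipped to [40, 400] mg/dl. All draws flow through one
`numpy` generator per (patient, week) in a fixed order, so studies are
bit-reproducible from (config, seed).

### What the surrogate does not emulate

No exercise, stress or alcohol; no pump quantization, occlusions or sensor
dropout; no meal-absorption variability beyond size/timing; sickness as a
pure sensitivity scaling; a single linear glucose compartment (no renal
threshold, no nonlinear utilization). Passing results show the *adaptation
machinery* behaves as designed against a plausible metabolic system — not
that it is clinically validated.

## Lower-layer controller

The feedback law is a deliberately minimal zone MPC. Glucose is predicted
9 steps (45 min) ahead from the last CGM reading plus a least-squares trend
over 30 min, damped by 0.9 per step; one above-basal adjustment, held over
the 5-step control horizon (move blocking), minimizes

    sum_j w_j (g_j - target_j)^2 + r_hat * R0 * (1 + brake) * u^2

where per-step weights are 0 inside the [80, 160] mg/dl zone, 1 above and
10 below (asymmetry against lows), `R0 = 7000`, and the velocity brake
`0.05 * max(0, d_bar - g_min)` activates only for above-basal dosing while
glucose is falling below `d_bar` (nominal 140 mg/dl). The scalar minimizer
is closed-form, then clipped to the insulin-on-board cap

    u <= max(0, gamma_iob * (cgm - 110)/ISF - IOB)

with IOB the 4-h linear decay of deliveries above the scheduled basal.
Delivery suspends outright below 70 mg/dl or when the 45-min trend
projection falls below 75 mg/dl (a predictive low-glucose suspend, standard
in commercial systems). The closed form makes the dosing contracts exact:
monotone nonincreasing above-basal dose in `r_hat`, monotone nondecreasing
in `gamma_iob`, basal delivery at rest inside the zone.

The controller's gain `ISF` comes from the 1800 rule. It is programmed
initially from the (possibly wrong) basal profile and re-personalized once
from the *delivered* total daily insulin of the data-collection week —
without this, a doubled initial profile yields a doubly aggressive
controller whose corrections themselves cause hypoglycemia, and a halved
one yields a controller too weak to reveal the missing basal.

Meal boluses are `grams/γ(t)` plus a correction `(cgm - 150)/ISF` when
above 150 mg/dl, discounted by insulin on board.

## Phase I

* **Basal estimate (per segment).** Mean of all per-step deliveries inside
  the segment's hours that fall ≥ 3 h after the previous consumed meal of
  the day (pre-first-meal deliveries qualify), × 12 to U/hr. An empty
  qualifying set skips the segment.
* **Statistical IOB constraint.** Applied only to proposed increases. The
  candidate triple is (mean IOB over the 15 min before the segment start,
  averaged over the week; proposed basal; 1/γ for the CR segments whose
  hours overlap the basal segment's). The literal universal-domination
  reading is the default (`iob_reject_mode="all"`); a
  reject-only-if-dominating mode is available, since the universal reading
  is very conservative once stored triples are heterogeneous. Rejection
  cuts the segment to 0.95× its current value.
* **Smoothness.** `β_n ← min(β̄_n, 1.3·min(β̄_{n−}, β̄_{n+}, β_{n−}, β_{n+}))`
  with circular neighbors.
* **Postprandial measurement.** Pooled CGM mean over [meal, meal +
  min(4 h, gap to next meal)) windows (clipped at midnight), per CR
  segment, across the week.
* **Hypoglycemia attribution.** An event (CGM < 70 mg/dl sustained
  ≥ 15 min) charges the basal segment active at its start, and charges a CR
  segment when it starts within 4 h of a consumed meal in that segment —
  feeding the IOB database and the γ̄ lower bounds respectively. Dual
  attribution is deliberate: the data cannot distinguish the cause, so both
  safety nets tighten.
* **Scheduling.** Week 1 collects data (and personalizes the controller
  gain); adaptation starts at week 2 with a basal block of 2, then CR
  blocks of up to 5 iterations ending early when all measured segments sit
  in their zones; Phase I ends when the zones still hold immediately after
  a basal block. Exactly one family changes per week. Segments without a
  measurement that week retain their value.

## Phase II

Advisory replay recomputes the controller's commands over the recorded CGM
of the most recent week (open loop; glucose is not re-simulated) with IOB
rebuilt from the replayed commands plus recorded meal boluses; with the
recorded parameters it reproduces the recorded basal+feedback insulin
exactly. Selection takes the knob with the largest |ℐ(φ⁺) − ℐ(φ⁻)| —
the *strongest* controllability, which we take as the intended reading of
the selection rule; the literal arg-min variant is selectable
(`selection_rule="min_sensitivity"`). Ties break in the fixed order R̂, D̄,
γ_IOB.

The selected knob then steps weekly toward mean CGM < 135 mg/dl through the
safe optimizer, within its static box and dynamic bounds that move to
exclude a value (and everything more insulin-aggressive) once a week run
under it produces a low-glucose event. "More aggressive" is lower R̂,
*lower* D̄ (a larger D̄ widens the velocity-brake region and so delivers
less), and higher γ_IOB. Adaptation ends at the target, at an active bound,
or on an empty feasible interval; parameters then freeze.

## Safe optimizer

One scalar per problem. The admissible set contains past iterations whose
recorded environment (the frozen values of every other adaptation
parameter) matches the current one, and whose week followed an adaptation
of the same family. With ≤ `n_BO` admissible points the step is
`ψ ← (1 ± 0.10)ψ` along the known direction; otherwise an OLS line is
fitted to the admissible (ψ, y) pairs and minimized subject to
`|ŷ(ψ) − y_prev| ≤ δ` (δ = 12 mg/dl for carb ratios, 6 for feedback knobs)
and the interval constraints (rate bound, boxes, dynamic bounds) — a linear
program whose solution is an interval vertex. A step whose sign disagrees
with the search direction (no-move counts as disagreement when a move is
demanded) is replaced by the heuristic step; every emitted value is finally
projected into the feasible intersection. A zero fitted slope holds
position. The engine is deterministic; all randomness lives in the
measurements.

`n_BO = 3` (surrogate trusted from the 4th same-environment point). With
weekly measurements noisy at the 10–15 mg/dl level, lines through 3 points
over a ≤30% parameter range routinely underestimate the slope, which widens
the measurement-change band and lets the full 30% rate step through —
observed to cause 60–90 mg/dl postprandial overshoots and hypoglycemia
bursts in development runs. One extra point suppresses most of these at a
negligible cost in adaptation speed (the fixed ±10% steps dominate early
progress anyway).

## Numerical and convention choices

Clock times in minutes from midnight on a 5-min grid; intervals half-open
[start, end), wrapping across midnight; a boundary instant belongs to the
opening segment. Basal segments [02,05)[05,10)[10,16)[16,21)[21,02) U/hr;
CR segments [05,10)[10,16)[16,21)[21,05) g/U with the overnight segment
never adapted (and never perturbed by scenario initialization, matching its
role as a clinician-fixed default). Euler integration at 1-min substeps
(the stiffest time constant is ≥ 15 min); glucose floored at 15 mg/dl;
non-finite states raise. Audit comparisons use absolute tolerance 1e-9.
Quartiles use linear interpolation; the Wilcoxon signed-rank test is
two-sided with zero differences dropped (exact for small n via scipy);
all-zero differences report p = 1 with a zero-variance flag.

## Desk-scale experiment sizes and limitations

The shipped studies use 10-patient cohorts over 24 weekly iterations
(≈ 0.5 M controller decisions per study, seconds of runtime), with seed 0 as
the package-wide default. At this cohort size weekly medians carry visible
sampling noise (sickness alone moves a patient-week's mean by tens of
mg/dl), so week-over-week median trends are not monotone the way a
100+-patient cohort's would be; the acceptance checks therefore compare
first-versus-final weeks and bound the weekly hypoglycemia medians rather
than asserting monotone trajectories. On occasional cohort draws the
Scenario I weekly median time-below-70 can graze ~1% during mid-study
carb-ratio overshoot episodes before the dynamic bounds lock in. In
Scenario II, week-1 hypoglycemia (basal-driven, but within 4 h of meals)
also ratchets the CR lower bounds at their doubled initial values; the CR
profile then stays conservative and the study trades residual
hyperglycemia for a guaranteed absence of lows — time below 70 mg/dl
reaches 0.0% by week 3 and stays there, which is the headline safety
outcome, while time-in-range gains are mostly confined to Scenario I/III
conditions. Phase II engages only for patients whose zones are stably met
after a basal block; for many patients Phase I termination arrives late or
not at all within 24 weeks, which matches the conservative, safety-first
intent of the alternating scheduler.
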