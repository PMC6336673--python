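"""Serialization: WeekLog CSV + parameter sidecars, scenario YAML."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ParamsUsed, ScenarioConfig, WeekLog
from .control import BasalProfile, CarbRatioProfile, ControllerParams
from .timeutil import STEP_MIN


def week_to_frame(week: WeekLog) -> pd.DataFrame:
    """One row per 5-min step: day, time, cgm, dose components, meal, sick."""
    rows = []
    for di, day in enumerate(week.days):
        n = len(day.cgm)
        rows.append(
            pd.DataFrame(
                {
                    "day": di,
                    "time_min": np.arange(n) * STEP_MIN,
                    "cgm": day.cgm,
                    "dose_basal": day.dose_basal,
                    "dose_feedback": day.dose_feedback,
                    "dose_bolus": day.dose_bolus,
                    "meal_g": day.meal_g,
                    "sick": int(day.sickness_flag),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def params_to_dict(params: ParamsUsed) -> dict:
    cp = params.controller
    return {
        "basal": list(params.basal.values),
        "carb_ratio": list(params.carb_ratio.values),
        "controller": {
            "r_hat": cp.r_hat,
            "d_bar": cp.d_bar,
            "gamma_iob": cp.gamma_iob,
            "nominal_r_hat": cp.nominal_r_hat,
            "nominal_d_bar": cp.nominal_d_bar,
            "nominal_gamma_iob": cp.nominal_gamma_iob,
            "isf_est": cp.isf_est,
        },
    }


def params_from_dict(d: dict) -> ParamsUsed:
    c = d["controller"]
    return ParamsUsed(
        basal=BasalProfile(tuple(d["basal"])),
        carb_ratio=CarbRatioProfile(tuple(d["carb_ratio"])),
        controller=ControllerParams(**c),
    )


def write_week(week: WeekLog, csv_path, sidecar_path=None) -> None:
    """WeekLog as CSV plus a JSON sidecar with the parameters used."""
    csv_path = Path(csv_path)
    week_to_frame(week).to_csv(csv_path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".params.json")
    payload = {
        "iteration_index": week.iteration_index,
        "patient_id": week.patient_id,
        "parameters_used": params_to_dict(week.parameters_used),
    }
    sidecar.write_text(json.dumps(payload, indent=2))


def scenario_to_yaml(config: ScenarioConfig, path) -> None:
    from dataclasses import asdict

    d = asdict(config)
    d["meal_means"] = list(config.meal_means)
    d["meal_sds"] = list(config.meal_sds)
    d["meal_windows"] = [list(w) for w in config.meal_windows]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def scenario_from_yaml(path) -> ScenarioConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["meal_means"] = tuple(d["meal_means"])
    d["meal_sds"] = tuple(d["meal_sds"])
    d["meal_windows"] = tuple(tuple(w) for w in d["meal_windows"])
    return ScenarioConfig(**d)
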