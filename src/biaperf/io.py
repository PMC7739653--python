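"""CSV and YAML I/O for the analysis pipeline.

Three tables move between the simulator and the analysis:

* ``stages.csv`` — one row per submaximal stage:
  athlete_id, stage_index, speed_kmh, incline_deg, vo2_L_min, vco2_L_min,
  rer, lactate_mmol, hr, rpe, ve_L_min
* ``tt.csv`` — long format, one row per 10-s time-trial sample:
  athlete_id, distance_m, time_s, t_s, vo2_mL_kg_min
  (distance_m/time_s repeat within an athlete: the per-athlete summary)
* ``athletes.csv`` — roster plus field-competition result:
  athlete_id, sex, body_mass_kg, equipment_mass_kg, height_cm, age_yr,
  hr_max, bc_speed_m_s, total_ski_time_s

Protocol constants live in a small YAML file keyed by sex.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .cohort import CompetitionResult, SyntheticAthlete, TimeTrialRecord
from .energetics import SAMPLE_PERIOD_S
from .types import AthleteProfile, StageRecord, TreadmillProtocol

STAGE_COLUMNS = [
    "athlete_id", "stage_index", "speed_kmh", "incline_deg", "vo2_L_min",
    "vco2_L_min", "rer", "lactate_mmol", "hr", "rpe", "ve_L_min",
]
TT_COLUMNS = ["athlete_id", "distance_m", "time_s", "t_s", "vo2_mL_kg_min"]
ATHLETE_COLUMNS = [
    "athlete_id", "sex", "body_mass_kg", "equipment_mass_kg", "height_cm",
    "age_yr", "hr_max", "bc_speed_m_s", "total_ski_time_s",
]

_FLOAT_FMT = "%.10g"


def write_stage_csv(
    path: str | Path,
    stages_by_athlete: dict[str, Sequence[StageRecord]],
    incline_by_athlete: dict[str, float],
) -> None:
    rows = []
    for aid, stages in stages_by_athlete.items():
        for s in stages:
            rows.append(
                {
                    "athlete_id": aid,
                    "stage_index": s.stage_index,
                    "speed_kmh": s.speed_kmh,
                    "incline_deg": incline_by_athlete[aid],
                    "vo2_L_min": s.vo2_L_min,
                    "vco2_L_min": s.rer * s.vo2_L_min,
                    "rer": s.rer,
                    "lactate_mmol": s.lactate_mmol,
                    "hr": s.hr,
                    "rpe": s.rpe,
                    "ve_L_min": s.ve_L_min,
                }
            )
    pd.DataFrame(rows, columns=STAGE_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_stage_csv(path: str | Path) -> dict[str, list[StageRecord]]:
    df = _read_csv(path, STAGE_COLUMNS)
    out: dict[str, list[StageRecord]] = {}
    for aid, grp in df.groupby("athlete_id", sort=False):
        grp = grp.sort_values("stage_index")
        out[str(aid)] = [
            StageRecord(
                speed_kmh=float(r.speed_kmh),
                vo2_L_min=float(r.vo2_L_min),
                rer=float(r.rer),
                lactate_mmol=float(r.lactate_mmol),
                hr=float(r.hr),
                rpe=float(r.rpe),
                ve_L_min=float(r.ve_L_min),
                stage_index=int(r.stage_index),
            )
            for r in grp.itertuples()
        ]
    return out


def write_tt_csv(path: str | Path, records: Sequence[TimeTrialRecord]) -> None:
    rows = []
    for rec in records:
        for i, v in enumerate(rec.vo2_series_mL_kg_min):
            rows.append(
                {
                    "athlete_id": rec.athlete_id,
                    "distance_m": rec.distance_m,
                    "time_s": rec.time_s,
                    "t_s": (i + 1) * SAMPLE_PERIOD_S,
                    "vo2_mL_kg_min": v,
                }
            )
    pd.DataFrame(rows, columns=TT_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_tt_csv(path: str | Path) -> dict[str, TimeTrialRecord]:
    df = _read_csv(path, TT_COLUMNS)
    out: dict[str, TimeTrialRecord] = {}
    for aid, grp in df.groupby("athlete_id", sort=False):
        grp = grp.sort_values("t_s")
        out[str(aid)] = TimeTrialRecord(
            athlete_id=str(aid),
            distance_m=float(grp["distance_m"].iloc[0]),
            time_s=float(grp["time_s"].iloc[0]),
            vo2_series_mL_kg_min=tuple(float(v) for v in grp["vo2_mL_kg_min"]),
        )
    return out


def write_athletes_csv(
    path: str | Path,
    cohort: Sequence[SyntheticAthlete],
    competition: Sequence[CompetitionResult],
) -> None:
    comp = {c.athlete_id: c for c in competition}
    rows = []
    for ath in cohort:
        p = ath.profile
        c = comp[p.athlete_id]
        rows.append(
            {
                "athlete_id": p.athlete_id,
                "sex": p.sex,
                "body_mass_kg": p.body_mass_kg,
                "equipment_mass_kg": p.equipment_mass_kg,
                "height_cm": p.height_cm,
                "age_yr": p.age_yr,
                "hr_max": p.hr_max,
                "bc_speed_m_s": c.bc_speed_m_s,
                "total_ski_time_s": c.total_ski_time_s,
            }
        )
    pd.DataFrame(rows, columns=ATHLETE_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_athletes_csv(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ATHLETE_COLUMNS)
    df["athlete_id"] = df["athlete_id"].astype(str)
    return df


def athlete_profile_from_row(row) -> AthleteProfile:
    return AthleteProfile(
        athlete_id=str(row["athlete_id"]),
        sex=str(row["sex"]),
        body_mass_kg=float(row["body_mass_kg"]),
        equipment_mass_kg=float(row["equipment_mass_kg"]),
        height_cm=float(row["height_cm"]),
        age_yr=float(row["age_yr"]),
        hr_max=float(row["hr_max"]),
    )


def write_protocol_yaml(
    path: str | Path, protocols: dict[str, TreadmillProtocol]
) -> None:
    payload = {
        sex: {
            "incline_deg": p.incline_deg,
            "mu_R": p.mu_r,
            "g": p.g,
            "distance_m": p.distance_m,
            "start_speed_kmh": p.start_speed_kmh,
            "submax_start_speed_kmh": p.submax_start_speed_kmh,
            "submax_increment_kmh": p.submax_increment_kmh,
        }
        for sex, p in protocols.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_protocol_yaml(path: str | Path) -> dict[str, TreadmillProtocol]:
    payload = yaml.safe_load(Path(path).read_text())
    out = {}
    for sex, d in payload.items():
        out[sex] = TreadmillProtocol(
            incline_deg=float(d["incline_deg"]),
            mu_r=float(d["mu_R"]),
            g=float(d.get("g", 9.81)),
            distance_m=float(d["distance_m"]),
            start_speed_kmh=float(d["start_speed_kmh"]),
            submax_start_speed_kmh=float(d.get("submax_start_speed_kmh", 7.0)),
            submax_increment_kmh=float(d.get("submax_increment_kmh", 2.0)),
        )
    return out


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
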