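"""CSV and JSON-lines readers/writers for patient profiles and cohorts.

Column dictionary (one row per patient, dates ISO-8601):

====================== ==========================================================
column                 meaning
====================== ==========================================================
patient_id             opaque identifier
site_item_id           rubric site row id (e.g. ``prostate_sv_only``)
age                    integer years
retreatment            True/False -- re-irradiation of same/overlapping site
trial_level            randomized | interventional | registry | off_protocol
planning_constraint    none | primary | secondary | other
other_constraint_points integer, used only when planning_constraint = other
photon_unsafe          True/False -- photons unsafe, +5 bonus
risk_factors           ``;``-joined subset of SLE_scleroderma,IBD,other_genetic,HIV
misc_adjustment        signed integer (chairman-reviewed)
misc_annotation        reviewer annotation (required when misc_adjustment != 0)
insurance              medicare | other
sex                    male | female
race                   caucasian | african_american | other
evaluation_date        ISO date the patient was considered for proton therapy
====================== ==========================================================

Cohort files add: ``site_group``, ``cbs``, ``candidate``, ``received_pbt``.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Union

import pandas as pd

from .rubric import (
    Insurance,
    PatientProfile,
    PlanningConstraint,
    Race,
    Sex,
    TrialLevel,
)

PROFILE_COLUMNS = [
    "patient_id", "site_item_id", "age", "retreatment", "trial_level",
    "planning_constraint", "other_constraint_points", "photon_unsafe",
    "risk_factors", "misc_adjustment", "misc_annotation", "insurance",
    "sex", "race", "evaluation_date",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def _to_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return _BOOL[str(v).strip().lower()]


def profile_to_row(p: PatientProfile) -> dict:
    return {
        "patient_id": p.patient_id,
        "site_item_id": p.site_item_id,
        "age": p.age,
        "retreatment": p.retreatment,
        "trial_level": p.trial_level.value,
        "planning_constraint": p.planning_constraint.value,
        "other_constraint_points": p.other_constraint_points,
        "photon_unsafe": p.photon_unsafe,
        "risk_factors": ";".join(sorted(p.risk_factors)),
        "misc_adjustment": p.misc_adjustment,
        "misc_annotation": p.misc_annotation,
        "insurance": p.insurance.value,
        "sex": p.sex.value,
        "race": p.race.value,
        "evaluation_date": p.evaluation_date.isoformat(),
    }


def profile_from_row(row: dict) -> PatientProfile:
    rf = row.get("risk_factors") or ""
    if isinstance(rf, float):  # NaN from pandas
        rf = ""
    ann = row.get("misc_annotation") or ""
    if isinstance(ann, float):
        ann = ""
    ev = row["evaluation_date"]
    if not isinstance(ev, datetime.date):
        ev = datetime.date.fromisoformat(str(ev)[:10])
    return PatientProfile(
        patient_id=str(row["patient_id"]),
        site_item_id=str(row["site_item_id"]),
        age=int(row["age"]),
        retreatment=_to_bool(row.get("retreatment", False)),
        trial_level=TrialLevel(str(row.get("trial_level", "off_protocol"))),
        planning_constraint=PlanningConstraint(
            str(row.get("planning_constraint", "none"))),
        other_constraint_points=int(row.get("other_constraint_points", 0) or 0),
        photon_unsafe=_to_bool(row.get("photon_unsafe", False)),
        risk_factors=frozenset(s for s in str(rf).split(";") if s),
        misc_adjustment=int(row.get("misc_adjustment", 0) or 0),
        misc_annotation=str(ann),
        insurance=Insurance(str(row.get("insurance", "other"))),
        sex=Sex(str(row.get("sex", "male"))),
        race=Race(str(row.get("race", "caucasian"))),
        evaluation_date=ev,
    )


def read_patients_csv(path: Union[str, Path]) -> list[PatientProfile]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [profile_from_row(row) for row in df.to_dict("records")]


def write_patients_csv(profiles, path: Union[str, Path]) -> None:
    df = pd.DataFrame([profile_to_row(p) for p in profiles],
                      columns=PROFILE_COLUMNS)
    df.to_csv(path, index=False)


def read_patients_jsonl(path: Union[str, Path]) -> list[PatientProfile]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(profile_from_row(json.loads(line)))
    return out


def write_patients_jsonl(profiles, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(json.dumps(profile_to_row(p), sort_keys=True) + "\n")
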