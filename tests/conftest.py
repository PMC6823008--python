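import datetime

import pytest

from pbtriage.cohort import CohortRecord
from pbtriage.rubric import (
    Insurance,
    PatientProfile,
    PlanningConstraint,
    TrialLevel,
    load_rubric,
)


@pytest.fixture(scope="session")
def rubric():
    return load_rubric()


def make_candidate(pid, cbs, eval_date, medicare=False, site="prostate_sv_only",
                   group="male_gu", received=False, age=70):
    """Hand-built candidate record for allocation/inference tests; the cbs
    is set directly (allocation and inference never re-score)."""
    profile = PatientProfile(
        patient_id=pid,
        site_item_id=site,
        age=age,
        insurance=Insurance.MEDICARE if medicare else Insurance.OTHER,
        evaluation_date=eval_date,
    )
    return CohortRecord(profile=profile, site_group=group, cbs=cbs,
                        candidate=True, received_pbt=received)


@pytest.fixture
def max_profile():
    """The worked 65-point profile: nasopharynx + retreatment + age 12 +
    randomized trial + secondary constraint + photon-unsafe + SLE."""
    return PatientProfile(
        patient_id="max",
        site_item_id="nasopharynx",
        age=12,
        retreatment=True,
        trial_level=TrialLevel.RANDOMIZED,
        planning_constraint=PlanningConstraint.SECONDARY,
        photon_unsafe=True,
        risk_factors=frozenset({"SLE_scleroderma"}),
        evaluation_date=datetime.date(2016, 3, 1),
    )


@pytest.fixture
def zero_profile():
    """The worked 0-point profile: larynx, no retreatment, age 65,
    off-protocol, no planning flags, no risk factors."""
    return PatientProfile(
        patient_id="zero",
        site_item_id="larynx",
        age=65,
    )


@pytest.fixture
def five_point_profile():
    """The worked 5-point profile: prostate/SV only + registry study,
    age 70 (2 + 0 + 3)."""
    return PatientProfile(
        patient_id="five",
        site_item_id="prostate_sv_only",
        age=70,
        trial_level=TrialLevel.REGISTRY,
    )
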