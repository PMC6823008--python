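"""Capacity-constrained allocation of proton-therapy treatment slots.

Candidates queue for a limited number of weekly treatment slots under a
time-varying gantry capacity schedule (one room at first treatment,
more as additional gantries open).  Within each period, candidates who
have cleared the payer-approval gate are served in descending CBS order
until the period's slots are exhausted; unserved approved candidates
remain queued for the next period.  Approval is a single seeded
Bernoulli draw per patient at evaluation time (no re-application;
non-approved patients are assumed to proceed with photon therapy), and
takes effect after a configurable delay.

Ties on CBS are broken by earlier evaluation date, then by stable input
order, so a run is fully deterministic given its seed.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .cohort import CohortRecord
from .inference import TwoByTwoTable
from .rubric import Insurance

__all__ = [
    "AllocationConfig",
    "PatientAllocation",
    "PeriodStats",
    "AllocationOutcome",
    "default_allocation_config",
    "simulate_allocation",
    "apply_allocation",
    "receipt_table",
]

# slots per gantry per week; the source never quantifies slot counts, so
# this is a configuration constant, not an estimate
DEFAULT_SLOTS_PER_GANTRY = 10


@dataclass(frozen=True)
class AllocationConfig:
    """Capacity schedule and payer-approval model.

    ``capacity_schedule`` lists (start date, slots per period) with
    strictly increasing dates; the first entry opens the first period.
    Periods are half-open ``[start, start + period_days)``.
    """

    capacity_schedule: tuple[tuple[datetime.date, int], ...]
    horizon_end: datetime.date
    period_days: int = 7
    approval_prob: Mapping[str, float] = field(
        default_factory=lambda: {"medicare": 1.0, "other": 1.0})
    approval_delay_days: int = 0

    def validate(self) -> None:
        if not self.capacity_schedule:
            raise ValueError("capacity schedule is empty")
        dates = [d for d, _ in self.capacity_schedule]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("capacity schedule dates must be strictly increasing")
        if any(s < 0 for _, s in self.capacity_schedule):
            raise ValueError("slot counts must be non-negative")
        for k, p in self.approval_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"approval probability for {k!r} outside [0,1]")
        if self.period_days <= 0:
            raise ValueError("period length must be positive")
        if self.approval_delay_days < 0:
            raise ValueError("approval delay must be non-negative")

    def slots_at(self, day: datetime.date) -> int:
        slots = 0
        for start, s in self.capacity_schedule:
            if start <= day:
                slots = s
        return slots


def default_allocation_config(
    slots_per_gantry: int = DEFAULT_SLOTS_PER_GANTRY,
    first_treatment: datetime.date = datetime.date(2016, 2, 23),
    second_gantry: datetime.date = datetime.date(2016, 4, 29),
    horizon_end: datetime.date = datetime.date(2016, 7, 19),
    approval_prob: Optional[Mapping[str, float]] = None,
) -> AllocationConfig:
    """Two-room ramp-up schedule: one gantry at first treatment, a second
    opening later, horizon at the third gantry (after which slots were no
    longer scarce)."""
    return AllocationConfig(
        capacity_schedule=(
            (first_treatment, slots_per_gantry),
            (second_gantry, 2 * slots_per_gantry),
        ),
        horizon_end=horizon_end,
        approval_prob=(dict(approval_prob) if approval_prob is not None
                       else {"medicare": 1.0, "other": 1.0}),
    )


@dataclass
class PatientAllocation:
    patient_id: str
    cbs: int
    evaluation_date: datetime.date
    approved: bool
    available_date: Optional[datetime.date]
    scheduled_date: Optional[datetime.date] = None

    @property
    def received_pbt(self) -> bool:
        return self.scheduled_date is not None


@dataclass
class PeriodStats:
    start: datetime.date
    end: datetime.date
    slots_available: int
    slots_used: int
    queue_length: int  # approved patients waiting at the start of service


@dataclass
class AllocationOutcome:
    patients: dict[str, PatientAllocation]
    periods: list[PeriodStats]

    def __post_init__(self):
        for p in self.periods:
            assert p.slots_used <= p.slots_available
        for pa in self.patients.values():
            assert not (pa.received_pbt and not pa.approved)


def simulate_allocation(cohort: Sequence[CohortRecord],
                        config: AllocationConfig,
                        seed: int = 0) -> AllocationOutcome:
    """Run the priority-queue allocation over the capacity schedule.

    In every period, approved candidates whose approval completed before
    the period's end are served in descending CBS order (ties: earlier
    evaluation date, then input order) until slots run out.  Deterministic
    given ``seed``, which drives only the approval draws.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    candidates = [r for r in cohort if r.candidate]

    patients: dict[str, PatientAllocation] = {}
    waiting: list[tuple[int, datetime.date, int, str]] = []  # sort key + id
    for idx, rec in enumerate(candidates):
        prof = rec.profile
        prob = config.approval_prob.get(prof.insurance.value, 1.0)
        approved = bool(rng.random() < prob)
        available = (prof.evaluation_date
                     + datetime.timedelta(days=config.approval_delay_days)
                     if approved else None)
        pa = PatientAllocation(
            patient_id=prof.patient_id, cbs=int(rec.cbs),
            evaluation_date=prof.evaluation_date,
            approved=approved, available_date=available,
        )
        patients[prof.patient_id] = pa
        if approved:
            waiting.append((-pa.cbs, pa.evaluation_date, idx, pa.patient_id))

    waiting.sort()
    periods: list[PeriodStats] = []
    start = config.capacity_schedule[0][0]
    while start < config.horizon_end:
        end = start + datetime.timedelta(days=config.period_days)
        slots = config.slots_at(start)
        eligible = [w for w in waiting
                    if patients[w[3]].available_date < end]
        served = eligible[:slots]
        for w in served:
            patients[w[3]].scheduled_date = start
            waiting.remove(w)
        periods.append(PeriodStats(
            start=start, end=end, slots_available=slots,
            slots_used=len(served), queue_length=len(eligible),
        ))
        start = end
    return AllocationOutcome(patients=patients, periods=periods)


def apply_allocation(cohort: Sequence[CohortRecord],
                     outcome: AllocationOutcome) -> None:
    """Write the simulated receipt flags back onto the cohort records."""
    for rec in cohort:
        if rec.candidate:
            pa = outcome.patients.get(rec.profile.patient_id)
            rec.received_pbt = bool(pa and pa.received_pbt)


def receipt_table(outcome: Optional[AllocationOutcome],
                  cohort: Sequence[CohortRecord],
                  stratifier: Union[str, Callable[[CohortRecord], bool]]
                  = "medicare") -> TwoByTwoTable:
    """2x2 receipt table by a binary stratum, bridging simulation to the
    odds-ratio layer.

    ``stratifier`` is either the string ``"medicare"`` or a callable
    returning a boolean per candidate record.  When ``outcome`` is None
    the records' own ``received_pbt`` flags are used.
    """
    if stratifier == "medicare":
        strat = lambda r: r.profile.insurance is Insurance.MEDICARE
    elif callable(stratifier):
        strat = stratifier
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    a = b = c = d = 0
    for rec in cohort:
        if not rec.candidate:
            continue
        exposed = strat(rec)
        if not isinstance(exposed, (bool, np.bool_)):
            raise ValueError("stratifier must return a boolean")
        if outcome is not None:
            pa = outcome.patients.get(rec.profile.patient_id)
            received = bool(pa and pa.received_pbt)
        else:
            received = rec.received_pbt
        if exposed:
            a, b = (a + 1, b) if received else (a, b + 1)
        else:
            c, d = (c + 1, d) if received else (c, d + 1)
    return TwoByTwoTable(a, b, c, d)
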