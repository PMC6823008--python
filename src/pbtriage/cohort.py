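"""Synthetic patient-cohort generation.

The study cohort (205 proton-therapy candidates out of 2163 evaluated
patients) is not publicly deposited, so this module generates synthetic
cohorts that reproduce its printed marginal structure: the six-group
site mixture with per-site CBS means/SDs, the insurance, sex, race, age
and retreatment mixtures, uniform evaluation dates over the study
window, and a Bernoulli receipt-of-treatment outcome with
logit p = beta0 + beta1*CBS + beta2*[Medicare].

Every generated CBS value is realizable under the rubric: scores are
drawn from a per-site truncated normal on [0, 65], rounded half-up and
snapped to the nearest score achievable by an actual patient profile in
that site group (:func:`profile_from_score_target` produces a witness
profile that re-scores to the value exactly).

Demographics are drawn independently of the CBS (the source reports
marginals only), so a record's own age/retreatment fields do not feed
back into its sampled score; joint structure beyond the printed
marginals is deliberately not modeled.
"""

from __future__ import annotations

import datetime
import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .rubric import (
    AgeBand,
    Insurance,
    PatientProfile,
    PlanningConstraint,
    Race,
    Rubric,
    Sex,
    TrialLevel,
    load_rubric,
    score,
)
from .io import PROFILE_COLUMNS, profile_from_row, profile_to_row

__all__ = [
    "ANALYSIS_GROUPS",
    "GeneratorConfig",
    "CohortRecord",
    "DEFAULT_INTERCEPT",
    "achievable_scores",
    "profile_from_score_target",
    "generate_cohort",
    "summarize_cohort",
    "calibrate_intercept",
    "score_pmf",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

# Rubric site-group id -> analysis site group (the six-group descriptive
# breakdown: male GU, breast, CNS, head & neck, thoracic, other).
ANALYSIS_GROUPS: dict[str, str] = {
    "head_and_neck": "head_and_neck",
    "esophagus": "other",
    "gi": "other",
    "thoracic": "thoracic",
    "breast": "breast",
    "gynecologic": "other",
    "male_gu": "male_gu",
    "cns": "cns",
    "other": "other",
}

ANALYSIS_GROUP_LABELS = {
    "male_gu": "Male Genitourinary",
    "breast": "Breast",
    "cns": "Central Nervous System",
    "head_and_neck": "Head and Neck",
    "thoracic": "Thoracic",
    "other": "Other",
}

# Descriptive age grouping used in cohort summaries (distinct from the
# rubric's scoring bands).
SUMMARY_AGE_BANDS = (("under_21", 0, 20), ("21_64", 21, 64), ("over_64", 65, None))

# Intercept of the default outcome model, calibrated once so that the
# expected receipt fraction over the default covariate mixture equals
# 122/205 (see calibrate_intercept); beta1 = ln 1.04, beta2 = ln 3.13.
DEFAULT_INTERCEPT = -0.6594260356960575


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort generator.

    The default values are the cohort's printed marginals: 2163 patients
    evaluated, 205 candidates, the six-group site mixture with per-site
    CBS mean/SD, 64/205 Medicare, 27/204 retreated, and the sex, race and
    age-group counts.  ``exact_mix`` reproduces categorical counts
    exactly (permuted assignment); otherwise categories are drawn
    multinomially from the same proportions.
    """

    n_evaluated: int = 2163
    n_candidates: int = 205
    site_mixture: Mapping[str, int] = field(default_factory=lambda: {
        "male_gu": 53, "breast": 25, "cns": 64,
        "head_and_neck": 27, "thoracic": 21, "other": 15,
    })
    cbs_params: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "male_gu": (5.1, 2.9), "breast": (23.2, 6.8), "cns": (22.5, 8.2),
        "head_and_neck": (23.7, 8.7), "thoracic": (27.5, 6.9),
        "other": (22.3, 7.7),
    })
    medicare_fraction: float = 64 / 205
    retreatment_fraction: float = 27 / 204
    sex_mixture: Mapping[str, int] = field(
        default_factory=lambda: {"male": 113, "female": 92})
    race_mixture: Mapping[str, int] = field(
        default_factory=lambda: {"caucasian": 138, "african_american": 42,
                                 "other": 25})
    age_mixture: Mapping[str, int] = field(
        default_factory=lambda: {"under_21": 12, "21_64": 117, "over_64": 76})
    beta0: float = DEFAULT_INTERCEPT
    beta1: float = math.log(1.04)
    beta2: float = math.log(3.13)
    date_start: datetime.date = datetime.date(2015, 1, 6)
    date_end: datetime.date = datetime.date(2016, 7, 18)
    first_treatment_date: datetime.date = datetime.date(2016, 2, 23)
    second_gantry_date: datetime.date = datetime.date(2016, 4, 29)
    third_gantry_date: datetime.date = datetime.date(2016, 7, 19)
    exact_mix: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.exact_mix and sum(self.site_mixture.values()) != self.n_candidates:
            raise ValueError(
                f"site mixture counts sum to {sum(self.site_mixture.values())}, "
                f"expected n_candidates={self.n_candidates} (exact_mix)")
        for g, (_, sd) in self.cbs_params.items():
            if sd < 0:
                raise ValueError(f"negative SD for site group {g!r}")
        for name, frac in (("medicare", self.medicare_fraction),
                           ("retreatment", self.retreatment_fraction)):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} fraction must be in [0,1]")
        if set(self.site_mixture) - set(self.cbs_params):
            raise ValueError("site mixture group without CBS parameters")
        if self.n_candidates > self.n_evaluated:
            raise ValueError("n_candidates exceeds n_evaluated")


@dataclass
class CohortRecord:
    """One evaluated patient; candidates carry a CBS and an outcome."""

    profile: Optional[PatientProfile]
    site_group: Optional[str]
    cbs: Optional[int]
    candidate: bool
    received_pbt: bool = False

    def __post_init__(self):
        if self.received_pbt and not self.candidate:
            raise ValueError("received PBT implies candidate")
        if self.candidate and self.cbs is not None and not 0 <= self.cbs <= 65:
            raise ValueError(f"cbs {self.cbs} outside [0, 65]")


# ---------------------------------------------------------------------------
# achievable scores and witness profiles

_ENUM_CACHE: dict[tuple[int, str], dict[int, tuple]] = {}

# canonical ages used for witness profiles, one per scoring band
def _rep_age(band: AgeBand) -> int:
    if band.max is None:
        return band.min + 10
    return band.min if band.min > 0 else 10


def _enumerate_group(rubric: Rubric, group: str) -> dict[int, tuple]:
    """First-found witness combination for every achievable standard score.

    Iteration order prefers simple profiles: zero-point options first in
    every category, sites in rubric order.
    """
    key = (id(rubric), group)
    if key in _ENUM_CACHE:
        return _ENUM_CACHE[key]
    site_items = [
        it
        for sg in rubric.site_groups
        if ANALYSIS_GROUPS.get(sg.id, "other") == group
        for it in sg.items
    ]
    if not site_items:
        raise ValueError(f"unknown site group {group!r}")
    bands = sorted(rubric.age_bands, key=lambda b: b.points)
    trials = sorted(rubric.trial_points, key=rubric.trial_points.get)
    plannings = [("none", 0)] + sorted(
        rubric.planning_points.items(), key=lambda kv: kv[1])
    risks = [(None, 0)] + sorted(
        rubric.risk_factor_points.items(), key=lambda kv: kv[1])
    table: dict[int, tuple] = {}
    for site, retreat, band, trial, planning, photon, risk in itertools.product(
        site_items, (False, True), bands, trials, plannings, (False, True), risks
    ):
        total = (
            site.points
            + rubric.retreatment_points["yes" if retreat else "no"] * retreat
            + band.points
            + rubric.trial_points[trial]
            + planning[1]
            + rubric.photon_unsafe_bonus * photon
            + risk[1]
        )
        if total not in table:
            table[total] = (site.id, retreat, band, trial, planning[0], photon,
                            risk[0])
    _ENUM_CACHE[key] = table
    return table


def achievable_scores(group: str, rubric: Optional[Rubric] = None) -> tuple[int, ...]:
    """Sorted standard CBS totals realizable for an analysis site group."""
    rubric = rubric if rubric is not None else _default_rubric()
    return tuple(sorted(_enumerate_group(rubric, group)))


_DEFAULT_RUBRIC: Optional[Rubric] = None


def _default_rubric() -> Rubric:
    global _DEFAULT_RUBRIC
    if _DEFAULT_RUBRIC is None:
        _DEFAULT_RUBRIC = load_rubric()
    return _DEFAULT_RUBRIC


def profile_from_score_target(
    site_group: str,
    target_cbs: int,
    rubric: Optional[Rubric] = None,
    patient_id: str = "synthetic",
) -> PatientProfile:
    """Deterministically construct a valid profile scoring ``target_cbs``.

    Raises ``ValueError`` listing the achievable score set when the target
    cannot be realized in the given site group.
    """
    rubric = rubric if rubric is not None else _default_rubric()
    table = _enumerate_group(rubric, site_group)
    if target_cbs not in table:
        raise ValueError(
            f"CBS {target_cbs} is not achievable for site group "
            f"{site_group!r}; achievable scores: {sorted(table)}")
    site_id, retreat, band, trial, planning, photon, risk = table[target_cbs]
    profile = PatientProfile(
        patient_id=patient_id,
        site_item_id=site_id,
        age=_rep_age(band),
        retreatment=retreat,
        trial_level=TrialLevel(trial),
        planning_constraint=(PlanningConstraint(planning)),
        photon_unsafe=photon,
        risk_factors=frozenset() if risk is None else frozenset({risk}),
    )
    assert score(rubric, profile).total == target_cbs
    return profile


# ---------------------------------------------------------------------------
# sampling helpers

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float, size: int) -> np.ndarray:
    """Rejection sampling from N(mean, sd) restricted to [low, high]."""
    if sd == 0:
        if not low <= mean <= high:
            raise ValueError("degenerate distribution outside truncation bounds")
        return np.full(size, float(mean))
    out = np.empty(size)
    n = 0
    while n < size:
        draws = rng.normal(mean, sd, size=max(2 * (size - n), 16))
        keep = draws[(draws >= low) & (draws <= high)]
        take = min(keep.size, size - n)
        out[n:n + take] = keep[:take]
        n += take
    return out


def _snap(values: np.ndarray, achievable: Sequence[int]) -> np.ndarray:
    """Snap integers to the nearest achievable score (ties to the lower)."""
    a = np.asarray(achievable)
    values = np.asarray(values)
    idx = np.searchsorted(a, values)
    lo = a[np.clip(idx - 1, 0, len(a) - 1)]
    hi = a[np.clip(idx, 0, len(a) - 1)]
    pick_lo = np.abs(values - lo) <= np.abs(hi - values)
    return np.where(pick_lo, lo, hi)


def _exact_labels(rng: np.random.Generator, counts: Mapping[str, int],
                  n: int, exact: bool) -> list[str]:
    """Assign categorical labels with exact (permuted) or multinomial counts."""
    labels = list(counts)
    if exact:
        pool: list[str] = []
        for lab in labels:
            pool.extend([lab] * counts[lab])
        if len(pool) < n:  # pad with the modal label (rounding slack)
            pool.extend([max(labels, key=counts.get)] * (n - len(pool)))
        pool = pool[:n]
        return [pool[i] for i in rng.permutation(n)]
    probs = np.array([counts[l] for l in labels], dtype=float)
    probs /= probs.sum()
    return [labels[i] for i in rng.choice(len(labels), size=n, p=probs)]


def _exact_bool(rng: np.random.Generator, fraction: float, n: int,
                exact: bool) -> np.ndarray:
    if exact:
        k = int(math.floor(fraction * n + 0.5))
        flags = np.zeros(n, dtype=bool)
        flags[:k] = True
        return flags[rng.permutation(n)]
    return rng.random(n) < fraction


# ---------------------------------------------------------------------------
# generation

def generate_cohort(config: Optional[GeneratorConfig] = None,
                    rubric: Optional[Rubric] = None,
                    seed: Optional[int] = None) -> list[CohortRecord]:
    """Generate one synthetic cohort under the configured study conditions.

    Fully reproducible from ``config.seed`` (or the ``seed`` override):
    one seed sequence per run, with fixed spawned sub-streams for site
    assignment, scores, demographics, evaluation dates and outcomes.
    """
    config = config if config is not None else GeneratorConfig()
    config.validate()
    rubric = rubric if rubric is not None else _default_rubric()
    run_seed = config.seed if seed is None else seed
    streams = np.random.SeedSequence(run_seed).spawn(5)
    rng_sites = np.random.default_rng(streams[0])
    rng_scores = np.random.default_rng(streams[1])
    rng_demo = np.random.default_rng(streams[2])
    rng_dates = np.random.default_rng(streams[3])
    rng_outcome = np.random.default_rng(streams[4])

    n_cand = config.n_candidates
    groups = _exact_labels(rng_sites, dict(config.site_mixture), n_cand,
                           config.exact_mix)

    # per-candidate CBS: truncated normal by site group, rounded half-up,
    # snapped to the group's achievable score set
    cbs = np.empty(n_cand, dtype=int)
    order = np.arange(n_cand)
    for g in config.site_mixture:
        mask = np.array([gr == g for gr in groups])
        if not mask.any():
            continue
        mean, sd = config.cbs_params[g]
        raw = _truncated_normal(rng_scores, mean, sd, 0.0, 65.0, int(mask.sum()))
        rounded = np.floor(raw + 0.5).astype(int)
        cbs[order[mask]] = _snap(rounded, achievable_scores(g, rubric))

    medicare = _exact_bool(rng_demo, config.medicare_fraction, n_cand,
                           config.exact_mix)
    retreat = _exact_bool(rng_demo, config.retreatment_fraction, n_cand,
                          config.exact_mix)
    sexes = _exact_labels(rng_demo, dict(config.sex_mixture), n_cand,
                          config.exact_mix)
    races = _exact_labels(rng_demo, dict(config.race_mixture), n_cand,
                          config.exact_mix)
    age_bands = _exact_labels(rng_demo, dict(config.age_mixture), n_cand,
                              config.exact_mix)
    ages = np.empty(n_cand, dtype=int)
    for i, band_id in enumerate(age_bands):
        lo, hi = next((lo, hi) for bid, lo, hi in SUMMARY_AGE_BANDS
                      if bid == band_id)
        hi = 90 if hi is None else hi
        ages[i] = rng_demo.integers(lo, hi + 1)

    span = (config.date_end - config.date_start).days
    all_dates = [
        config.date_start + datetime.timedelta(days=int(d))
        for d in rng_dates.integers(0, span + 1, size=config.n_evaluated)
    ]

    p = expit(config.beta0 + config.beta1 * cbs
              + config.beta2 * medicare.astype(float))
    received = rng_outcome.random(n_cand) < p

    records: list[CohortRecord] = []
    width = len(str(config.n_evaluated))
    for i in range(n_cand):
        witness = profile_from_score_target(groups[i], int(cbs[i]), rubric)
        profile = replace(
            witness,
            patient_id=f"P{i + 1:0{width}d}",
            age=int(ages[i]),
            retreatment=bool(retreat[i]),
            insurance=Insurance.MEDICARE if medicare[i] else Insurance.OTHER,
            sex=Sex(sexes[i]),
            race=Race(races[i]),
            evaluation_date=all_dates[i],
        )
        records.append(CohortRecord(
            profile=profile, site_group=groups[i], cbs=int(cbs[i]),
            candidate=True, received_pbt=bool(received[i]),
        ))
    for i in range(n_cand, config.n_evaluated):
        records.append(CohortRecord(
            profile=PatientProfile(
                patient_id=f"P{i + 1:0{width}d}",
                site_item_id="",
                age=0,
                evaluation_date=all_dates[i],
            ),
            site_group=None, cbs=None, candidate=False, received_pbt=False,
        ))
    return records


# ---------------------------------------------------------------------------
# intercept calibration

def score_pmf(config: GeneratorConfig,
              rubric: Optional[Rubric] = None) -> np.ndarray:
    """Marginal pmf of the generated integer CBS over scores 0..65.

    Mixes the per-site truncated normals (rounded half-up, snapped to the
    achievable set) with the site-mixture weights.  Used for deterministic
    intercept calibration.
    """
    rubric = rubric if rubric is not None else _default_rubric()
    weights = np.array([config.site_mixture[g] for g in config.site_mixture],
                       dtype=float)
    weights /= weights.sum()
    pmf = np.zeros(66)
    for w, g in zip(weights, config.site_mixture):
        mean, sd = config.cbs_params[g]
        ach = np.asarray(achievable_scores(g, rubric))
        if sd == 0:
            k = _snap(np.array([int(math.floor(mean + 0.5))]), ach)[0]
            pmf[k] += w
            continue
        z = (np.arange(67) - 0.5 - mean) / sd  # rounding-cell edges
        edges = norm.cdf(np.clip(z, (0 - mean) / sd, (65 - mean) / sd))
        cell = np.diff(edges)
        total = norm.cdf((65 - mean) / sd) - norm.cdf((0 - mean) / sd)
        cell = cell / total
        snapped = _snap(np.arange(66), ach)
        for k in range(66):
            pmf[snapped[k]] += w * cell[k]
    return pmf


def calibrate_intercept(config: Optional[GeneratorConfig] = None,
                        target_rate: float = 122 / 205,
                        rubric: Optional[Rubric] = None) -> float:
    """Solve for beta0 so the expected receipt fraction equals ``target_rate``.

    The expectation is over the configured site/CBS mixture and the
    Medicare fraction; deterministic (no simulation).
    """
    config = config if config is not None else GeneratorConfig()
    pmf = score_pmf(config, rubric)
    ks = np.arange(66)
    q = config.medicare_fraction

    def expected(b0: float) -> float:
        p = (q * expit(b0 + config.beta1 * ks + config.beta2)
             + (1 - q) * expit(b0 + config.beta1 * ks))
        return float(np.dot(pmf, p)) - target_rate

    return float(brentq(expected, -30.0, 30.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# summaries and IO

def _sd(x: np.ndarray) -> float:
    # convention: SD of a single observation is 0.0
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def summarize_cohort(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    """Descriptive table over candidates: n, %, mean CBS, SD per stratum.

    Strata mirror the study's descriptive breakdown: score halves about
    the median, receipt of proton therapy, age group, sex, race,
    retreatment, insurance, and site group; the first row is the overall
    total with the score range.
    """
    cands = [r for r in cohort if r.candidate]
    if not cands:
        raise ValueError("cohort has no candidates to summarize")
    cbs = np.array([r.cbs for r in cands], dtype=float)
    n = len(cands)
    median = float(np.median(cbs))

    def stratum(characteristic: str, level: str, mask: np.ndarray) -> dict:
        sub = cbs[mask]
        return {
            "characteristic": characteristic,
            "level": level,
            "n": int(mask.sum()),
            "pct": round(100.0 * mask.sum() / n, 1),
            "cbs_mean": round(float(sub.mean()), 1) if sub.size else float("nan"),
            "cbs_sd": round(_sd(sub), 1) if sub.size else float("nan"),
        }

    rows = [{
        "characteristic": "total", "level": "total", "n": n, "pct": 100.0,
        "cbs_mean": round(float(cbs.mean()), 1), "cbs_sd": round(_sd(cbs), 1),
        "cbs_min": int(cbs.min()), "cbs_max": int(cbs.max()),
    }]
    rows.append(stratum("score_half", "le_median", cbs <= median))
    rows.append(stratum("score_half", "gt_median", cbs > median))
    received = np.array([r.received_pbt for r in cands])
    rows.append(stratum("proton_therapy", "yes", received))
    rows.append(stratum("proton_therapy", "no", ~received))
    ages = np.array([r.profile.age for r in cands])
    for bid, lo, hi in SUMMARY_AGE_BANDS:
        mask = (ages >= lo) & (ages <= (hi if hi is not None else 200))
        rows.append(stratum("age_group", bid, mask))
    sexes = np.array([r.profile.sex.value for r in cands])
    for s in ("male", "female"):
        rows.append(stratum("sex", s, sexes == s))
    races = np.array([r.profile.race.value for r in cands])
    for rc in ("caucasian", "african_american", "other"):
        rows.append(stratum("race", rc, races == rc))
    retre = np.array([r.profile.retreatment for r in cands])
    rows.append(stratum("retreatment", "yes", retre))
    rows.append(stratum("retreatment", "no", ~retre))
    ins = np.array([r.profile.insurance.value for r in cands])
    rows.append(stratum("insurance", "medicare", ins == "medicare"))
    rows.append(stratum("insurance", "other", ins == "other"))
    sites = np.array([r.site_group for r in cands])
    for g in ("male_gu", "breast", "cns", "head_and_neck", "thoracic", "other"):
        rows.append(stratum("site", g, sites == g))
    return pd.DataFrame(rows)


COHORT_COLUMNS = PROFILE_COLUMNS + ["site_group", "cbs", "candidate",
                                    "received_pbt"]


def cohort_to_frame(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in cohort:
        row = profile_to_row(r.profile)
        row["site_group"] = r.site_group if r.site_group is not None else ""
        row["cbs"] = r.cbs if r.cbs is not None else ""
        row["candidate"] = r.candidate
        row["received_pbt"] = r.received_pbt
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[CohortRecord]:
    out = []
    for row in df.to_dict("records"):
        candidate = str(row["candidate"]).strip().lower() in ("true", "1", "yes")
        received = str(row["received_pbt"]).strip().lower() in ("true", "1", "yes")
        cbs_raw = row.get("cbs", "")
        cbs = None if cbs_raw in ("", None) or (isinstance(cbs_raw, float)
                                                and math.isnan(cbs_raw)) \
            else int(float(cbs_raw))
        group = row.get("site_group") or None
        if isinstance(group, float):
            group = None
        out.append(CohortRecord(
            profile=profile_from_row(row) if row.get("site_item_id") or candidate
            else profile_from_row({**row, "site_item_id": ""}),
            site_group=group, cbs=cbs, candidate=candidate,
            received_pbt=received,
        ))
    return out


def write_cohort_csv(cohort: Sequence[CohortRecord],
                     path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[CohortRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame_to_cohort(df)
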