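"""Clinical Benefit Score (CBS) rubric engine.

The CBS is a 0-65 point triage score used to prioritize patients for
proton beam therapy (PBT) when treatment slots are scarce.  Points are
awarded in six categories -- primary disease site, retreatment of a
previously irradiated or overlapping site, age group, clinical-trial
enrollment, treatment-planning considerations (organ-at-risk constraint
violations, with a bonus when photon therapy would be unsafe), and
patient risk factors for radiation complications -- plus a free-form
miscellaneous adjustment that requires chairman-level review.

Only a single point value may be scored per category; the photon-unsafe
bonus is the one additive modifier, stacking on top of the
planning-constraint choice.  This module represents the rubric as data
(a YAML document shipped with the package), validates patient profiles
against it, and computes scores with a per-category audit trail.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "RubricError",
    "ProfileError",
    "TrialLevel",
    "PlanningConstraint",
    "Insurance",
    "Sex",
    "Race",
    "RubricItem",
    "AgeBand",
    "SiteGroup",
    "Rubric",
    "PatientProfile",
    "ScoreBreakdown",
    "load_rubric",
    "dump_rubric",
    "age_band_points",
    "category_points",
    "score",
    "max_score",
    "validate_profile",
    "suggest_site_item",
]


class RubricError(ValueError):
    """Malformed or internally inconsistent rubric definition."""


class ProfileError(ValueError):
    """Patient profile that cannot be scored against the rubric."""


class TrialLevel(str, enum.Enum):
    RANDOMIZED = "randomized"
    INTERVENTIONAL = "interventional"
    REGISTRY = "registry"
    OFF_PROTOCOL = "off_protocol"


class PlanningConstraint(str, enum.Enum):
    NONE = "none"
    PRIMARY = "primary"
    SECONDARY = "secondary"
    OTHER = "other"


class Insurance(str, enum.Enum):
    MEDICARE = "medicare"
    OTHER = "other"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Race(str, enum.Enum):
    CAUCASIAN = "caucasian"
    AFRICAN_AMERICAN = "african_american"
    OTHER = "other"


@dataclass(frozen=True)
class RubricItem:
    id: str
    label: str
    points: int


@dataclass(frozen=True)
class AgeBand:
    id: str
    label: str
    min: int
    max: Optional[int]  # inclusive upper bound; None = open-ended
    points: int

    def contains(self, age: int) -> bool:
        return age >= self.min and (self.max is None or age <= self.max)


@dataclass(frozen=True)
class SiteGroup:
    id: str
    label: str
    items: tuple[RubricItem, ...]


@dataclass(frozen=True)
class Category:
    """Generic view of one scoring category.

    ``exclusive`` categories accept at most one non-modifier item;
    ``modifiers`` are additive on top of the exclusive choice.
    """

    id: str
    label: str
    exclusive: bool
    items: tuple[RubricItem, ...]
    modifiers: tuple[RubricItem, ...] = ()


@dataclass(frozen=True)
class Rubric:
    version: str
    site_groups: tuple[SiteGroup, ...]
    retreatment_points: Mapping[str, int]  # keys "yes"/"no"
    age_bands: tuple[AgeBand, ...]
    trial_points: Mapping[str, int]  # keyed by TrialLevel value
    planning_points: Mapping[str, int]  # "primary"/"secondary"
    planning_other_max: int
    photon_unsafe_bonus: int
    risk_factor_points: Mapping[str, int]

    # -- lookup helpers ------------------------------------------------

    @property
    def site_items(self) -> dict[str, RubricItem]:
        return {it.id: it for g in self.site_groups for it in g.items}

    def site_group_of(self, item_id: str) -> SiteGroup:
        for g in self.site_groups:
            if any(it.id == item_id for it in g.items):
                return g
        raise KeyError(item_id)

    @property
    def categories(self) -> tuple[Category, ...]:
        """All scoring categories in rubric order, as generic Category views."""
        site_items = tuple(it for g in self.site_groups for it in g.items)
        return (
            Category("site", "Primary Disease Site Being Treated", True, site_items),
            Category(
                "retreatment",
                "Retreatment of Same/Overlapping Site",
                True,
                tuple(
                    RubricItem(k, k, v) for k, v in self.retreatment_points.items()
                ),
            ),
            Category(
                "age",
                "Age Group",
                True,
                tuple(RubricItem(b.id, b.label, b.points) for b in self.age_bands),
            ),
            Category(
                "trial",
                "Clinical Trial",
                True,
                tuple(RubricItem(k, k, v) for k, v in self.trial_points.items()),
            ),
            Category(
                "planning",
                "Treatment Planning Considerations",
                True,
                tuple(
                    RubricItem(k, k, v) for k, v in self.planning_points.items()
                ),
                modifiers=(
                    RubricItem(
                        "photon_unsafe",
                        "OAR Differences Would Make It Unsafe to Treat "
                        "Patient with Photons",
                        self.photon_unsafe_bonus,
                    ),
                ),
            ),
            Category(
                "risk",
                "Patient Risk Factors for RT Complications",
                True,
                tuple(
                    RubricItem(k, k, v) for k, v in self.risk_factor_points.items()
                ),
            ),
        )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "site": {
                "exclusive": True,
                "groups": [
                    {
                        "id": g.id,
                        "label": g.label,
                        "items": [
                            {"id": it.id, "label": it.label, "points": it.points}
                            for it in g.items
                        ],
                    }
                    for g in self.site_groups
                ],
            },
            "retreatment": dict(self.retreatment_points),
            "age_bands": [
                {
                    "id": b.id,
                    "label": b.label,
                    "min": b.min,
                    "max": b.max,
                    "points": b.points,
                }
                for b in self.age_bands
            ],
            "trial": dict(self.trial_points),
            "planning": {
                **dict(self.planning_points),
                "other_max": self.planning_other_max,
                "photon_unsafe_bonus": self.photon_unsafe_bonus,
            },
            "risk_factors": dict(self.risk_factor_points),
        }


@dataclass(frozen=True)
class PatientProfile:
    """Everything needed to score and analyze one patient."""

    patient_id: str
    site_item_id: str
    age: int
    retreatment: bool = False
    trial_level: TrialLevel = TrialLevel.OFF_PROTOCOL
    planning_constraint: PlanningConstraint = PlanningConstraint.NONE
    other_constraint_points: int = 0
    photon_unsafe: bool = False
    risk_factors: frozenset[str] = frozenset()
    misc_adjustment: int = 0
    misc_annotation: str = ""
    insurance: Insurance = Insurance.OTHER
    sex: Sex = Sex.MALE
    race: Race = Race.CAUCASIAN
    evaluation_date: datetime.date = datetime.date(2016, 2, 23)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-category audit trail for one scored profile.

    ``standard_range`` is True when the total lies inside the rubric's
    standard 0-65 envelope; a miscellaneous adjustment can push the total
    outside, which is flagged here rather than treated as an error.
    """

    per_category: Mapping[str, int]
    total: int
    standard_range: bool
    nonstandard_planning: bool = False  # "other" variable planning points used

    def __post_init__(self):
        assert self.total == sum(self.per_category.values())


# ---------------------------------------------------------------------------
# loading / validation


def _as_points(value, where: str) -> int:
    if not isinstance(value, int) or isinstance(value, bool) or value < 0:
        raise RubricError(f"{where}: points must be a non-negative integer, got {value!r}")
    return value


def _parse_rubric(doc: dict) -> Rubric:
    if not isinstance(doc, dict):
        raise RubricError("rubric document must be a mapping")
    for key in ("version", "site", "retreatment", "age_bands", "trial",
                "planning", "risk_factors"):
        if key not in doc:
            raise RubricError(f"rubric is missing required field {key!r}")

    groups = []
    seen_ids: set[str] = set()
    for gdoc in doc["site"].get("groups", []):
        items = []
        for idoc in gdoc.get("items", []):
            iid = idoc.get("id")
            if iid in seen_ids:
                raise RubricError(f"duplicate item id {iid!r} in site category")
            seen_ids.add(iid)
            items.append(
                RubricItem(iid, idoc.get("label", iid),
                           _as_points(idoc.get("points"), f"site item {iid!r}"))
            )
        groups.append(SiteGroup(gdoc["id"], gdoc.get("label", gdoc["id"]), tuple(items)))
    if len({g.id for g in groups}) != len(groups):
        raise RubricError("duplicate site group ids")
    if not groups:
        raise RubricError("site category has no groups")

    retreat = {str(k): _as_points(v, f"retreatment {k!r}")
               for k, v in doc["retreatment"].items()}
    if set(retreat) != {"yes", "no"}:
        raise RubricError("retreatment must define exactly 'yes' and 'no'")

    bands = tuple(
        AgeBand(b["id"], b.get("label", b["id"]), int(b["min"]),
                None if b.get("max") is None else int(b["max"]),
                _as_points(b.get("points"), f"age band {b['id']!r}"))
        for b in doc["age_bands"]
    )
    # bands must partition the non-negative integers
    expected = 0
    for i, b in enumerate(bands):
        if b.min != expected:
            raise RubricError(
                f"age bands do not partition ages: band {b.id!r} starts at "
                f"{b.min}, expected {expected}")
        if b.max is None:
            if i != len(bands) - 1:
                raise RubricError("only the last age band may be open-ended")
        else:
            expected = b.max + 1
    if bands[-1].max is not None:
        raise RubricError("last age band must be open-ended (max: null)")

    trial = {str(k): _as_points(v, f"trial {k!r}") for k, v in doc["trial"].items()}
    missing = {t.value for t in TrialLevel} - set(trial)
    if missing:
        raise RubricError(f"trial category missing levels: {sorted(missing)}")

    planning_doc = dict(doc["planning"])
    other_max = _as_points(planning_doc.pop("other_max"), "planning.other_max")
    bonus = _as_points(planning_doc.pop("photon_unsafe_bonus"),
                       "planning.photon_unsafe_bonus")
    planning = {str(k): _as_points(v, f"planning {k!r}")
                for k, v in planning_doc.items()}
    if not {"primary", "secondary"} <= set(planning):
        raise RubricError("planning must define 'primary' and 'secondary'")

    risk = {str(k): _as_points(v, f"risk factor {k!r}")
            for k, v in doc["risk_factors"].items()}

    return Rubric(
        version=str(doc["version"]),
        site_groups=tuple(groups),
        retreatment_points=retreat,
        age_bands=bands,
        trial_points=trial,
        planning_points=planning,
        planning_other_max=other_max,
        photon_unsafe_bonus=bonus,
        risk_factor_points=risk,
    )


def load_rubric(source: Union[str, Path, None] = None) -> Rubric:
    """Load a rubric from a YAML/JSON file, or the built-in default.

    The default rubric ships with the package and reproduces the published
    CBS scoring table; loading it, serializing with :func:`dump_rubric`
    and re-loading round-trips identically.
    """
    if source is None:
        text = (resources.files("pbtriage.data") / "default_rubric.yaml").read_text()
    else:
        text = Path(source).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise RubricError(f"cannot parse rubric file: {exc}") from exc
    return _parse_rubric(doc)


def dump_rubric(rubric: Rubric, path: Union[str, Path]) -> None:
    """Serialize a rubric to YAML such that load_rubric round-trips."""
    Path(path).write_text(
        yaml.safe_dump(rubric.to_dict(), sort_keys=False, allow_unicode=True)
    )


# ---------------------------------------------------------------------------
# scoring


def age_band_points(rubric: Rubric, age: int) -> int:
    """Points for the age band containing ``age`` (years, >= 0)."""
    if age < 0:
        raise ProfileError(f"age must be non-negative, got {age}")
    for band in rubric.age_bands:
        if band.contains(age):
            return band.points
    raise RubricError(f"age {age} not covered by any band")  # pragma: no cover


def category_points(category: Category, selected: Iterable[str]) -> int:
    """Score one generic category given selected item/modifier ids.

    Raises :class:`ProfileError` if more than one non-modifier item is
    selected in an exclusive category (only a single point value can be
    assigned per category).
    """
    selected = list(selected)
    items = {it.id: it for it in category.items}
    modifiers = {it.id: it for it in category.modifiers}
    unknown = [s for s in selected if s not in items and s not in modifiers]
    if unknown:
        raise ProfileError(
            f"unknown item(s) {unknown} in category {category.id!r}")
    chosen = [s for s in selected if s in items]
    if category.exclusive and len(chosen) > 1:
        raise ProfileError(
            f"category {category.id!r} is exclusive: only a single point "
            f"value can be assigned per category, got {chosen}")
    total = sum(items[s].points for s in chosen)
    total += sum(modifiers[s].points for s in selected if s in modifiers)
    return total


def validate_profile(rubric: Rubric, profile: PatientProfile) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    violations: list[str] = []
    if profile.site_item_id not in rubric.site_items:
        violations.append(
            f"unknown site item {profile.site_item_id!r}: not a rubric site id")
    if profile.age < 0:
        violations.append(f"age must be non-negative, got {profile.age}")
    if profile.planning_constraint is not PlanningConstraint.OTHER:
        if profile.other_constraint_points != 0:
            violations.append(
                "other_constraint_points must be 0 unless planning constraint "
                "is 'other'")
    else:
        if not 0 <= profile.other_constraint_points <= rubric.planning_other_max:
            violations.append(
                f"other_constraint_points must be in "
                f"[0, {rubric.planning_other_max}], got "
                f"{profile.other_constraint_points}")
    unknown_rf = set(profile.risk_factors) - set(rubric.risk_factor_points)
    if unknown_rf:
        violations.append(f"unknown risk factor(s): {sorted(unknown_rf)}")
    if profile.misc_adjustment != 0 and not profile.misc_annotation.strip():
        violations.append(
            "non-zero miscellaneous adjustment requires review by chairman "
            "and an additional MD: a reviewer annotation must be provided")
    return violations


def score(rubric: Rubric, profile: PatientProfile) -> ScoreBreakdown:
    """Compute the CBS with a per-category audit trail.

    Scoring is a pure function of (rubric, profile).  Within each category a
    single point value is assigned; for risk factors, the highest-point
    factor present scores.  The photon-unsafe bonus is additive on top of
    the planning-constraint choice.
    """
    violations = validate_profile(rubric, profile)
    if violations:
        raise ProfileError("; ".join(violations))

    per: dict[str, int] = {}
    per["site"] = rubric.site_items[profile.site_item_id].points
    per["retreatment"] = rubric.retreatment_points["yes" if profile.retreatment else "no"]
    per["age"] = age_band_points(rubric, profile.age)
    per["trial"] = rubric.trial_points[profile.trial_level.value]

    pc = profile.planning_constraint
    nonstandard = pc is PlanningConstraint.OTHER
    if pc is PlanningConstraint.NONE:
        planning = 0
    elif pc is PlanningConstraint.OTHER:
        planning = profile.other_constraint_points
    else:
        planning = rubric.planning_points[pc.value]
    if profile.photon_unsafe:
        planning += rubric.photon_unsafe_bonus
    per["planning"] = planning

    per["risk"] = max(
        (rubric.risk_factor_points[rf] for rf in profile.risk_factors), default=0
    )
    per["misc"] = profile.misc_adjustment

    total = sum(per.values())
    standard_max = max_score(rubric)
    return ScoreBreakdown(
        per_category=per,
        total=total,
        standard_range=0 <= total <= standard_max,
        nonstandard_planning=nonstandard,
    )


def max_score(rubric: Rubric) -> int:
    """Maximum standard total: one best item per category plus all bonuses.

    Excludes the miscellaneous adjustment and "other" variable planning
    points.  Equals 65 for the default rubric.
    """
    best_site = max(it.points for it in rubric.site_items.values())
    best_age = max(b.points for b in rubric.age_bands)
    best_trial = max(rubric.trial_points.values())
    best_planning = max(rubric.planning_points.values())
    best_risk = max(rubric.risk_factor_points.values(), default=0)
    return (
        best_site
        + max(rubric.retreatment_points.values())
        + best_age
        + best_trial
        + best_planning
        + rubric.photon_unsafe_bonus
        + best_risk
    )


def suggest_site_item(rubric: Rubric, qualifying_item_ids: Sequence[str]) -> str:
    """Advisory helper: among sites a patient qualifies for, suggest the
    maximum-point item (ties broken by rubric order).

    The engine never auto-selects a site; a patient qualifying for several
    must be assigned a single one explicitly.
    """
    items = rubric.site_items
    unknown = [i for i in qualifying_item_ids if i not in items]
    if unknown:
        raise ProfileError(f"unknown site item(s): {unknown}")
    if not qualifying_item_ids:
        raise ProfileError("no qualifying site items given")
    order = {iid: k for k, iid in enumerate(items)}
    return max(qualifying_item_ids, key=lambda i: (items[i].points, -order[i]))
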