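"""Rubric engine: loading, age bands, scoring, max score, validation."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from pbtriage.rubric import (
    PatientProfile,
    PlanningConstraint,
    ProfileError,
    RubricError,
    TrialLevel,
    age_band_points,
    category_points,
    dump_rubric,
    load_rubric,
    max_score,
    score,
    suggest_site_item,
    validate_profile,
)


# ---------------------------------------------------------------------------
# loading

class TestLoadRubric:
    @pytest.mark.parametrize("item_id,points", [
        ("nasopharynx", 10),
        ("larynx", 0),
        ("prostate_sv_only", 2),
        ("base_of_skull_benign_low_grade", 10),
        ("anal", 7),
        ("left_whole_breast", 3),
    ])
    def test_default_site_points(self, rubric, item_id, points):
        assert rubric.site_items[item_id].points == points

    def test_default_category_points(self, rubric):
        assert rubric.retreatment_points == {"yes": 10, "no": 0}
        assert rubric.trial_points == {"randomized": 10, "interventional": 6,
                                       "registry": 3, "off_protocol": 0}
        assert rubric.planning_points == {"primary": 5, "secondary": 10}
        assert rubric.photon_unsafe_bonus == 5
        assert rubric.risk_factor_points == {"SLE_scleroderma": 5, "IBD": 5,
                                             "other_genetic": 5, "HIV": 3}

    def test_item_ids_unique(self, rubric):
        ids = [it.id for g in rubric.site_groups for it in g.items]
        assert len(ids) == len(set(ids))

    def test_round_trip(self, rubric, tmp_path):
        path = tmp_path / "rubric.yaml"
        dump_rubric(rubric, path)
        assert load_rubric(path) == rubric

    def test_malformed_file_names_field(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("version: '1'\nsite: {groups: []}\n")
        with pytest.raises(RubricError, match="retreatment|missing"):
            load_rubric(path)

    def test_duplicate_item_ids_rejected(self, rubric, tmp_path):
        doc = rubric.to_dict()
        doc["site"]["groups"][0]["items"].append(
            {"id": "nasopharynx", "label": "dup", "points": 1})
        import yaml
        path = tmp_path / "dup.yaml"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(RubricError, match="duplicate"):
            load_rubric(path)

    def test_negative_points_rejected(self, rubric, tmp_path):
        doc = rubric.to_dict()
        doc["trial"]["registry"] = -3
        import yaml
        path = tmp_path / "neg.yaml"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(RubricError, match="non-negative"):
            load_rubric(path)


# ---------------------------------------------------------------------------
# age bands

class TestAgeBands:
    @pytest.mark.parametrize("age,points", [
        (0, 15), (12, 15), (20, 15),
        (21, 10),  # the unassigned age 21 is merged into the 10-point band
        (22, 10), (39, 10),
        (40, 5), (49, 5),
        (50, 3), (59, 3),
        (60, 0), (65, 0), (120, 0),
    ])
    def test_band_points(self, rubric, age, points):
        assert age_band_points(rubric, age) == points

    def test_bands_partition_all_ages(self, rubric):
        # every age 0..120 falls in exactly one band
        for age in range(121):
            n = sum(b.contains(age) for b in rubric.age_bands)
            assert n == 1, f"age {age} in {n} bands"

    def test_negative_age_rejected(self, rubric):
        with pytest.raises(ProfileError, match="non-negative"):
            age_band_points(rubric, -1)


# ---------------------------------------------------------------------------
# scoring

class TestScore:
    def test_worked_maximum_profile(self, rubric, max_profile):
        bd = score(rubric, max_profile)
        assert bd.total == 65
        assert bd.per_category == {"site": 10, "retreatment": 10, "age": 15,
                                   "trial": 10, "planning": 15, "risk": 5,
                                   "misc": 0}
        assert bd.standard_range

    def test_worked_zero_profile(self, rubric, zero_profile):
        bd = score(rubric, zero_profile)
        assert bd.total == 0
        assert bd.standard_range

    def test_worked_five_point_profile(self, rubric, five_point_profile):
        assert score(rubric, five_point_profile).total == 5

    def test_photon_unsafe_adds_on_top_of_planning(self, rubric, zero_profile):
        from dataclasses import replace
        p = replace(zero_profile, planning_constraint=PlanningConstraint.PRIMARY,
                    photon_unsafe=True)
        assert score(rubric, p).per_category["planning"] == 10

    def test_risk_factors_score_single_highest(self, rubric, zero_profile):
        from dataclasses import replace
        p = replace(zero_profile,
                    risk_factors=frozenset({"HIV", "IBD", "SLE_scleroderma"}))
        assert score(rubric, p).per_category["risk"] == 5

    def test_other_planning_points_flagged_nonstandard(self, rubric, zero_profile):
        from dataclasses import replace
        p = replace(zero_profile, planning_constraint=PlanningConstraint.OTHER,
                    other_constraint_points=3)  # e.g. hippocampus
        bd = score(rubric, p)
        assert bd.total == 3
        assert bd.nonstandard_planning

    def test_misc_adjustment_included_and_range_flagged(self, rubric, max_profile):
        from dataclasses import replace
        p = replace(max_profile, misc_adjustment=7,
                    misc_annotation="chairman approved")
        bd = score(rubric, p)
        assert bd.total == 72
        assert not bd.standard_range

    def test_unknown_site_raises(self, rubric, zero_profile):
        from dataclasses import replace
        with pytest.raises(ProfileError, match="unknown site"):
            score(rubric, replace(zero_profile, site_item_id="pancreas"))

    def test_exclusive_category_rejects_double_selection(self, rubric):
        site_cat = rubric.categories[0]
        with pytest.raises(ProfileError, match="single point value"):
            category_points(site_cat, ["nasopharynx", "larynx"])

    def test_scoring_is_pure(self, rubric, max_profile):
        assert score(rubric, max_profile) == score(rubric, max_profile)


# ---------------------------------------------------------------------------
# max score

def _brute_force_max(rubric):
    """Oracle: exhaustive cross-product over standard category choices."""
    site = [it.points for it in rubric.site_items.values()]
    retreat = list(rubric.retreatment_points.values())
    age = [b.points for b in rubric.age_bands]
    trial = list(rubric.trial_points.values())
    planning = [0] + list(rubric.planning_points.values())
    photon = [0, rubric.photon_unsafe_bonus]
    risk = [0] + list(rubric.risk_factor_points.values())
    return max(sum(combo) for combo in
               itertools.product(site, retreat, age, trial, planning, photon,
                                 risk))


class TestMaxScore:
    def test_default_is_65(self, rubric):
        assert max_score(rubric) == 65

    def test_matches_brute_force(self, rubric):
        assert max_score(rubric) == _brute_force_max(rubric)

    def test_zeroed_rubric(self, rubric, tmp_path):
        import yaml
        doc = rubric.to_dict()
        for g in doc["site"]["groups"]:
            for it in g["items"]:
                it["points"] = 0
        for k in doc["retreatment"]:
            doc["retreatment"][k] = 0
        for b in doc["age_bands"]:
            b["points"] = 0
        for k in doc["trial"]:
            doc["trial"][k] = 0
        doc["planning"] = {"primary": 0, "secondary": 0, "other_max": 0,
                           "photon_unsafe_bonus": 0}
        for k in doc["risk_factors"]:
            doc["risk_factors"][k] = 0
        path = tmp_path / "zero.yaml"
        path.write_text(yaml.safe_dump(doc))
        assert max_score(load_rubric(path)) == 0

    def test_without_photon_bonus_is_60(self, rubric, tmp_path):
        import yaml
        doc = rubric.to_dict()
        doc["planning"]["photon_unsafe_bonus"] = 0
        path = tmp_path / "nobonus.yaml"
        path.write_text(yaml.safe_dump(doc))
        r = load_rubric(path)
        assert max_score(r) == 60
        assert max_score(r) == _brute_force_max(r)


# ---------------------------------------------------------------------------
# validation

class TestValidateProfile:
    def test_valid_profile_empty(self, rubric, five_point_profile):
        assert validate_profile(rubric, five_point_profile) == []

    def test_misc_without_annotation(self, rubric, zero_profile):
        from dataclasses import replace
        p = replace(zero_profile, misc_adjustment=5)
        violations = validate_profile(rubric, p)
        assert len(violations) == 1
        assert "chairman" in violations[0]

    def test_unknown_site_item(self, rubric, zero_profile):
        from dataclasses import replace
        p = replace(zero_profile, site_item_id="pancreas")
        violations = validate_profile(rubric, p)
        assert len(violations) == 1
        assert "unknown site" in violations[0]

    def test_other_points_require_other_constraint(self, rubric, zero_profile):
        from dataclasses import replace
        p = replace(zero_profile, other_constraint_points=3)
        assert any("other_constraint_points" in v
                   for v in validate_profile(rubric, p))

    def test_other_points_capped(self, rubric, zero_profile):
        from dataclasses import replace
        p = replace(zero_profile, planning_constraint=PlanningConstraint.OTHER,
                    other_constraint_points=11)
        assert any("[0, 10]" in v for v in validate_profile(rubric, p))


def test_suggest_site_item_picks_max_points(rubric):
    assert suggest_site_item(rubric, ["larynx", "oropharynx", "nasopharynx"]) \
        == "nasopharynx"
    with pytest.raises(ProfileError):
        suggest_site_item(rubric, ["not_a_site"])


# ---------------------------------------------------------------------------
# properties

RUBRIC = load_rubric()

valid_profiles = st.builds(
    PatientProfile,
    patient_id=st.just("h"),
    site_item_id=st.sampled_from(sorted(RUBRIC.site_items)),
    age=st.integers(0, 100),
    retreatment=st.booleans(),
    trial_level=st.sampled_from(list(TrialLevel)),
    planning_constraint=st.sampled_from([
        PlanningConstraint.NONE, PlanningConstraint.PRIMARY,
        PlanningConstraint.SECONDARY]),
    photon_unsafe=st.booleans(),
    risk_factors=st.frozensets(
        st.sampled_from(sorted(RUBRIC.risk_factor_points))),
)


@settings(max_examples=200, deadline=None)
@given(profile=valid_profiles)
def test_standard_profiles_score_within_bounds(profile):
    """Any valid standard profile (no misc, no 'other' planning) scores in
    [0, max_score] and is flagged standard-range."""
    bd = score(RUBRIC, profile)
    assert 0 <= bd.total <= max_score(RUBRIC) == 65
    assert bd.standard_range


@settings(max_examples=100, deadline=None)
@given(profile=valid_profiles, data=st.data())
def test_score_monotone_in_site_points(profile, data):
    """Swapping the selected site for one with >= points never lowers the
    total (monotonicity in each component)."""
    from dataclasses import replace
    current = RUBRIC.site_items[profile.site_item_id].points
    higher = [i for i, it in RUBRIC.site_items.items() if it.points >= current]
    other = data.draw(st.sampled_from(sorted(higher)))
    assert score(RUBRIC, replace(profile, site_item_id=other)).total \
        >= score(RUBRIC, profile).total
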