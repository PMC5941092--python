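import pytest

from helpers import make_record
from surveyscreen import (
    RULE_REGISTRY,
    Indicator,
    RuleConfig,
    StrikeCategory,
    check_completion_time,
    check_geo_consistency,
    collect_strikes,
    evaluate_clinical_profile,
    evaluate_response_style,
    indicator_categories,
)
from surveyscreen.audit import AuditLog

CFG = RuleConfig()


# -------------------------------------------------------------------- registry
def test_registry_exposes_exactly_the_eight_indicator_categories():
    """The default rule registry covers the eight classic suspicious-survey
    characteristics, no more and no fewer."""
    assert indicator_categories() == frozenset(Indicator)
    assert len(frozenset(Indicator)) == 8


def test_every_rule_has_a_valid_category():
    assert all(info.category in StrikeCategory for info in RULE_REGISTRY.values())


# ------------------------------------------------------------- completion time
@pytest.mark.parametrize(
    "duration,expected",
    [(25, True), (50, False), (30, False)],  # boundary is strict
)
def test_absolute_speeding_floor(duration, expected):
    r = make_record("a", duration_min=duration)
    strike = check_completion_time(r, None, CFG)
    assert (strike is not None) is expected
    if strike:
        assert strike.rule_id == "completion_time"


def test_relative_speed_uses_cohort_median():
    cfg = RuleConfig(relative_speed_enabled=True, duration_min_minutes=10)
    r = make_record("a", duration_min=14)
    assert check_completion_time(r, 60.0, cfg) is not None  # 14 < 60/3
    assert check_completion_time(r, 30.0, cfg) is None  # 14 >= 30/3


# ------------------------------------------------------------- geo consistency
def test_matching_regions_no_strike(geo):
    r = make_record("a", ip="100.64.0.9", zip_code="10001")  # both NY
    assert check_geo_consistency(r, geo) is None


def test_mismatched_regions_strike(geo):
    r = make_record("a", ip="100.64.32.9", zip_code="10001")  # CA ip, NY zip
    strike = check_geo_consistency(r, geo)
    assert strike is not None and strike.rule_id == "geo_mismatch"


def test_unknown_prefix_is_unverifiable_not_a_strike(geo):
    r = make_record("a", ip="198.51.100.1", zip_code="10001")
    audit = AuditLog()
    assert check_geo_consistency(r, geo, audit) is None
    assert any("unverifiable" in n.message for n in audit.notes)


# ------------------------------------------------------------ clinical profile
def _rules(strikes):
    return sorted(s.rule_id for s in strikes)


def test_young_age_high_psa_high_gleason_three_strikes():
    r = make_record("a", age_at_diagnosis=28, psa_at_diagnosis=25.0, gleason_total=8)
    assert _rules(evaluate_clinical_profile(r, CFG)) == [
        "age_at_diagnosis",
        "gleason_implausible",
        "psa_implausible",
    ]


def test_benign_profile_no_strikes():
    r = make_record(
        "a",
        age_at_diagnosis=63,
        psa_at_diagnosis=6.5,
        gleason_total=6,
        treatment_history=[("active_surveillance", "urologist"), ("prostatectomy", "urologist")],
    )
    assert evaluate_clinical_profile(r, CFG) == []


def test_impossible_treatment_sequence_is_one_strike():
    r = make_record(
        "a",
        age_at_diagnosis=63,
        psa_at_diagnosis=6.5,
        gleason_total=6,
        treatment_history=[
            ("prostatectomy", "urologist"),
            ("watchful_waiting", "urologist"),
            ("radiation", "radiation_oncologist"),
            ("diet", "none"),
        ],
    )
    # two forbidden transitions appear, but the sequence rule caps at one strike
    assert _rules(evaluate_clinical_profile(r, CFG)) == ["treatment_sequence"]


def test_radiation_from_urologist_is_provider_mismatch():
    r = make_record(
        "a",
        age_at_diagnosis=63,
        psa_at_diagnosis=6.5,
        gleason_total=6,
        treatment_history=[("radiation", "urologist")],
    )
    assert _rules(evaluate_clinical_profile(r, CFG)) == ["provider_mismatch"]


def test_disclosure_gated_rehab_without_disclosure():
    r = make_record(
        "a",
        age_at_diagnosis=63,
        psa_at_diagnosis=6.5,
        gleason_total=6,
        rehab_recommendations=["dilator"],
        disclosure_to_provider=False,
    )
    assert _rules(evaluate_clinical_profile(r, CFG)) == ["disclosure_rehab"]


def test_peripheral_only_discrimination_profile():
    r = make_record(
        "a",
        age_at_diagnosis=63,
        psa_at_diagnosis=6.5,
        gleason_total=6,
        discrimination_attributes=["weight", "height", "appearance"],
    )
    assert _rules(evaluate_clinical_profile(r, CFG)) == ["discrimination_profile"]


def test_all_core_items_forgotten_on_complete_survey():
    r = make_record("a")
    assert _rules(evaluate_clinical_profile(r, CFG)) == ["clinical_missing"]


# -------------------------------------------------------------- response style
def test_straight_lined_grid_strikes():
    r = make_record("a", grid_responses={"g": [3.0] * 10})
    strikes = evaluate_response_style(r, CFG)
    assert _rules(strikes) == ["straight_lining"]
    assert "0.10" in strikes[0].evidence


def test_small_grid_exempt_from_straight_lining():
    r = make_record("a", grid_responses={"g": [3.0] * 4})
    assert evaluate_response_style(r, CFG) == []


def test_high_nonresponse_strikes():
    r = make_record("a", grid_responses={"g": [1.0, 2.0, None, None, 3.0, 4.0, 5.0, 1.0, None, None]})
    assert _rules(evaluate_response_style(r, CFG)) == ["nonresponse"]


def test_all_blank_text_strikes():
    r = make_record("a", text_responses={"q1": "", "q2": "  "})
    assert _rules(evaluate_response_style(r, CFG)) == ["text_quality"]


def test_gibberish_text_strikes():
    r = make_record("a", text_responses={"q1": "sdfk qwrt zzzz"})
    strikes = evaluate_response_style(r, CFG)
    assert _rules(strikes) == ["text_quality"]
    assert "vowel" in strikes[0].evidence


def test_duplicated_text_strikes_once():
    r = make_record(
        "a",
        text_responses={"q1": "it was hard", "q2": "it was hard", "q3": "fine"},
    )
    assert _rules(evaluate_response_style(r, CFG)) == ["text_quality"]


def test_all_options_selected_in_multi_response():
    r = make_record(
        "a",
        discrimination_attributes=["weight", "height", "appearance", "race", "sexual_orientation"],
    )
    assert _rules(evaluate_response_style(r, CFG)) == ["all_options"]


def test_failed_verification_item_strikes():
    r = make_record("a", verification_items={"v1": (2.0, 5.0)})
    strikes = evaluate_response_style(r, CFG)
    assert _rules(strikes) == ["verification"]


def test_clean_record_no_style_strikes():
    r = make_record(
        "a",
        grid_responses={"g": [1.0, 4.0, 2.0, 5.0, 3.0, 2.0, 4.0, 1.0]},
        text_responses={"q1": "surgery went well", "q2": "more support please"},
        verification_items={"v1": (2.0, 2.0)},
    )
    assert evaluate_response_style(r, CFG) == []


# ----------------------------------------------------- purity & rule disabling
def _spammy_record():
    return make_record(
        "a",
        duration_min=10,
        age_at_diagnosis=22,
        psa_at_diagnosis=44.0,
        gleason_total=9,
        text_responses={"q1": ""},
    )


def test_rules_are_pure_and_batch_independent(geo):
    r = _spammy_record()
    first = collect_strikes(r, None, geo, CFG)
    second = collect_strikes(r, None, geo, CFG)
    assert first == second


def test_disabling_a_rule_removes_exactly_its_strikes(geo):
    r = _spammy_record()
    full = collect_strikes(r, None, geo, CFG)
    cfg = RuleConfig(disabled_rules={"psa_implausible"})
    reduced = collect_strikes(r, None, geo, cfg)
    assert {s.rule_id for s in full} - {s.rule_id for s in reduced} == {"psa_implausible"}
    assert [s for s in full if s.rule_id != "psa_implausible"] == reduced


def test_strikes_per_record_bounded_by_registered_rules(geo):
    r = _spammy_record()
    strikes = collect_strikes(r, None, geo, CFG)
    assert len(strikes) <= len(RULE_REGISTRY)
    assert len({s.rule_id for s in strikes}) == len(strikes)
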