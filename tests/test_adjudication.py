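import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_record
from surveyscreen import (
    CohortScenario,
    CompletionStatus,
    DecisionStatus,
    ProtocolError,
    RuleConfig,
    SpamWave,
    Strike,
    StrikeCategory,
    adjudicate,
    collect_strikes,
    generate_cohort,
    monitor_drift,
    retrospective_pass,
    run_protocol,
)

CFG = RuleConfig()


def _strikes(n):
    return [Strike(f"rule{i}", StrikeCategory.metadata, f"e{i}") for i in range(n)]


# ------------------------------------------------------------------ adjudicate
@pytest.mark.parametrize(
    "n_strikes,expected",
    [(3, DecisionStatus.invalid), (1, DecisionStatus.review), (0, DecisionStatus.valid)],
)
def test_k_strikes_rule_on_complete_records(n_strikes, expected):
    d = adjudicate(make_record("a"), _strikes(n_strikes), CFG)
    assert d.status == expected
    assert d.strike_count == n_strikes


def test_partial_record_invalid_even_with_zero_strikes():
    r = make_record("a", completion_status=CompletionStatus.partial)
    d = adjudicate(r, [], CFG)
    assert d.status == DecisionStatus.invalid
    assert d.reason_codes == ["incomplete"]


def test_partial_record_keeps_strike_evidence():
    r = make_record("a", completion_status=CompletionStatus.partial)
    d = adjudicate(r, _strikes(2), CFG)
    assert d.status == DecisionStatus.invalid
    assert d.reason_codes[0] == "incomplete"
    assert d.strike_count == 2


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=6), st.booleans())
def test_adding_a_strike_never_moves_toward_valid(n, partial):
    r = make_record(
        "a",
        completion_status=CompletionStatus.partial if partial else CompletionStatus.complete,
    )
    before = adjudicate(r, _strikes(n), CFG)
    after = adjudicate(r, _strikes(n + 1), CFG)
    assert after.status.rank >= before.status.rank


def test_single_strike_never_invalid_when_complete():
    for k in (2, 3, 4):
        cfg = RuleConfig(strike_threshold_k=k)
        d = adjudicate(make_record("a"), _strikes(1), cfg)
        assert d.status == DecisionStatus.review


# ---------------------------------------------------------------- run_protocol
def _era(config_id, start, end, **kw):
    return RuleConfig(
        config_id=config_id,
        effective_start=dt.date.fromisoformat(start) if start else None,
        effective_end=dt.date.fromisoformat(end) if end else None,
        **kw,
    )


def test_single_era_equals_per_record_adjudication(geo):
    scenario = CohortScenario(
        n_valid=30, waves=[SpamWave(start_day=2, n=10, profile="naive")], seed=5
    )
    records, _ = generate_cohort(scenario)
    from surveyscreen import build_dedup_context
    from surveyscreen.adjudicate import cohort_median_duration

    got = run_protocol(records, [CFG], geo)
    ctx = build_dedup_context(records, CFG)
    med = cohort_median_duration(records)
    expected = [
        adjudicate(r, collect_strikes(r, ctx, geo, CFG, med), CFG) for r in records
    ]
    assert got == expected


def test_era_assignment_uses_end_date(geo):
    era1 = _era("era1", "2015-10-21", "2015-11-05")
    era2 = _era("era2", "2015-11-05", "2016-01-02", duration_min_minutes=35)
    in_era1 = make_record("a", start="2015-11-01T10:00:00-05:00", duration_min=32)
    in_era2 = make_record("b", start="2015-11-20T10:00:00-05:00", duration_min=32)
    decisions = run_protocol([in_era1, in_era2], [era1, era2], geo)
    by_id = {d.submission_id: d for d in decisions}
    assert "completion_time" not in by_id["a"].reason_codes  # 32 >= era1's 30
    assert "completion_time" in by_id["b"].reason_codes  # 32 < era2's 35
    assert by_id["a"].config_id == "era1" and by_id["b"].config_id == "era2"


def test_record_outside_all_eras_raises(geo):
    era = _era("era1", "2015-10-21", "2015-11-05")
    stray = make_record("ghost", start="2016-03-01T10:00:00-05:00")
    with pytest.raises(ProtocolError, match="ghost"):
        run_protocol([stray], [era], geo)


def test_overlapping_eras_rejected(geo):
    era1 = _era("era1", "2015-10-21", "2015-11-10")
    era2 = _era("era2", "2015-11-05", "2016-01-02")
    with pytest.raises(ProtocolError, match="overlap"):
        run_protocol([], [era1, era2], geo)


def test_empty_record_list_yields_empty_decisions(geo):
    assert run_protocol([], [CFG], geo) == []


# ---------------------------------------------------------- retrospective pass
def test_strict_era_decision_relaxed_by_final_config(geo):
    strict = _era("strict", "2015-10-21", "2016-01-02", duration_min_minutes=45,
                  strike_threshold_k=2)
    # 40-minute record with one other anomaly: invalid under strict era
    r = make_record(
        "a",
        start="2015-11-01T10:00:00-05:00",
        duration_min=40,
        age_at_diagnosis=63,
        psa_at_diagnosis=6.0,
        gleason_total=6,
        verification_items={"v1": (2.0, 5.0)},
        text_responses={"q": "surgery went well overall"},
    )
    era_decisions = run_protocol([r], [strict], geo)
    assert era_decisions[0].status == DecisionStatus.invalid
    pairs = retrospective_pass([r], [strict], CFG, geo)
    assert pairs == [("a", DecisionStatus.invalid, DecisionStatus.review)]


def test_retrospective_pass_is_idempotent(geo):
    scenario = CohortScenario(
        n_valid=20, waves=[SpamWave(start_day=2, n=6, profile="naive")], seed=9
    )
    records, _ = generate_cohort(scenario)
    first = retrospective_pass(records, [CFG], CFG, geo)
    second = retrospective_pass(records, [CFG], CFG, geo)
    assert first == second
    assert retrospective_pass([], [CFG], CFG, geo) == []


# --------------------------------------------------------------- drift monitor
def test_drift_alert_when_clinical_rates_collapse(geo):
    """Naive wave then evolved wave: clinical hit rates collapse while the
    email-convention signature persists — the monitor must alert on the
    clinical rule and stay quiet on the metadata one."""
    scenario = CohortScenario(
        n_valid=0,
        waves=[
            SpamWave(start_day=0, n=20, profile="naive"),
            SpamWave(start_day=7, n=20, profile="evolved"),
        ],
        seed=2,
    )
    records, _ = generate_cohort(scenario)
    decisions = run_protocol(records, [CFG], geo)
    report = monitor_drift(decisions, CFG)
    assert len(report.windows) >= 2
    alerted = {a.rule_id for a in report.alerts}
    assert "age_at_diagnosis" in alerted
    assert "email_convention" not in alerted


def test_constant_rates_produce_no_alerts():
    from surveyscreen import Decision

    decisions = []
    for w, day0 in enumerate((dt.date(2015, 11, 1), dt.date(2015, 11, 8))):
        for i in range(10):
            strikes = [
                Strike("completion_time", StrikeCategory.metadata, "short"),
                Strike("email_convention", StrikeCategory.dedup, "convention"),
            ]
            decisions.append(
                Decision(
                    submission_id=f"s{w}{i}",
                    strikes=strikes,
                    strike_count=2,
                    status=DecisionStatus.review,
                    reason_codes=[s.rule_id for s in strikes],
                    config_id="default",
                    end_date=day0 + dt.timedelta(days=i % 7),
                )
            )
    report = monitor_drift(decisions, CFG)
    assert len(report.windows) == 2
    assert report.alerts == []


def test_single_window_yields_empty_report(geo):
    scenario = CohortScenario(
        n_valid=0, waves=[SpamWave(start_day=0, n=6, profile="naive")], seed=4
    )
    records, _ = generate_cohort(scenario)
    decisions = run_protocol(records, [CFG], geo)
    report = monitor_drift(decisions, CFG)
    assert report.windows == [] and report.alerts == []
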