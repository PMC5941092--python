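import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_record
from oracles import (
    brute_adjacency,
    brute_duplicate_ips,
    brute_email_convention,
    brute_odd_hour,
    brute_shared_anomaly,
)
from surveyscreen import (
    RuleConfig,
    build_dedup_context,
    detect_odd_hour,
    detect_shared_anomaly,
    email_signature,
    find_duplicate_ips,
    find_temporal_adjacency,
    score_email_convention,
)

CFG = RuleConfig()


# ---------------------------------------------------------------- duplicate IP
def test_two_records_sharing_ip_form_one_group():
    records = [make_record("a", ip="203.0.113.5"), make_record("b", ip="203.0.113.5")]
    assert find_duplicate_ips(records) == [{"a", "b"}]


def test_distinct_ips_yield_no_groups():
    records = [make_record(s, ip=f"203.0.113.{i}") for i, s in enumerate("abc")]
    assert find_duplicate_ips(records) == []


def test_three_of_five_sharing_ip_matches_bruteforce():
    records = [
        make_record("a", ip="203.0.113.5"),
        make_record("b", ip="203.0.113.9"),
        make_record("c", ip="203.0.113.5"),
        make_record("d", ip="203.0.113.5"),
        make_record("e", ip="203.0.113.77"),
    ]
    got = find_duplicate_ips(records)
    assert got == [{"a", "c", "d"}]
    assert got == brute_duplicate_ips(records)


def test_missing_ip_is_ignored_for_grouping():
    records = [make_record("a", ip=None), make_record("b", ip=None)]
    assert find_duplicate_ips(records) == []


# ------------------------------------------------------------ email convention
def test_signature_run_length_classes():
    assert email_signature("abc123") == "L3D3"
    assert email_signature("john.smith") == "L4O1L5"
    assert email_signature("a1b2") == "L1D1L1D1"


def test_convention_trio_flagged_at_one_host():
    records = [
        make_record("a", email="abc123@me.com"),
        make_record("b", email="qrs789@me.com"),
        make_record("c", email="xyz456@me.com"),
    ]
    assert score_email_convention(records, CFG) == {"a", "b", "c"}


def test_pair_below_cluster_minimum_not_flagged():
    records = [
        make_record("a", email="abc123@me.com"),
        make_record("b", email="qrs789@me.com"),
    ]
    assert score_email_convention(records, CFG) == set()


def test_personalized_handle_outside_cluster_not_flagged():
    records = [
        make_record("a", email="abc123@me.com"),
        make_record("b", email="qrs789@me.com"),
        make_record("c", email="xyz456@me.com"),
        make_record("d", email="john.smith@gmail.com"),
    ]
    got = score_email_convention(records, CFG)
    assert got == {"a", "b", "c"}
    assert got == brute_email_convention(records, CFG.email_cluster_min)


# ---------------------------------------------------------- temporal adjacency
def _timed(sid, start_minute, duration=30):
    base = dt.datetime(2015, 11, 1, 8, 0, tzinfo=dt.timezone.utc)
    start = base + dt.timedelta(minutes=start_minute)
    return make_record(sid, start=start.isoformat(), duration_min=duration)


def test_start_seconds_after_end_flags_both():
    a = _timed("a", 0, duration=30)  # ends 08:30
    b = make_record("b", start="2015-11-01T08:30:10+00:00", duration_min=30)
    assert find_temporal_adjacency([a, b], CFG) == {"a", "b"}


def test_wide_gap_not_flagged():
    a = _timed("a", 0, duration=30)
    b = _timed("b", 90, duration=30)  # 3600 s after a's end
    assert find_temporal_adjacency([a, b], CFG) == set()


def test_chain_propagates_and_matches_bruteforce():
    a = _timed("a", 0, duration=30)
    b = make_record("b", start="2015-11-01T08:30:05+00:00", duration_min=30)
    c = make_record("c", start="2015-11-01T09:00:10+00:00", duration_min=30)
    records = [a, b, c]
    got = find_temporal_adjacency(records, CFG)
    assert got == {"a", "b", "c"}
    assert got == brute_adjacency(records, CFG.adjacency_gap_seconds)


def test_zero_gap_is_not_adjacency():
    a = _timed("a", 0, duration=30)
    b = _timed("b", 30, duration=30)  # starts exactly when a ends
    assert find_temporal_adjacency([a, b], CFG) == set()


# -------------------------------------------------------------------- odd hour
@pytest.mark.parametrize(
    "end,expected",
    [
        ("2015-11-01T02:30:00-06:00", True),
        ("2015-11-01T14:00:00-06:00", False),
        ("2015-11-01T05:00:00-06:00", False),  # half-open boundary
        ("2015-11-01T00:00:00-06:00", True),
    ],
)
def test_odd_hour_window_is_half_open_local(end, expected):
    start = (dt.datetime.fromisoformat(end) - dt.timedelta(minutes=50)).isoformat()
    r = make_record("a", start=start, end=end)
    assert (detect_odd_hour([r], CFG) == {"a"}) is expected


# -------------------------------------------------------------- shared anomaly
def test_three_identical_birth_dates_group():
    records = [
        make_record(s, birth_date=dt.date(1901, 1, 1)) for s in ("a", "b", "c")
    ]
    assert detect_shared_anomaly(records, "birth_date", CFG) == [{"a", "b", "c"}]


def test_distinct_birth_dates_no_group():
    records = [
        make_record("a", birth_date=dt.date(1950, 3, 4)),
        make_record("b", birth_date=dt.date(1951, 5, 6)),
    ]
    assert detect_shared_anomaly(records, "birth_date", CFG) == []


def test_pair_below_anomaly_minimum_no_group():
    records = [
        make_record(s, birth_date=dt.date(1901, 1, 1)) for s in ("a", "b")
    ]
    assert detect_shared_anomaly(records, "birth_date", CFG) == []


# ------------------------------------------------- property: oracle equivalence
_ips = st.sampled_from(["10.0.0.1", "10.0.0.2", "10.0.0.3", None])
_births = st.sampled_from(
    [dt.date(1901, 1, 1), dt.date(1950, 2, 3), dt.date(1955, 6, 7), None]
)
_emails = st.sampled_from(
    ["abc123@me.com", "def456@me.com", "ghi789@me.com", "john.smith@x.com", None]
)


@st.composite
def record_batches(draw, max_size=14):
    n = draw(st.integers(min_value=0, max_value=max_size))
    records = []
    for i in range(n):
        start_min = draw(st.integers(min_value=0, max_value=600))
        duration = draw(st.integers(min_value=1, max_value=90))
        base = dt.datetime(2015, 11, 1, 0, 0, tzinfo=dt.timezone.utc)
        start = base + dt.timedelta(minutes=start_min, seconds=draw(st.integers(0, 59)))
        records.append(
            make_record(
                f"r{i}",
                start=start.isoformat(),
                duration_min=duration,
                ip=draw(_ips),
                email=draw(_emails),
                birth_date=draw(_births),
            )
        )
    return records


@settings(max_examples=60, derandomize=True, deadline=None)
@given(record_batches())
def test_signals_equal_bruteforce_oracles(records):
    """Every dataset-level signal equals its all-pairs reference."""
    assert find_duplicate_ips(records) == brute_duplicate_ips(records)
    assert score_email_convention(records, CFG) == brute_email_convention(
        records, CFG.email_cluster_min
    )
    assert find_temporal_adjacency(records, CFG) == brute_adjacency(
        records, CFG.adjacency_gap_seconds
    )
    assert detect_odd_hour(records, CFG) == brute_odd_hour(
        records, CFG.odd_hour_start, CFG.odd_hour_end
    )
    assert detect_shared_anomaly(records, "birth_date", CFG) == brute_shared_anomaly(
        records, "birth_date", CFG.shared_anomaly_min
    )


@settings(max_examples=40, derandomize=True, deadline=None)
@given(record_batches(), st.randoms(use_true_random=False))
def test_signals_are_order_invariant(records, rnd):
    shuffled = list(records)
    rnd.shuffle(shuffled)
    ctx_a = build_dedup_context(records, CFG)
    ctx_b = build_dedup_context(shuffled, CFG)
    assert ctx_a.ip_groups == ctx_b.ip_groups
    assert ctx_a.email_clusters == ctx_b.email_clusters
    assert ctx_a.adjacency_flags == ctx_b.adjacency_flags
    assert ctx_a.odd_hour_ids == ctx_b.odd_hour_ids
    assert ctx_a.shared_anomaly_groups == ctx_b.shared_anomaly_groups


def _flat(groups):
    return set().union(*groups) if groups else set()


@settings(max_examples=40, derandomize=True, deadline=None)
@given(record_batches(max_size=10), record_batches(max_size=3))
def test_adding_records_never_removes_flags(records, extra):
    """Group-membership signals are monotone under batch growth."""
    for r, i in zip(extra, range(len(extra))):
        r.submission_id = f"x{i}"
    before = build_dedup_context(records, CFG)
    after = build_dedup_context(records + extra, CFG)
    assert _flat(before.ip_groups) <= _flat(after.ip_groups)
    assert _flat(before.email_clusters) <= _flat(after.email_clusters)
    assert before.adjacency_flags <= after.adjacency_flags
    assert before.odd_hour_ids <= after.odd_hour_ids
    for f, groups in before.shared_anomaly_groups.items():
        assert _flat(groups) <= _flat(after.shared_anomaly_groups[f])
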