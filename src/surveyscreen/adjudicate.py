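"""Adjudication: the k-strikes rule, protocol eras, retrospective pass, drift.

A submission is invalid when it is incomplete (always, regardless of
strikes), or when it accrues at least ``strike_threshold_k`` strikes. One
to k-1 strikes send it to a manual review queue; zero strikes mean valid.
Because k >= 2 is enforced in configuration, no single indicator can ever
invalidate a complete submission.

A protocol history is a list of rule configurations with non-overlapping
effective windows ("dynamic protocol"); each record is adjudicated under
the era containing its end date. A retrospective pass re-applies one
final uniform configuration to everything, mirroring the recommended
retrospective analysis phase after recruitment ends. The drift monitor
tracks per-rule hit rates among flagged submissions across time windows
and raises alerts on jumps, so an evolving spam style (clinical values
drifting into the plausible range while metadata conventions persist) is
surfaced instead of silently eroding the protocol.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from statistics import median
from typing import Optional

from .audit import AuditLog
from .config import RuleConfig
from .dedup import build_dedup_context
from .exceptions import ProtocolError
from .geo import GeoTable
from .model import (
    CompletionStatus,
    Decision,
    DecisionStatus,
    Strike,
    SubmissionRecord,
)
from .rules import RULE_REGISTRY, collect_strikes


def adjudicate(
    record: SubmissionRecord, strikes: list[Strike], config: RuleConfig
) -> Decision:
    """Combine strikes into a decision under the k-strikes rule."""
    reasons = [s.rule_id for s in strikes]
    if record.completion_status == CompletionStatus.partial:
        status = DecisionStatus.invalid
        reasons = ["incomplete"] + reasons
    elif len(strikes) >= config.strike_threshold_k:
        status = DecisionStatus.invalid
    elif strikes:
        status = DecisionStatus.review
    else:
        status = DecisionStatus.valid
    return Decision(
        submission_id=record.submission_id,
        strikes=list(strikes),
        strike_count=len(strikes),
        status=status,
        reason_codes=reasons,
        config_id=config.config_id,
        end_date=record.end_date,
    )


def _check_windows(config_history: list[RuleConfig]) -> None:
    if not config_history:
        raise ProtocolError("config_history is empty")
    dated = [c for c in config_history if c.effective_start or c.effective_end]
    for i, a in enumerate(dated):
        for b in dated[i + 1:]:
            a_start = a.effective_start or dt.date.min
            a_end = a.effective_end or dt.date.max
            b_start = b.effective_start or dt.date.min
            b_end = b.effective_end or dt.date.max
            if a_start < b_end and b_start < a_end:
                raise ProtocolError(
                    f"configs {a.config_id!r} and {b.config_id!r} have overlapping "
                    "effective windows"
                )
    open_ended = [c for c in config_history if not (c.effective_start or c.effective_end)]
    if len(open_ended) > 1 or (open_ended and len(config_history) > 1):
        raise ProtocolError("an unbounded config cannot coexist with other eras")


def _era_for(record: SubmissionRecord, config_history: list[RuleConfig]) -> RuleConfig:
    for config in config_history:
        if config.covers(record.end_date):
            return config
    raise ProtocolError(
        f"record {record.submission_id!r} dated {record.end_date.isoformat()} falls "
        "outside every config's effective window"
    )


def cohort_median_duration(records: list[SubmissionRecord]) -> Optional[float]:
    durations = [r.duration_minutes for r in records if r.duration_minutes is not None]
    return median(durations) if durations else None


def run_protocol(
    records: list[SubmissionRecord],
    config_history: list[RuleConfig],
    geo: Optional[GeoTable] = None,
    audit: Optional[AuditLog] = None,
) -> list[Decision]:
    """Adjudicate each record under the era covering its end date.

    The dedup context is built once over the whole batch (dataset-level
    signals are not era-dependent), using the latest era's thresholds.
    """
    if not records:
        _check_windows(config_history)
        return []
    _check_windows(config_history)
    context_config = config_history[-1]
    context = build_dedup_context(records, context_config, audit)
    med = cohort_median_duration(records)
    decisions = []
    for record in records:
        config = _era_for(record, config_history)
        strikes = collect_strikes(record, context, geo, config, med, audit)
        decisions.append(adjudicate(record, strikes, config))
    return decisions


def retrospective_pass(
    records: list[SubmissionRecord],
    config_history: list[RuleConfig],
    final_config: RuleConfig,
    geo: Optional[GeoTable] = None,
) -> list[tuple[str, DecisionStatus, DecisionStatus]]:
    """Re-adjudicate everything under one uniform final configuration.

    Returns ``(submission_id, era_status, retrospective_status)`` triples;
    running the pass twice yields identical output.
    """
    era = run_protocol(records, config_history, geo)
    uniform = final_config.model_copy(
        update={"effective_start": None, "effective_end": None}
    )
    retro = run_protocol(records, [uniform], geo)
    return [
        (e.submission_id, e.status, r.status) for e, r in zip(era, retro)
    ]


@dataclass
class DriftWindow:
    start: dt.date
    n_flagged: int
    rates: dict[str, float] = field(default_factory=dict)


@dataclass
class DriftAlert:
    rule_id: str
    window_index: int
    previous: float
    current: float


@dataclass
class DriftReport:
    windows: list[DriftWindow] = field(default_factory=list)
    alerts: list[DriftAlert] = field(default_factory=list)


def monitor_drift(decisions: list[Decision], config: RuleConfig) -> DriftReport:
    """Per-rule hit rates among flagged submissions, per time window.

    The hit rate of a rule in a window is (submissions carrying that
    strike) / (submissions carrying at least one strike); computing it
    among flagged submissions keeps a change of spam *style* visible even
    as spam *volume* varies. An alert fires when the rate jumps by more
    than ``drift_delta`` between consecutive non-empty windows. Fewer than
    two non-empty windows yield an empty report.
    """
    dated = [d for d in decisions if d.end_date is not None]
    if not dated:
        return DriftReport()
    first = min(d.end_date for d in dated)
    last = max(d.end_date for d in dated)
    width = dt.timedelta(days=config.drift_window_days)
    windows: list[DriftWindow] = []
    start = first
    while start <= last:
        end = start + width
        members = [d for d in dated if start <= d.end_date < end]
        if members:
            flagged = [d for d in members if d.strike_count > 0]
            rates: dict[str, float] = {}
            if flagged:
                for rule_id in RULE_REGISTRY:
                    hit = sum(1 for d in flagged if rule_id in d.reason_codes)
                    rates[rule_id] = hit / len(flagged)
            windows.append(DriftWindow(start=start, n_flagged=len(flagged), rates=rates))
        start = end
    if len(windows) < 2:
        return DriftReport()
    alerts: list[DriftAlert] = []
    for i in range(1, len(windows)):
        prev, cur = windows[i - 1], windows[i]
        if not prev.rates or not cur.rates:
            continue
        for rule_id in RULE_REGISTRY:
            p, c = prev.rates[rule_id], cur.rates[rule_id]
            if abs(c - p) > config.drift_delta:
                alerts.append(DriftAlert(rule_id=rule_id, window_index=i, previous=p, current=c))
    return DriftReport(windows=windows, alerts=alerts)
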