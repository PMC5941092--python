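"""Summary statistics, detector performance and audit reports.

Rounding happens at presentation only and is half-up (the convention used
when percentages like 289/478 = 60.4% are printed); all internal values
keep full precision. In the confusion matrix "positive" means spam; a
review-status decision counts as *not* invalid by default — in the manual
protocol these were resolved by contacting the respondent, so treating
them as spam would overstate the detector. A strict mode counting review
as invalid sits behind a flag.
"""
from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .adjudicate import DriftReport
from .exceptions import EvaluationError
from .model import Decision, DecisionStatus, SubmissionRecord

SPAM_LABELS = frozenset({"naive", "evolved", "spam"})


def _round_half_up(value: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def proportion_invalid(decisions: Iterable[Decision], ndigits: int = 1) -> float:
    """Percentage of decisions with invalid status, half-up rounded."""
    decisions = list(decisions)
    if not decisions:
        raise EvaluationError("proportion_invalid requires at least one decision")
    n_invalid = sum(1 for d in decisions if d.status == DecisionStatus.invalid)
    return _round_half_up(100.0 * n_invalid / len(decisions), ndigits)


@dataclass
class EvaluationSummary:
    n_total: int
    n_valid_status: int
    n_review: int
    n_invalid: int
    percent_invalid: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]


def confusion_metrics(
    decisions: list[Decision],
    truth_labels: Mapping[str, str],
    review_counts_as_invalid: bool = False,
) -> EvaluationSummary:
    """Detector performance against ground truth, with spam as positive."""
    missing = [d.submission_id for d in decisions if d.submission_id not in truth_labels]
    if missing:
        raise EvaluationError(f"decisions without truth labels: {missing[:10]}")
    tp = fp = tn = fn = 0
    for d in decisions:
        is_spam = truth_labels[d.submission_id] in SPAM_LABELS
        predicted_spam = d.status == DecisionStatus.invalid or (
            review_counts_as_invalid and d.status == DecisionStatus.review
        )
        if is_spam and predicted_spam:
            tp += 1
        elif is_spam:
            fn += 1
        elif predicted_spam:
            fp += 1
        else:
            tn += 1
    n_total = len(decisions)
    return EvaluationSummary(
        n_total=n_total,
        n_valid_status=sum(1 for d in decisions if d.status == DecisionStatus.valid),
        n_review=sum(1 for d in decisions if d.status == DecisionStatus.review),
        n_invalid=sum(1 for d in decisions if d.status == DecisionStatus.invalid),
        percent_invalid=proportion_invalid(decisions) if decisions else 0.0,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / (tp + fn) if tp + fn else None,
        specificity=tn / (tn + fp) if tn + fp else None,
        ppv=tp / (tp + fp) if tp + fp else None,
    )


def study_window_days(start_date: dt.date, end_date: dt.date) -> int:
    """Calendar-day difference end - start (launch to close)."""
    if end_date < start_date:
        raise EvaluationError("end_date precedes start_date")
    return (end_date - start_date).days


@dataclass
class CohortSummary:
    n: int
    n_with_age: int
    mean_age: Optional[float]
    sd_age: Optional[float]
    n_with_status: int
    treated_fraction: Optional[float]


def summarize_cohort(records: list[SubmissionRecord]) -> CohortSummary:
    """Sample mean/SD of age (n-1 denominator) and treated fraction."""
    if not records:
        raise EvaluationError("summarize_cohort requires at least one record")
    ages = [r.age_years for r in records if r.age_years is not None]
    if not ages:
        raise EvaluationError("summarize_cohort requires at least one record with age")
    n = len(ages)
    mean = sum(ages) / n
    if n > 1:
        sd = math.sqrt(sum((a - mean) ** 2 for a in ages) / (n - 1))
    else:
        sd = None
    statuses = [r.cancer_status for r in records if r.cancer_status.value != "missing"]
    treated = (
        sum(1 for s in statuses if s.value == "successfully_treated") / len(statuses)
        if statuses
        else None
    )
    return CohortSummary(
        n=len(records),
        n_with_age=n,
        mean_age=mean,
        sd_age=sd,
        n_with_status=len(statuses),
        treated_fraction=treated,
    )


def write_audit_report(
    records: list[SubmissionRecord],
    decisions: list[Decision],
    path: Union[str, Path],
    drift: Optional[DriftReport] = None,
) -> tuple[Path, Path]:
    """Write the per-record case-study narrative as Markdown plus JSON.

    Each flagged submission gets a block listing every strike with its
    evidence string — the machine half of the read-each-survey-as-a-case-
    study step. Output is deterministic: identical inputs give identical
    bytes. Returns (markdown path, json path).
    """
    by_id = {r.submission_id: r for r in records}
    unknown = [d.submission_id for d in decisions if d.submission_id not in by_id]
    if unknown:
        raise EvaluationError(f"decisions without records: {unknown[:10]}")
    md_path = Path(path)
    json_path = md_path.with_suffix(".json")

    lines: list[str] = ["# Screening audit report", ""]
    n_invalid = sum(1 for d in decisions if d.status == DecisionStatus.invalid)
    lines += [
        "## Batch summary",
        "",
        f"- submissions: {len(decisions)}",
        f"- valid: {sum(1 for d in decisions if d.status == DecisionStatus.valid)}",
        f"- review: {sum(1 for d in decisions if d.status == DecisionStatus.review)}",
        f"- invalid: {n_invalid}",
    ]
    if decisions:
        lines.append(f"- percent invalid: {proportion_invalid(decisions)}")
    try:
        summary = summarize_cohort(records)
        lines += [
            "",
            "## Cohort",
            "",
            f"- records with age: {summary.n_with_age}",
            f"- mean age: {summary.mean_age:.2f}" if summary.mean_age is not None else "- mean age: n/a",
            f"- sd age: {summary.sd_age:.2f}" if summary.sd_age is not None else "- sd age: n/a",
            (
                f"- successfully treated fraction: {summary.treated_fraction:.3f}"
                if summary.treated_fraction is not None
                else "- successfully treated fraction: n/a"
            ),
        ]
    except EvaluationError:
        pass
    lines += ["", "## Case studies", ""]
    flagged = [d for d in sorted(decisions, key=lambda d: d.submission_id) if d.strike_count > 0
               or d.status == DecisionStatus.invalid]
    if not flagged:
        lines.append("No flagged submissions.")
    for d in flagged:
        lines += [
            f"### {d.submission_id} — {d.status.value} "
            f"({d.strike_count} strike{'s' if d.strike_count != 1 else ''}, "
            f"config {d.config_id})",
            "",
        ]
        if "incomplete" in d.reason_codes:
            lines.append("- incomplete submission (invalid by rule)")
        for s in d.strikes:
            lines.append(f"- [{s.category.value}] {s.rule_id}: {s.evidence}")
        lines.append("")
    if drift is not None:
        lines += ["## Drift timeline", ""]
        for i, w in enumerate(drift.windows):
            active = {k: round(v, 3) for k, v in sorted(w.rates.items()) if v > 0}
            lines.append(f"- window {i} starting {w.start.isoformat()}: "
                         f"{w.n_flagged} flagged; rates {active}")
        for a in drift.alerts:
            lines.append(
                f"- ALERT {a.rule_id}: window {a.window_index} rate "
                f"{a.current:.3f} vs previous {a.previous:.3f}"
            )
        lines.append("")

    md_path.write_text("\n".join(lines).rstrip() + "\n", encoding="utf-8")

    payload = {
        "summary": {
            "n_total": len(decisions),
            "n_invalid": n_invalid,
            "percent_invalid": proportion_invalid(decisions) if decisions else None,
        },
        "cases": [
            {
                "submission_id": d.submission_id,
                "status": d.status.value,
                "strike_count": d.strike_count,
                "reason_codes": d.reason_codes,
                "strikes": [
                    {"rule_id": s.rule_id, "category": s.category.value, "evidence": s.evidence}
                    for s in d.strikes
                ],
            }
            for d in flagged
        ],
    }
    if drift is not None:
        payload["drift"] = {
            "windows": [
                {"start": w.start.isoformat(), "n_flagged": w.n_flagged, "rates": w.rates}
                for w in drift.windows
            ],
            "alerts": [
                {
                    "rule_id": a.rule_id,
                    "window_index": a.window_index,
                    "previous": a.previous,
                    "current": a.current,
                }
                for a in drift.alerts
            ],
        }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return md_path, json_path
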