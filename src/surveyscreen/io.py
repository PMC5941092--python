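"""CSV readers and writers for submissions, decisions and reject files.

Dialect: comma-separated, UTF-8, header row required. List-valued fields
are serialized with ``|`` separators; treatment history as
``code:provider`` pairs; verification items as ``instructed:given``.
Grid, verification and free-text blocks live in per-block columns named
``grid.<block>``, ``verify.<item>`` and ``text.<prompt>`` so that
``read(write(records))`` reproduces every field bit-exactly.

One encoding quirk: a free-text cell that is present but empty is written
as ``""`` (two double-quote characters) to distinguish it from an absent
prompt — blank text boxes are themselves a suspicion indicator and must
survive a round trip.

Malformed rows are quarantined (returned in :class:`ReadResult.rejects`
and optionally written to a reject CSV) rather than aborting the batch.
"""
from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from pydantic import ValidationError

from .audit import AuditLog
from .exceptions import ConfigurationError
from .model import (
    CancerStatus,
    CompletionStatus,
    Decision,
    DecisionStatus,
    RejectedRow,
    Strike,
    SubmissionRecord,
)

SCALAR_FIELDS: list[str] = [
    "submission_id",
    "channel_id",
    "screener_age_ok",
    "screener_residence_ok",
    "screener_identity_ok",
    "screener_treatment_ok",
    "prior_completion_denied",
    "consent_given",
    "start_timestamp",
    "end_timestamp",
    "duration_minutes",
    "ip_address",
    "email_address",
    "zip_code",
    "birth_date",
    "age_years",
    "age_at_diagnosis",
    "psa_at_diagnosis",
    "gleason_total",
    "treatment_history",
    "disclosure_to_provider",
    "rehab_recommendations",
    "discrimination_attributes",
    "cancer_status",
    "completion_status",
    "ballot_box_cookie_present",
]

REQUIRED_FIELDS = (
    "submission_id",
    "channel_id",
    "ip_address",
    "start_timestamp",
    "end_timestamp",
    "completion_status",
)

_BOOL_TRUE = {"true", "1", "yes", "y"}
_BOOL_FALSE = {"false", "0", "no", "n"}


@dataclass
class ReadResult:
    records: list[SubmissionRecord] = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)


def _ser_bool(v: Optional[bool]) -> str:
    if v is None:
        return ""
    return "true" if v else "false"


def _parse_bool(cell: str, *, fieldname: str) -> Optional[bool]:
    s = cell.strip().lower()
    if s == "":
        return None
    if s in _BOOL_TRUE:
        return True
    if s in _BOOL_FALSE:
        return False
    raise ValueError(f"{fieldname}: cannot parse boolean from {cell!r}")


def _ser_num(v: Optional[float]) -> str:
    if v is None:
        return ""
    return repr(v) if isinstance(v, float) else str(v)


def _ser_grid(items: list[Optional[float]]) -> str:
    return "|".join("" if x is None else _ser_num(x) for x in items)


def _parse_grid(cell: str) -> list[Optional[float]]:
    return [None if part == "" else float(part) for part in cell.split("|")]


def _ser_text(text: str) -> str:
    return '""' if text == "" else text


def _parse_text(cell: str) -> Optional[str]:
    if cell == "":
        return None  # prompt absent
    if cell == '""':
        return ""
    return cell


def record_to_row(record: SubmissionRecord) -> dict[str, str]:
    """Flatten one record into CSV cells keyed by logical column name."""
    row: dict[str, str] = {
        "submission_id": record.submission_id,
        "channel_id": record.channel_id,
        "screener_age_ok": _ser_bool(record.screener_age_ok),
        "screener_residence_ok": _ser_bool(record.screener_residence_ok),
        "screener_identity_ok": _ser_bool(record.screener_identity_ok),
        "screener_treatment_ok": _ser_bool(record.screener_treatment_ok),
        "prior_completion_denied": _ser_bool(record.prior_completion_denied),
        "consent_given": _ser_bool(record.consent_given),
        "start_timestamp": record.start_timestamp.isoformat(),
        "end_timestamp": record.end_timestamp.isoformat(),
        "duration_minutes": _ser_num(record.duration_minutes),
        "ip_address": record.ip_address or "",
        "email_address": record.email_address or "",
        "zip_code": record.zip_code or "",
        "birth_date": record.birth_date.isoformat() if record.birth_date else "",
        "age_years": _ser_num(record.age_years),
        "age_at_diagnosis": _ser_num(record.age_at_diagnosis),
        "psa_at_diagnosis": _ser_num(record.psa_at_diagnosis),
        "gleason_total": _ser_num(record.gleason_total),
        "treatment_history": "|".join(f"{t}:{p}" for t, p in record.treatment_history),
        "disclosure_to_provider": _ser_bool(record.disclosure_to_provider),
        "rehab_recommendations": "|".join(record.rehab_recommendations),
        "discrimination_attributes": "|".join(record.discrimination_attributes),
        "cancer_status": record.cancer_status.value,
        "completion_status": record.completion_status.value,
        "ballot_box_cookie_present": _ser_bool(record.ballot_box_cookie_present),
    }
    for block, items in record.grid_responses.items():
        row[f"grid.{block}"] = _ser_grid(items)
    for item, (instructed, given) in record.verification_items.items():
        row[f"verify.{item}"] = f"{_ser_num(instructed)}:{_ser_num(given)}"
    for prompt, text in record.text_responses.items():
        row[f"text.{prompt}"] = _ser_text(text)
    return row


def row_to_record(row: dict[str, str], mapping: dict[str, str]) -> SubmissionRecord:
    """Build one record from CSV cells; raises ValueError on malformed cells."""

    def cell(name: str) -> str:
        col = mapping.get(name, name)
        return (row.get(col) or "").strip()

    def opt(name: str) -> Optional[str]:
        return cell(name) or None

    kwargs: dict = {
        "submission_id": cell("submission_id"),
        "channel_id": cell("channel_id"),
        "ip_address": opt("ip_address"),
        "email_address": opt("email_address"),
        "zip_code": opt("zip_code"),
    }
    for b in (
        "screener_age_ok",
        "screener_residence_ok",
        "screener_identity_ok",
        "screener_treatment_ok",
        "prior_completion_denied",
        "consent_given",
        "ballot_box_cookie_present",
    ):
        parsed = _parse_bool(cell(b), fieldname=b)
        if parsed is not None:
            kwargs[b] = parsed
    disclosure = _parse_bool(cell("disclosure_to_provider"), fieldname="disclosure_to_provider")
    kwargs["disclosure_to_provider"] = disclosure

    for ts_field in ("start_timestamp", "end_timestamp"):
        raw = cell(ts_field)
        if not raw:
            raise ValueError(f"{ts_field}: missing timestamp")
        try:
            kwargs[ts_field] = dt.datetime.fromisoformat(raw)
        except ValueError as exc:
            raise ValueError(f"{ts_field}: unparseable timestamp {raw!r}") from exc

    if cell("birth_date"):
        kwargs["birth_date"] = dt.date.fromisoformat(cell("birth_date"))
    for int_field in ("age_years", "age_at_diagnosis", "gleason_total"):
        if cell(int_field):
            kwargs[int_field] = int(float(cell(int_field)))
    if cell("psa_at_diagnosis"):
        kwargs["psa_at_diagnosis"] = float(cell("psa_at_diagnosis"))
    if cell("duration_minutes"):
        kwargs["duration_minutes"] = float(cell("duration_minutes"))

    if cell("treatment_history"):
        pairs = []
        for part in cell("treatment_history").split("|"):
            if ":" not in part:
                raise ValueError(f"treatment_history: malformed pair {part!r}")
            t, p = part.split(":", 1)
            pairs.append((t, p))
        kwargs["treatment_history"] = pairs
    for list_field in ("rehab_recommendations", "discrimination_attributes"):
        if cell(list_field):
            kwargs[list_field] = cell(list_field).split("|")
    if cell("cancer_status"):
        kwargs["cancer_status"] = CancerStatus(cell("cancer_status"))
    kwargs["completion_status"] = CompletionStatus(cell("completion_status"))

    grids: dict[str, list[Optional[float]]] = {}
    verify: dict[str, tuple[float, float]] = {}
    texts: dict[str, str] = {}
    for col, raw in row.items():
        if raw is None:
            continue
        if col.startswith("grid."):
            if raw != "":
                grids[col[len("grid."):]] = _parse_grid(raw)
        elif col.startswith("verify."):
            if raw != "":
                instructed, given = raw.split(":", 1)
                verify[col[len("verify."):]] = (float(instructed), float(given))
        elif col.startswith("text."):
            parsed_text = _parse_text(raw)
            if parsed_text is not None:
                texts[col[len("text."):]] = parsed_text
    kwargs["grid_responses"] = grids
    kwargs["verification_items"] = verify
    kwargs["text_responses"] = texts
    return SubmissionRecord(**kwargs)


def read_submissions(
    path: Union[str, Path],
    mapping: Optional[dict[str, str]] = None,
    reject_path: Union[str, Path, None] = None,
    audit: Optional[AuditLog] = None,
) -> ReadResult:
    """Read a submissions CSV, quarantining malformed rows.

    ``mapping`` maps logical field names to source column names (identity by
    default). A required column missing from the header is a
    :class:`ConfigurationError`; a malformed row becomes a
    :class:`RejectedRow` carrying the 1-based file row number and the
    violated invariant.
    """
    mapping = dict(mapping or {})
    result = ReadResult()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for name in REQUIRED_FIELDS:
            col = mapping.get(name, name)
            if col not in header:
                raise ConfigurationError(
                    f"missing required column {col!r} (field {name!r}) in {path}"
                )
        for i, row in enumerate(reader, start=2):
            try:
                result.records.append(row_to_record(row, mapping))
            except (ValueError, ValidationError) as exc:
                reason = _summarize_error(exc)
                result.rejects.append(RejectedRow(row_number=i, reason=reason, raw=dict(row)))
                if audit is not None:
                    audit.note(row.get(mapping.get("submission_id", "submission_id"), "") or "?",
                               "read_submissions", f"row {i} rejected: {reason}")
    if reject_path is not None:
        write_rejects(result.rejects, reject_path)
    return result


def _summarize_error(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        return "; ".join(
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" if e["loc"] else e["msg"]
            for e in exc.errors()
        )
    return str(exc)


def submission_columns(records: list[SubmissionRecord]) -> list[str]:
    extra: set[str] = set()
    for r in records:
        extra.update(f"grid.{b}" for b in r.grid_responses)
        extra.update(f"verify.{v}" for v in r.verification_items)
        extra.update(f"text.{t}" for t in r.text_responses)
    return SCALAR_FIELDS + sorted(extra)


def write_submissions(records: list[SubmissionRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(submissions_to_csv(records))


def submissions_to_csv(records: list[SubmissionRecord]) -> str:
    """Serialize records to one CSV string (handy for byte-identity checks)."""
    import io as _io

    buf = _io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=submission_columns(records), restval="",
                            lineterminator="\n")
    writer.writeheader()
    for r in records:
        writer.writerow(record_to_row(r))
    return buf.getvalue()


def write_rejects(rejects: list[RejectedRow], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["row_number", "reason"])
        for rej in rejects:
            writer.writerow([rej.row_number, rej.reason])


DECISION_COLUMNS = ["submission_id", "config_id", "end_date", "status", "strike_count", "reason_codes"]


def write_decision_table(decisions: list[Decision], path: Union[str, Path]) -> None:
    """One row per decision; strikes serialized as a ``|``-delimited reason list."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(DECISION_COLUMNS)
        for d in decisions:
            writer.writerow(
                [
                    d.submission_id,
                    d.config_id,
                    d.end_date.isoformat() if d.end_date else "",
                    d.status.value,
                    d.strike_count,
                    "|".join(d.reason_codes),
                ]
            )


def read_decision_table(path: Union[str, Path]) -> list[Decision]:
    """Round-trip reader: statuses and strike counts are reproduced exactly.

    Evidence strings are not stored in the decision table (the audit report
    holds them); rebuilt strikes carry empty evidence.
    """
    from .rules import RULE_REGISTRY  # late import to avoid a cycle

    decisions = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            reasons = row["reason_codes"].split("|") if row["reason_codes"] else []
            strikes = [
                Strike(
                    rule_id=r,
                    category=RULE_REGISTRY[r].category,
                    evidence="",
                )
                for r in reasons
                if r != "incomplete"
            ]
            decisions.append(
                Decision(
                    submission_id=row["submission_id"],
                    strikes=strikes,
                    strike_count=int(row["strike_count"]),
                    status=DecisionStatus(row["status"]),
                    reason_codes=reasons,
                    config_id=row["config_id"],
                    end_date=dt.date.fromisoformat(row["end_date"]) if row["end_date"] else None,
                )
            )
    return decisions


def write_review_queue(decisions: list[Decision], path: Union[str, Path]) -> None:
    """Manual-review queue: complete submissions with 1..k-1 strikes."""
    write_decision_table([d for d in decisions if d.status == DecisionStatus.review], path)
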