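"""Core domain types: survey submissions, strikes and adjudication decisions.

A :class:`SubmissionRecord` is one attempt at the web survey — the metadata
the survey platform logs (IP, timestamps, completion status, channel) plus
the screener, clinical, grid and free-text responses the screening rules
inspect. Field invariants (timestamp ordering, value ranges, zip shape) are
enforced at construction time so that malformed rows are caught when a CSV
is parsed, not deep inside a rule.
"""
from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

_ZIP_RE = re.compile(r"^\d{5}$")


class CompletionStatus(str, Enum):
    complete = "complete"
    partial = "partial"


class CancerStatus(str, Enum):
    successfully_treated = "successfully_treated"
    in_treatment = "in_treatment"
    progressed = "progressed"
    missing = "missing"


class DecisionStatus(str, Enum):
    valid = "valid"
    review = "review"
    invalid = "invalid"

    @property
    def rank(self) -> int:
        """Severity ordering: valid < review < invalid."""
        return _STATUS_RANK[self.value]


_STATUS_RANK = {"valid": 0, "review": 1, "invalid": 2}


class StrikeCategory(str, Enum):
    dedup = "dedup"
    metadata = "metadata"
    clinical = "clinical"
    style = "style"


class SubmissionRecord(BaseModel):
    """One survey attempt: platform metadata plus responses.

    ``duration_minutes`` is always recomputed from the two timestamps
    (the single source of truth); a supplied duration column is ignored.
    Timestamps should carry a UTC offset — "early hours of the morning"
    rules evaluate the submission's own local clock. Naive timestamps are
    accepted and treated as UTC.
    """

    model_config = ConfigDict(extra="forbid")

    submission_id: str
    channel_id: str
    # Eligibility screener: the four check-boxes a respondent must tick
    # (adult, US/Canada resident, GBM identity, completed treatment).
    screener_age_ok: bool = True
    screener_residence_ok: bool = True
    screener_identity_ok: bool = True
    screener_treatment_ok: bool = True
    prior_completion_denied: bool = True
    consent_given: bool = True
    start_timestamp: dt.datetime
    end_timestamp: dt.datetime
    duration_minutes: Optional[float] = Field(default=None, ge=0)
    ip_address: Optional[str] = None
    email_address: Optional[str] = None
    zip_code: Optional[str] = None
    birth_date: Optional[dt.date] = None
    age_years: Optional[int] = None
    age_at_diagnosis: Optional[int] = None
    psa_at_diagnosis: Optional[float] = Field(default=None, ge=0)
    gleason_total: Optional[int] = Field(default=None, ge=2, le=10)
    treatment_history: list[tuple[str, str]] = Field(default_factory=list)
    disclosure_to_provider: Optional[bool] = None
    rehab_recommendations: list[str] = Field(default_factory=list)
    discrimination_attributes: list[str] = Field(default_factory=list)
    cancer_status: CancerStatus = CancerStatus.missing
    grid_responses: dict[str, list[Optional[float]]] = Field(default_factory=dict)
    verification_items: dict[str, tuple[float, float]] = Field(default_factory=dict)
    text_responses: dict[str, str] = Field(default_factory=dict)
    completion_status: CompletionStatus = CompletionStatus.complete
    ballot_box_cookie_present: bool = False

    @model_validator(mode="after")
    def _check_invariants(self) -> "SubmissionRecord":
        if self.start_timestamp.tzinfo is None:
            self.start_timestamp = self.start_timestamp.replace(tzinfo=dt.timezone.utc)
        if self.end_timestamp.tzinfo is None:
            self.end_timestamp = self.end_timestamp.replace(tzinfo=dt.timezone.utc)
        if self.end_timestamp < self.start_timestamp:
            raise ValueError(
                "end_timestamp precedes start_timestamp "
                f"({self.end_timestamp.isoformat()} < {self.start_timestamp.isoformat()})"
            )
        span = (self.end_timestamp - self.start_timestamp).total_seconds() / 60.0
        if self.duration_minutes is not None and abs(self.duration_minutes - span) > 0.5:
            # supplied duration disagrees with the timestamps; timestamps win
            pass
        self.duration_minutes = span
        if self.zip_code is not None and not _ZIP_RE.match(self.zip_code):
            raise ValueError(f"zip_code {self.zip_code!r} is not a 5-digit string")
        return self

    @property
    def screener_eligible(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.screener_age_ok,
            self.screener_residence_ok,
            self.screener_identity_ok,
            self.screener_treatment_ok,
        )

    @property
    def end_date(self) -> dt.date:
        """Calendar date of completion in the submission's local clock."""
        return self.end_timestamp.date()


@dataclass(frozen=True)
class Strike:
    """One triggered suspicion indicator, with human-readable evidence."""

    rule_id: str
    category: StrikeCategory
    evidence: str


@dataclass
class Decision:
    """Adjudicated status of one submission under a named configuration."""

    submission_id: str
    strikes: list[Strike]
    strike_count: int
    status: DecisionStatus
    reason_codes: list[str]
    config_id: str
    end_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.strike_count != len(self.strikes):
            raise ValueError(
                f"strike_count {self.strike_count} != number of strikes {len(self.strikes)}"
            )


@dataclass
class RejectedRow:
    """A malformed input row, quarantined rather than silently dropped."""

    row_number: int
    reason: str
    raw: dict = field(default_factory=dict)
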