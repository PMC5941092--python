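"""Shared record factory for tests."""
from __future__ import annotations

import datetime as dt

from surveyscreen import SubmissionRecord


def make_record(
    sid: str = "S1",
    *,
    start: str = "2015-11-01T10:00:00-05:00",
    end: str | None = None,
    duration_min: float = 50.0,
    ip: str | None = "100.64.0.5",
    email: str | None = None,
    zip_code: str | None = None,
    **kwargs,
) -> SubmissionRecord:
    start_dt = dt.datetime.fromisoformat(start)
    end_dt = (
        dt.datetime.fromisoformat(end)
        if end is not None
        else start_dt + dt.timedelta(minutes=duration_min)
    )
    return SubmissionRecord(
        submission_id=sid,
        channel_id="link_a",
        start_timestamp=start_dt,
        end_timestamp=end_dt,
        ip_address=ip,
        email_address=email,
        zip_code=zip_code,
        **kwargs,
    )
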