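"""Dataset-level deduplication signals.

These are the signals that only exist when all submissions are seen
together: shared IP addresses, email handles following one predictable
convention at one host, submissions that start seconds after a previous
one ended, completion in the early hours of the morning, and identical
improbable values (such as one shared birth date) across respondents.

Every signal is order-invariant and monotone (adding a record never
removes an existing flag), and on small inputs each equals a brute-force
all-pairs reference — properties the test suite checks directly.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .audit import AuditLog
from .config import RuleConfig
from .model import Strike, StrikeCategory, SubmissionRecord

_EMAIL_RE = re.compile(r"^(?P<handle>[^@]+)@(?P<host>[^@]+)$")


@dataclass
class DedupContext:
    """All dataset-level signals, evaluated once per batch."""

    ip_groups: list[set[str]] = field(default_factory=list)
    email_clusters: list[set[str]] = field(default_factory=list)
    adjacency_flags: set[str] = field(default_factory=set)
    odd_hour_ids: set[str] = field(default_factory=set)
    shared_anomaly_groups: dict[str, list[set[str]]] = field(default_factory=dict)

    def strikes_for(self, record: SubmissionRecord) -> list[Strike]:
        sid = record.submission_id
        strikes: list[Strike] = []
        for group in self.ip_groups:
            if sid in group:
                strikes.append(
                    Strike(
                        "duplicate_ip",
                        StrikeCategory.dedup,
                        f"ip_address {record.ip_address} shared by {len(group)} submissions",
                    )
                )
                break
        for cluster in self.email_clusters:
            if sid in cluster:
                strikes.append(
                    Strike(
                        "email_convention",
                        StrikeCategory.dedup,
                        f"email_address {record.email_address} matches a handle convention "
                        f"shared by {len(cluster)} submissions at one host",
                    )
                )
                break
        if sid in self.adjacency_flags:
            strikes.append(
                Strike(
                    "temporal_adjacency",
                    StrikeCategory.dedup,
                    f"start_timestamp {record.start_timestamp.isoformat()} falls within "
                    "seconds of another submission's end",
                )
            )
        if sid in self.odd_hour_ids:
            strikes.append(
                Strike(
                    "odd_hour",
                    StrikeCategory.metadata,
                    f"end_timestamp {record.end_timestamp.isoformat()} completed in the "
                    "early-hours window",
                )
            )
        for field_id, groups in self.shared_anomaly_groups.items():
            for group in groups:
                if sid in group:
                    strikes.append(
                        Strike(
                            "shared_anomaly",
                            StrikeCategory.dedup,
                            f"{field_id} value {getattr(record, field_id)!r} shared "
                            f"identically by {len(group)} submissions",
                        )
                    )
                    break
        return strikes


def _sorted_groups(groups: Iterable[set[str]]) -> list[set[str]]:
    return sorted((set(g) for g in groups), key=lambda g: sorted(g))


def find_duplicate_ips(
    records: list[SubmissionRecord],
    group_by_prefix: bool = False,
    audit: Optional[AuditLog] = None,
) -> list[set[str]]:
    """Groups of >= 2 submissions sharing one IP (or /24 prefix when asked)."""
    by_key: dict[str, set[str]] = {}
    for r in records:
        if not r.ip_address:
            if audit is not None:
                audit.note(r.submission_id, "duplicate_ip", "missing ip_address; skipped")
            continue
        key = r.ip_address
        if group_by_prefix:
            key = ".".join(key.split(".")[:3])
        by_key.setdefault(key, set()).add(r.submission_id)
    return _sorted_groups(g for g in by_key.values() if len(g) >= 2)


def email_signature(handle: str) -> str:
    """Run-length character-class signature of an email handle.

    Letters become ``L``, digits ``D``, anything else ``O``, each with its
    run length: ``abc123`` -> ``L3D3``; ``john.smith`` -> ``L4O1L5``. Handles
    following one mechanical convention (three letters, three digits) share
    a signature even when the characters differ.
    """
    out: list[str] = []
    prev: Optional[str] = None
    run = 0
    for ch in handle:
        cls = "L" if ch.isalpha() else "D" if ch.isdigit() else "O"
        if cls == prev:
            run += 1
        else:
            if prev is not None:
                out.append(f"{prev}{run}")
            prev, run = cls, 1
    if prev is not None:
        out.append(f"{prev}{run}")
    return "".join(out)


def score_email_convention(
    records: list[SubmissionRecord],
    config: RuleConfig,
    audit: Optional[AuditLog] = None,
) -> set[str]:
    """Flag all members of (host, handle-signature) clusters of size >= minimum."""
    clusters: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if not r.email_address:
            if audit is not None:
                audit.note(r.submission_id, "email_convention", "missing email_address; skipped")
            continue
        m = _EMAIL_RE.match(r.email_address.strip().lower())
        if m is None:
            if audit is not None:
                audit.note(r.submission_id, "email_convention",
                           f"unparseable email {r.email_address!r}; skipped")
            continue
        key = (m.group("host"), email_signature(m.group("handle")))
        clusters.setdefault(key, set()).add(r.submission_id)
    flagged: set[str] = set()
    for members in clusters.values():
        if len(members) >= config.email_cluster_min:
            flagged |= members
    return flagged


def email_convention_clusters(
    records: list[SubmissionRecord], config: RuleConfig
) -> list[set[str]]:
    """Cluster view of :func:`score_email_convention` (for the context object)."""
    clusters: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if not r.email_address:
            continue
        m = _EMAIL_RE.match(r.email_address.strip().lower())
        if m is None:
            continue
        key = (m.group("host"), email_signature(m.group("handle")))
        clusters.setdefault(key, set()).add(r.submission_id)
    return _sorted_groups(g for g in clusters.values() if len(g) >= config.email_cluster_min)


def find_temporal_adjacency(
    records: list[SubmissionRecord], config: RuleConfig
) -> set[str]:
    """Submissions in any start-follows-end chain.

    A pair (a, b) is chained when b's start falls within
    ``(0, adjacency_gap_seconds]`` after a's end; both members are flagged
    and chains propagate. Equivalent to the brute-force check over all
    ordered pairs.
    """
    n = len(records)
    if n < 2:
        return set()
    gap = config.adjacency_gap_seconds
    starts = np.array([r.start_timestamp.timestamp() for r in records])
    ends = np.array([r.end_timestamp.timestamp() for r in records])
    order = np.argsort(ends, kind="stable")
    ends_sorted = ends[order]
    flagged: set[str] = set()
    for i in range(n):
        lo = np.searchsorted(ends_sorted, starts[i] - gap, side="left")
        hi = np.searchsorted(ends_sorted, starts[i], side="left")
        for j in order[lo:hi]:
            if j == i:
                continue
            # end == start - gap .. end < start, i.e. gap in (0, gap_seconds]
            flagged.add(records[i].submission_id)
            flagged.add(records[j].submission_id)
    return flagged


def detect_odd_hour(records: list[SubmissionRecord], config: RuleConfig) -> set[str]:
    """Submissions whose local end-of-survey clock time is in the odd-hour window.

    The window is half-open ``[odd_hour_start, odd_hour_end)`` in the
    submission's own local clock; a window wrapping midnight is supported.
    """
    start, end = config.odd_hour_start, config.odd_hour_end
    flagged: set[str] = set()
    for r in records:
        t = r.end_timestamp.time()
        if start <= end:
            inside = start <= t < end
        else:  # wraps midnight
            inside = t >= start or t < end
        if inside:
            flagged.add(r.submission_id)
    return flagged


def detect_shared_anomaly(
    records: list[SubmissionRecord], field_id: str, config: RuleConfig
) -> list[set[str]]:
    """Groups of >= minimum submissions sharing one identical improbable value."""
    by_value: dict[object, set[str]] = {}
    for r in records:
        value = getattr(r, field_id)
        if value is None:
            continue
        by_value.setdefault(value, set()).add(r.submission_id)
    return _sorted_groups(g for g in by_value.values() if len(g) >= config.shared_anomaly_min)


def build_dedup_context(
    records: list[SubmissionRecord],
    config: RuleConfig,
    audit: Optional[AuditLog] = None,
) -> DedupContext:
    """Evaluate every dataset-level signal once over a batch."""
    return DedupContext(
        ip_groups=find_duplicate_ips(records, config.ip_prefix_grouping, audit),
        email_clusters=email_convention_clusters(records, config),
        adjacency_flags=find_temporal_adjacency(records, config),
        odd_hour_ids=detect_odd_hour(records, config),
        shared_anomaly_groups={
            f: detect_shared_anomaly(records, f, config) for f in config.shared_anomaly_fields
        },
    )
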