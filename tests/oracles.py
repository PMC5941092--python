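"""Brute-force all-pairs reference implementations of the dedup signals.

Deliberately naive (quadratic, no sorting tricks) and written without
reusing any surveyscreen internals, so they can act as independent
oracles on small inputs.
"""
from __future__ import annotations

import re


def brute_duplicate_ips(records):
    groups = []
    seen = set()
    for a in records:
        if a.ip_address is None or a.submission_id in seen:
            continue
        group = {
            b.submission_id
            for b in records
            if b.ip_address is not None and b.ip_address == a.ip_address
        }
        if len(group) >= 2:
            groups.append(group)
            seen |= group
    return sorted(groups, key=lambda g: sorted(g))


def _shape(handle: str) -> tuple:
    runs = re.findall(r"[a-zA-Z]+|[0-9]+|[^a-zA-Z0-9]+", handle)
    out = []
    for run in runs:
        if run[0].isalpha():
            out.append(("L", len(run)))
        elif run[0].isdigit():
            out.append(("D", len(run)))
        else:
            out.append(("O", len(run)))
    return tuple(out)


def brute_email_convention(records, minimum):
    flagged = set()
    for a in records:
        if not a.email_address or "@" not in a.email_address:
            continue
        ah, ad = a.email_address.lower().rsplit("@", 1)
        members = set()
        for b in records:
            if not b.email_address or "@" not in b.email_address:
                continue
            bh, bd = b.email_address.lower().rsplit("@", 1)
            if ad == bd and _shape(ah) == _shape(bh):
                members.add(b.submission_id)
        if len(members) >= minimum:
            flagged |= members
    return flagged


def brute_adjacency(records, gap_seconds):
    flagged = set()
    for a in records:
        for b in records:
            if a is b:
                continue
            delta = (b.start_timestamp - a.end_timestamp).total_seconds()
            if 0 < delta <= gap_seconds:
                flagged.add(a.submission_id)
                flagged.add(b.submission_id)
    return flagged


def brute_odd_hour(records, start, end):
    flagged = set()
    for r in records:
        t = r.end_timestamp.time()
        inside = (start <= t < end) if start <= end else (t >= start or t < end)
        if inside:
            flagged.add(r.submission_id)
    return flagged


def brute_shared_anomaly(records, field_id, minimum):
    groups = []
    seen = set()
    for a in records:
        value = getattr(a, field_id)
        if value is None or a.submission_id in seen:
            continue
        group = {
            b.submission_id for b in records if getattr(b, field_id) == value
        }
        if len(group) >= minimum:
            groups.append(group)
            seen |= group
    return sorted(groups, key=lambda g: sorted(g))
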