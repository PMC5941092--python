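"""Per-record indicator checks and the rule registry.

The registry maps every rule to one of the eight classic characteristics
of suspicious web-survey submissions (Baker & Downes-Le Guin): unusually
short completion times, selection of all items in a multiple response,
bogus or low-probability answers, internal inconsistencies, low
differentiation ("straight-lining") in grids, high item nonresponse,
failure of verification items, and gibberish or duplicated text
responses. The dataset-level dedup signals (shared IP, email convention,
temporal adjacency, shared anomalies) sit alongside these as their own
category — they are properties of a batch, not of a lone record.

Each sub-rule emits at most one strike per record; no single strike is
ever sufficient to invalidate a submission (that is the adjudicator's
k-strikes rule).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .audit import AuditLog
from .config import RuleConfig
from .dedup import DedupContext
from .geo import UNKNOWN, GeoTable
from .model import CompletionStatus, Strike, StrikeCategory, SubmissionRecord


class Indicator(str, Enum):
    """The eight classic suspicious-survey characteristics."""

    short_completion_time = "short_completion_time"
    all_items_selected = "all_items_selected"
    bogus_answers = "bogus_answers"
    internal_inconsistency = "internal_inconsistency"
    low_differentiation = "low_differentiation"
    item_nonresponse = "item_nonresponse"
    verification_failure = "verification_failure"
    gibberish_text = "gibberish_text"


@dataclass(frozen=True)
class RuleInfo:
    rule_id: str
    category: StrikeCategory
    indicator: Optional[Indicator]
    description: str


RULE_REGISTRY: dict[str, RuleInfo] = {
    info.rule_id: info
    for info in [
        RuleInfo("completion_time", StrikeCategory.metadata, Indicator.short_completion_time,
                 "completion faster than the plausible interview length"),
        RuleInfo("geo_mismatch", StrikeCategory.metadata, Indicator.internal_inconsistency,
                 "IP-derived region disagrees with zip-derived region"),
        RuleInfo("odd_hour", StrikeCategory.metadata, None,
                 "completed in the early hours of the morning"),
        RuleInfo("duplicate_ip", StrikeCategory.dedup, None,
                 "IP address shared with other submissions"),
        RuleInfo("email_convention", StrikeCategory.dedup, None,
                 "email handle follows a predictable convention at one host"),
        RuleInfo("temporal_adjacency", StrikeCategory.dedup, None,
                 "started seconds after a previous submission ended"),
        RuleInfo("shared_anomaly", StrikeCategory.dedup, None,
                 "identical improbable value shared across submissions"),
        RuleInfo("age_at_diagnosis", StrikeCategory.clinical, Indicator.bogus_answers,
                 "implausibly young age at prostate-cancer diagnosis"),
        RuleInfo("psa_implausible", StrikeCategory.clinical, Indicator.bogus_answers,
                 "PSA at diagnosis above the plausible ceiling"),
        RuleInfo("gleason_implausible", StrikeCategory.clinical, Indicator.bogus_answers,
                 "Gleason total above the plausible ceiling"),
        RuleInfo("clinical_missing", StrikeCategory.clinical, Indicator.item_nonresponse,
                 "all core clinical items 'forgotten' on a complete survey"),
        RuleInfo("treatment_sequence", StrikeCategory.clinical, Indicator.internal_inconsistency,
                 "improbable-to-impossible ordered treatment transition"),
        RuleInfo("provider_mismatch", StrikeCategory.clinical, Indicator.internal_inconsistency,
                 "treatment delivered by an incompatible provider type"),
        RuleInfo("disclosure_rehab", StrikeCategory.clinical, Indicator.internal_inconsistency,
                 "disclosure-dependent rehab recommendation without disclosure"),
        RuleInfo("discrimination_profile", StrikeCategory.clinical, Indicator.bogus_answers,
                 "peripheral discrimination attributes without any core attribute"),
        RuleInfo("straight_lining", StrikeCategory.style, Indicator.low_differentiation,
                 "low differentiation in a grid"),
        RuleInfo("nonresponse", StrikeCategory.style, Indicator.item_nonresponse,
                 "high fraction of missing items"),
        RuleInfo("text_quality", StrikeCategory.style, Indicator.gibberish_text,
                 "blank, gibberish or duplicated text responses"),
        RuleInfo("all_options", StrikeCategory.style, Indicator.all_items_selected,
                 "every option selected in a multiple-response block"),
        RuleInfo("verification", StrikeCategory.style, Indicator.verification_failure,
                 "instructed-response verification item answered wrongly"),
    ]
}


def indicator_categories() -> frozenset[Indicator]:
    """The indicator categories covered by the default registry (exactly 8)."""
    return frozenset(info.indicator for info in RULE_REGISTRY.values() if info.indicator)


def _strike(rule_id: str, evidence: str) -> Strike:
    return Strike(rule_id, RULE_REGISTRY[rule_id].category, evidence)


def check_completion_time(
    record: SubmissionRecord,
    cohort_median_minutes: Optional[float],
    config: RuleConfig,
    audit: Optional[AuditLog] = None,
) -> Optional[Strike]:
    """Speeding check: absolute floor, plus optional cohort-relative test."""
    d = record.duration_minutes
    if d is None:
        if audit is not None:
            audit.note(record.submission_id, "completion_time", "missing duration; skipped")
        return None
    if d < config.duration_min_minutes:
        return _strike(
            "completion_time",
            f"duration_minutes {d:.1f} < absolute minimum {config.duration_min_minutes:g}",
        )
    if (
        config.relative_speed_enabled
        and cohort_median_minutes is not None
        and d < config.relative_speed_fraction * cohort_median_minutes
    ):
        return _strike(
            "completion_time",
            f"duration_minutes {d:.1f} < {config.relative_speed_fraction:g} x cohort "
            f"median {cohort_median_minutes:.1f}",
        )
    return None


def check_geo_consistency(
    record: SubmissionRecord,
    geo: GeoTable,
    audit: Optional[AuditLog] = None,
) -> Optional[Strike]:
    """Strike only when IP region and zip region both resolve and disagree."""
    ip_region = geo.region_for_ip(record.ip_address)
    zip_region = geo.region_for_zip(record.zip_code)
    if ip_region == UNKNOWN or zip_region == UNKNOWN:
        if audit is not None:
            audit.note(record.submission_id, "geo_mismatch",
                       f"unverifiable (ip region {ip_region}, zip region {zip_region})")
        return None
    if ip_region != zip_region:
        return _strike(
            "geo_mismatch",
            f"ip_address {record.ip_address} resolves to {ip_region} but "
            f"zip_code {record.zip_code} resolves to {zip_region}",
        )
    return None


def evaluate_clinical_profile(record: SubmissionRecord, config: RuleConfig) -> list[Strike]:
    """Clinical plausibility sub-rules; each emits at most one strike.

    Sub-rules skip silently when their fields are missing, except the
    forgotten-clinical-data rule, whose whole point is the missingness.
    """
    strikes: list[Strike] = []

    if record.age_at_diagnosis is not None and record.age_at_diagnosis < config.age_dx_min:
        strikes.append(_strike(
            "age_at_diagnosis",
            f"age_at_diagnosis {record.age_at_diagnosis} < {config.age_dx_min} "
            "(diagnosis this young is rarer than 1 in 10,000)",
        ))
    if record.psa_at_diagnosis is not None and record.psa_at_diagnosis > config.psa_max:
        strikes.append(_strike(
            "psa_implausible",
            f"psa_at_diagnosis {record.psa_at_diagnosis:g} > {config.psa_max:g}",
        ))
    if record.gleason_total is not None and record.gleason_total > config.gleason_max:
        strikes.append(_strike(
            "gleason_implausible",
            f"gleason_total {record.gleason_total} > {config.gleason_max}",
        ))
    if (
        record.age_at_diagnosis is None
        and record.psa_at_diagnosis is None
        and record.gleason_total is None
        and record.completion_status == CompletionStatus.complete
    ):
        strikes.append(_strike(
            "clinical_missing",
            "age_at_diagnosis, psa_at_diagnosis and gleason_total all missing on a "
            "complete survey",
        ))

    codes = [t for t, _ in record.treatment_history]
    bad_transitions = [
        (a, b) for a, b in zip(codes, codes[1:]) if (a, b) in config.forbidden_transitions
    ]
    if bad_transitions:
        # one strike regardless of how many forbidden transitions appear
        strikes.append(_strike(
            "treatment_sequence",
            "forbidden treatment transition(s): "
            + ", ".join(f"{a}->{b}" for a, b in bad_transitions),
        ))

    bad_pairs = [
        (t, p)
        for t, p in record.treatment_history
        if t in config.provider_compat and p not in config.provider_compat[t]
    ]
    if bad_pairs:
        strikes.append(_strike(
            "provider_mismatch",
            "treatment/provider mismatch: " + ", ".join(f"{t} from {p}" for t, p in bad_pairs),
        ))

    if record.disclosure_to_provider is False:
        gated = sorted(set(record.rehab_recommendations) & config.disclosure_required_rehab)
        if gated:
            strikes.append(_strike(
                "disclosure_rehab",
                f"rehab recommendation(s) {', '.join(gated)} reported without disclosure "
                "to provider",
            ))

    attrs = set(record.discrimination_attributes)
    if attrs & config.peripheral_discrimination and not attrs & config.core_discrimination:
        strikes.append(_strike(
            "discrimination_profile",
            f"discrimination attributes {sorted(attrs & config.peripheral_discrimination)} "
            "reported with no core attribute",
        ))
    return strikes


def _vowel_token_fraction(text: str) -> Optional[float]:
    tokens = text.split()
    if not tokens:
        return None
    vowelled = sum(1 for t in tokens if any(c in "aeiouAEIOU" for c in t))
    return vowelled / len(tokens)


def evaluate_response_style(record: SubmissionRecord, config: RuleConfig) -> list[Strike]:
    """Response-style sub-rules; each emits at most one strike."""
    strikes: list[Strike] = []

    # (i) straight-lining: differentiation index = distinct / answered
    for block, items in record.grid_responses.items():
        if len(items) < config.grid_min_items:
            continue
        answered = [x for x in items if x is not None]
        if not answered:
            continue
        index = len(set(answered)) / len(answered)
        if index <= config.differentiation_threshold:
            strikes.append(_strike(
                "straight_lining",
                f"grid {block}: differentiation index {index:.2f} <= "
                f"{config.differentiation_threshold:g}",
            ))
            break

    # (ii) item nonresponse across all grid blocks
    total = sum(len(items) for items in record.grid_responses.values())
    if total > 0:
        missing = sum(
            1 for items in record.grid_responses.values() for x in items if x is None
        )
        frac = missing / total
        if frac > config.nonresponse_threshold:
            strikes.append(_strike(
                "nonresponse",
                f"{missing}/{total} items missing ({frac:.0%}) > "
                f"{config.nonresponse_threshold:.0%}",
            ))

    # (iii) text quality: all blank, gibberish, or verbatim duplication
    texts = record.text_responses
    if texts:
        nonblank = {k: v for k, v in texts.items() if v.strip()}
        if not nonblank:
            strikes.append(_strike(
                "text_quality", "all text entry boxes left blank"
            ))
        else:
            gibberish = [
                (k, f)
                for k, f in ((k, _vowel_token_fraction(v)) for k, v in nonblank.items())
                if f is not None and f < config.gibberish_vowel_fraction
            ]
            seen: dict[str, str] = {}
            duplicated = None
            for k in sorted(nonblank):
                v = nonblank[k]
                if v in seen.values():
                    duplicated = v
                    break
                seen[k] = v
            if gibberish:
                k, f = gibberish[0]
                strikes.append(_strike(
                    "text_quality",
                    f"text response {k}: vowel-bearing token fraction {f:.2f} < "
                    f"{config.gibberish_vowel_fraction:g}",
                ))
            elif duplicated is not None:
                strikes.append(_strike(
                    "text_quality",
                    f"text response duplicated verbatim across prompts: {duplicated[:40]!r}",
                ))

    # (iv) every option of the discrimination multi-response block selected
    vocabulary = config.peripheral_discrimination | config.core_discrimination
    if vocabulary and vocabulary <= set(record.discrimination_attributes):
        strikes.append(_strike(
            "all_options",
            f"all {len(vocabulary)} options of the discrimination block selected",
        ))

    # (v) verification items
    failed = [
        (item, instructed, given)
        for item, (instructed, given) in sorted(record.verification_items.items())
        if instructed != given
    ]
    if failed:
        item, instructed, given = failed[0]
        strikes.append(_strike(
            "verification",
            f"verification item {item}: instructed {instructed:g}, answered {given:g}",
        ))
    return strikes


def collect_strikes(
    record: SubmissionRecord,
    context: Optional[DedupContext],
    geo: Optional[GeoTable],
    config: RuleConfig,
    cohort_median_minutes: Optional[float] = None,
    audit: Optional[AuditLog] = None,
) -> list[Strike]:
    """All strikes for one record, honoring ``config.disabled_rules``."""
    strikes: list[Strike] = []
    if context is not None:
        strikes.extend(context.strikes_for(record))
    s = check_completion_time(record, cohort_median_minutes, config, audit)
    if s is not None:
        strikes.append(s)
    if geo is not None:
        s = check_geo_consistency(record, geo, audit)
        if s is not None:
            strikes.append(s)
    strikes.extend(evaluate_clinical_profile(record, config))
    strikes.extend(evaluate_response_style(record, config))
    return [s for s in strikes if config.rule_enabled(s.rule_id)]
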