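"""Synthetic-cohort simulator: valid respondents, spam waves, ground truth.

No raw data from any real survey is available or shipped; instead this
module generates cohorts that emulate the study conditions, with
ground-truth labels, so the whole screening pipeline is verifiable at desk
scale. The valid cohort mimics older North American prostate-cancer
survivors: age from a truncated normal with mean 63.42 y and SD 8.19 y on
[40, 95] (the parent normal's parameters are solved numerically so the
*truncated* distribution has exactly the target moments), 45-60 minute
completion times during the day, 69.4% reporting successfully treated
cancer, personalized emails, IPs consistent with their zip region in the
bundled synthetic geo table, and varied grid/text responses.

Two spam profiles mirror the anatomy of a spam attack on such a survey:

* ``naive`` — blatant: 5-25 minute durations, age at diagnosis 18-35,
  PSA > 20 or "forgotten", Gleason 7-10, impossible treatment sequences,
  convention emails at one host, duplicate IPs, blank text boxes,
  straight-lined grids, failed verification items, a shared bogus birth
  date, geo-mismatched IPs, and early-morning chained submissions. Every
  naive record triggers at least three default indicators by construction.
* ``evolved`` — clinical and style fields drawn from the valid
  distributions (indistinguishable under clinical rules alone), but
  retaining at least three metadata signatures chosen from
  {email_convention, adjacency, odd_hour, geo_mismatch}.

Pseudo-random streams are split per record (seed, stream, index), so
adding a spam wave never perturbs the valid records generated under the
same seed, and a fixed seed yields byte-identical output.
"""
from __future__ import annotations

import datetime as dt
from functools import lru_cache
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.optimize import fsolve
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm

from .geo import REGION_SPECS, region_utc_offset
from .model import CancerStatus, CompletionStatus, SubmissionRecord

SIGNATURES = ("email_convention", "adjacency", "odd_hour", "geo_mismatch")

_REGIONS = list(REGION_SPECS)

_FIRST = [
    "james", "robert", "michael", "david", "richard", "thomas", "daniel",
    "paul", "mark", "donald", "george", "kenneth", "steven", "edward",
    "brian", "ronald", "anthony", "kevin", "jason", "jeffrey", "gary",
    "timothy", "jose", "larry", "frank", "scott", "eric", "stephen",
    "andrew", "raymond", "gregory", "joshua", "jerry", "dennis", "walter",
    "patrick", "peter", "harold", "douglas", "henry",
]
_LAST = [
    "smith", "johnson", "williams", "brown", "jones", "garcia", "miller",
    "davis", "rodriguez", "martinez", "hernandez", "lopez", "gonzalez",
    "wilson", "anderson", "thomas", "taylor", "moore", "jackson", "martin",
    "lee", "perez", "thompson", "white", "harris", "sanchez", "clark",
    "ramirez", "lewis", "robinson", "walker", "young", "allen", "king",
    "wright", "scott", "torres", "nguyen", "hill", "flores",
]
_DOMAINS = [
    "gmail.example", "yahoo.example", "aol.example", "hotmail.example",
    "outlook.example", "comcast.example", "verizon.example", "icloud.example",
    "earthlink.example", "sbcglobal.example", "att.example", "cox.example",
    "charter.example", "juno.example", "mac.example", "msn.example",
    "roadrunner.example", "bellsouth.example", "optonline.example",
    "frontier.example", "centurylink.example", "windstream.example",
    "mindspring.example", "rcn.example",
]
_WORDS = [
    "treatment", "recovery", "surgeon", "doctor", "helpful", "support",
    "partner", "surgery", "radiation", "therapy", "difficult", "honest",
    "questions", "answers", "hospital", "clinic", "follow", "visits",
    "energy", "fatigue", "sleep", "exercise", "walking", "diet",
    "medication", "side", "effects", "improved", "slowly", "better",
    "worried", "anxious", "relieved", "grateful", "community", "group",
    "online", "information", "decision", "options", "biopsy", "results",
    "waiting", "appointment", "nurse", "caring", "listened", "explained",
    "intimacy", "confidence", "routine", "monitoring", "checkup", "stable",
    "hopeful", "managing", "coping", "adjusting", "healing", "time",
]
_VALID_TREATMENTS = [
    [("prostatectomy", "urologist")],
    [("prostatectomy", "surgeon")],
    [("radiation", "radiation_oncologist")],
    [("active_surveillance", "urologist")],
    [("prostatectomy", "urologist"), ("radiation", "radiation_oncologist")],
    [("radiation", "radiation_oncologist"), ("hormone_therapy", "oncologist")],
    [("hormone_therapy", "oncologist")],
]
_VALID_REHAB = ["pelvic_floor_exercises", "ed_medication", "counseling", "peer_support"]
_VALID_DISCRIMINATION = [
    [],
    ["sexual_orientation"],
    ["race"],
    ["sexual_orientation", "weight"],
    ["race", "appearance"],
]
_TEXT_PROMPTS = ["treatment_experience", "rehab_needs", "final_comments"]
_GRID_BLOCKS = [("sexual_function", 10), ("mental_health", 8)]

_NAIVE_HOST = "me.example"
_EVOLVED_HOST = "inbox.example"


class SpamWave(BaseModel):
    model_config = ConfigDict(extra="forbid")

    start_day: int = Field(ge=0)
    n: int = Field(ge=0)
    profile: Literal["naive", "evolved"]
    channel_id: str = "link_a"


class CohortScenario(BaseModel):
    """Parameters of one synthetic study: valid cohort + spam waves + channels."""

    model_config = ConfigDict(extra="forbid")

    n_valid: int = Field(ge=0)
    waves: list[SpamWave] = Field(default_factory=list)
    age_mean: float = 63.42
    age_sd: float = 8.19
    age_bounds: tuple[float, float] = (40.0, 95.0)
    valid_duration_minutes: tuple[float, float] = (45.0, 60.0)
    successfully_treated_fraction: float = Field(default=0.694, ge=0.0, le=1.0)
    spam_duration_minutes: tuple[float, float] = (5.0, 25.0)
    spam_age_dx_range: tuple[int, int] = (18, 35)
    evolved_signatures: tuple[str, ...] = ("email_convention", "adjacency", "odd_hour")
    diversion_day: Optional[int] = None
    start_date: dt.date = dt.date(2015, 10, 21)
    span_days: int = Field(default=72, ge=1)
    seed: int = Field(default=0, ge=0)
    valid_channel: str = "link_a"
    diverted_channel: str = "link_b"

    @field_validator("evolved_signatures")
    @classmethod
    def _check_signatures(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        unknown = set(v) - set(SIGNATURES)
        if unknown:
            raise ValueError(f"unknown evolved signature(s): {sorted(unknown)}")
        if len(set(v)) < 3:
            raise ValueError(
                "evolved_signatures must contain at least 3 distinct signatures so "
                "evolved spam still accrues enough strikes to be detectable"
            )
        return tuple(dict.fromkeys(v))

    @model_validator(mode="after")
    def _check_bounds(self) -> "CohortScenario":
        if self.age_bounds[0] >= self.age_bounds[1]:
            raise ValueError("age_bounds must be ordered")
        sigs = set(self.evolved_signatures)
        for w in self.waves:
            if w.profile == "evolved" and w.n > 0:
                if "email_convention" in sigs and w.n < 3:
                    raise ValueError(
                        f"evolved wave of n={w.n} cannot form an email-convention "
                        "cluster (needs >= 3)"
                    )
                if "adjacency" in sigs and w.n < 2:
                    raise ValueError(
                        f"evolved wave of n={w.n} cannot form an adjacency chain "
                        "(needs >= 2)"
                    )
        return self


@lru_cache(maxsize=32)
def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Parent (mu, sigma) whose [lo, hi]-truncation has the target mean/SD."""

    def eqs(p):
        mu, s = p[0], abs(p[1])
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    mu, s = fsolve(eqs, [mean, sd], xtol=1e-12)
    s = abs(s)
    a, b = (lo - mu) / s, (hi - mu) / s
    return float(mu), float(s), float(ndtr(a)), float(ndtr(b))


def _draw_age(rng: np.random.Generator, scenario: CohortScenario) -> float:
    mu, s, fa, fb = _matched_truncnorm(
        scenario.age_mean, scenario.age_sd, *scenario.age_bounds
    )
    z = ndtri(fa + rng.random() * (fb - fa))
    return float(np.clip(mu + s * z, *scenario.age_bounds))


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(list(key))


def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def _sentence(rng: np.random.Generator) -> str:
    k = int(rng.integers(6, 13))
    return " ".join(_pick(rng, _WORDS) for _ in range(k))


def _letters(rng: np.random.Generator, k: int) -> str:
    return "".join(chr(97 + int(rng.integers(26))) for _ in range(k))


def _digits(rng: np.random.Generator, k: int) -> str:
    return "".join(str(int(rng.integers(10))) for _ in range(k))


def _personal_email(rng: np.random.Generator) -> str:
    first, last = _pick(rng, _FIRST), _pick(rng, _LAST)
    dom = _pick(rng, _DOMAINS)
    digits = _digits(rng, int(rng.integers(1, 5)))
    pattern = int(rng.integers(8))
    if pattern == 0:
        handle = f"{first}.{last}"
    elif pattern == 1:
        handle = f"{first}_{last}"
    elif pattern == 2:
        handle = f"{first}{last}"
    elif pattern == 3:
        handle = f"{first}.{last}{digits}"
    elif pattern == 4:
        handle = f"{first}{digits}"
    elif pattern == 5:
        handle = f"{last}.{first[0]}{digits}"
    elif pattern == 6:
        handle = f"{first[0]}{last}{digits}"
    else:
        handle = f"{last}{first}"
    return f"{handle}@{dom}"


def _valid_clinical(rng: np.random.Generator, scenario: CohortScenario, age_years: int):
    age_dx = max(40, age_years - int(rng.integers(0, 11)))
    psa = round(float(rng.uniform(3.0, 15.0)), 1)
    gleason = int(_pick(rng, [3, 4, 5, 6, 6, 6]))
    if rng.random() < scenario.successfully_treated_fraction:
        status = CancerStatus.successfully_treated
    else:
        status = CancerStatus.in_treatment if rng.random() < 0.5 else CancerStatus.progressed
    return age_dx, psa, gleason, status


def _valid_style(rng: np.random.Generator):
    grids = {}
    for block, size in _GRID_BLOCKS:
        items = rng.integers(1, 6, size=size)
        while len(set(items.tolist())) < 3:  # varied responders differentiate
            items = rng.integers(1, 6, size=size)
        grids[block] = [float(x) for x in items]
    verify = {"grid_check_a": (2.0, 2.0)}
    texts = {prompt: _sentence(rng) for prompt in _TEXT_PROMPTS}
    return grids, verify, texts


def _valid_social(rng: np.random.Generator, disclosure: bool):
    rehab = sorted(
        set(_pick(rng, _VALID_REHAB) for _ in range(int(rng.integers(0, 3))))
    )
    if disclosure and rng.random() < 0.2:
        rehab.append("dilator")
    discrimination = list(_pick(rng, _VALID_DISCRIMINATION))
    return rehab, discrimination


def _birth_date(rng: np.random.Generator, year_of_end: int, age_years: int) -> dt.date:
    return dt.date(
        year_of_end - age_years, 1 + int(rng.integers(12)), 1 + int(rng.integers(28))
    )


def _region_zip(rng: np.random.Generator, region: str) -> str:
    _, zips, _ = REGION_SPECS[region]
    return _pick(rng, zips) + _digits(rng, 2)


def _region_ip(region: str, slot: int, octet_base: int, octet_span: int) -> str:
    _, _, prefixes = REGION_SPECS[region]
    prefix = prefixes[(slot // octet_span) % len(prefixes)]
    return f"{prefix}.{octet_base + slot % octet_span}"


def _chain_sizes(n: int, cap: int) -> list[int]:
    sizes = []
    remaining = n
    while remaining > 0:
        take = min(cap, remaining)
        sizes.append(take)
        remaining -= take
    if len(sizes) >= 2 and sizes[-1] == 1:
        sizes[-2] -= 1
        sizes[-1] += 1
    return sizes


def _generate_valid(scenario: CohortScenario, seed: int) -> list[SubmissionRecord]:
    records = []
    for i in range(scenario.n_valid):
        rng = _rng(seed, 0, i)
        region = _pick(rng, _REGIONS)
        tz = region_utc_offset(region)
        day = int(rng.integers(scenario.span_days))
        start = dt.datetime.combine(
            scenario.start_date + dt.timedelta(days=day),
            dt.time(8 + int(rng.integers(12)), int(rng.integers(60)), int(rng.integers(60))),
            tz,
        )
        lo, hi = scenario.valid_duration_minutes
        end = start + dt.timedelta(minutes=float(rng.uniform(lo, hi)))
        age_years = int(round(_draw_age(rng, scenario)))
        age_dx, psa, gleason, status = _valid_clinical(rng, scenario, age_years)
        grids, verify, texts = _valid_style(rng)
        disclosure = bool(rng.random() < 0.85)
        rehab, discrimination = _valid_social(rng, disclosure)
        channel = scenario.valid_channel
        if scenario.diversion_day is not None and day >= scenario.diversion_day:
            channel = scenario.diverted_channel
        records.append(
            SubmissionRecord(
                submission_id=f"V{i:05d}",
                channel_id=channel,
                start_timestamp=start,
                end_timestamp=end,
                ip_address=_region_ip(region, i, 1, 120),
                email_address=_personal_email(rng),
                zip_code=_region_zip(rng, region),
                birth_date=_birth_date(rng, end.year, age_years),
                age_years=age_years,
                age_at_diagnosis=min(age_dx, age_years),
                psa_at_diagnosis=psa,
                gleason_total=gleason,
                treatment_history=_pick(rng, _VALID_TREATMENTS),
                disclosure_to_provider=disclosure,
                rehab_recommendations=rehab,
                discrimination_attributes=discrimination,
                cancer_status=status,
                grid_responses=grids,
                verification_items=verify,
                text_responses=texts,
                completion_status=CompletionStatus.complete,
            )
        )
    return records


def _two_regions(wrng: np.random.Generator) -> tuple[str, str]:
    i = int(wrng.integers(len(_REGIONS)))
    j = (i + 1 + int(wrng.integers(len(_REGIONS) - 1))) % len(_REGIONS)
    return _REGIONS[i], _REGIONS[j]


def _generate_naive_wave(
    scenario: CohortScenario, seed: int, wi: int, wave: SpamWave
) -> list[SubmissionRecord]:
    wrng = _rng(seed, 1, wi)
    region_ip, region_zip = _two_regions(wrng)
    tz = region_utc_offset(region_zip)
    _, _, prefixes = REGION_SPECS[region_ip]
    octets = wrng.choice(np.arange(128, 251), size=3, replace=False)
    wave_ips = [f"{_pick(wrng, prefixes)}.{int(o)}" for o in octets]
    sizes = _chain_sizes(wave.n, 10)
    records = []
    j = 0
    for chain_idx, size in enumerate(sizes):
        cursor = dt.datetime.combine(
            scenario.start_date + dt.timedelta(days=wave.start_day + chain_idx),
            dt.time(0, 5),
            tz,
        )
        for _ in range(size):
            rng = _rng(seed, 1, wi, j)
            lo, hi = scenario.spam_duration_minutes
            start = cursor + dt.timedelta(seconds=float(rng.uniform(5, 30)))
            end = start + dt.timedelta(minutes=float(rng.uniform(lo, hi)))
            cursor = end
            dx_lo, dx_hi = scenario.spam_age_dx_range
            age_dx = int(rng.integers(dx_lo, dx_hi + 1))
            psa = None if rng.random() < 0.3 else round(float(rng.uniform(21.0, 80.0)), 1)
            records.append(
                SubmissionRecord(
                    submission_id=f"N{wi:02d}{j:04d}",
                    channel_id=wave.channel_id,
                    start_timestamp=start,
                    end_timestamp=end,
                    ip_address=wave_ips[j % 3],
                    email_address=f"{_letters(rng, 3)}{_digits(rng, 3)}@{_NAIVE_HOST}",
                    zip_code=_region_zip(rng, region_zip),
                    birth_date=dt.date(1901, 1, 1),
                    age_years=age_dx + int(rng.integers(0, 6)),
                    age_at_diagnosis=age_dx,
                    psa_at_diagnosis=psa,
                    gleason_total=int(rng.integers(7, 11)),
                    treatment_history=[
                        ("prostatectomy", "oncologist"),
                        ("watchful_waiting", "urologist"),
                        ("radiation", "urologist"),
                        ("diet", "none"),
                    ],
                    disclosure_to_provider=False,
                    rehab_recommendations=["dilator", "dildo", "butt_plug"],
                    discrimination_attributes=["weight", "height", "appearance"],
                    cancer_status=CancerStatus.successfully_treated,
                    grid_responses={
                        block: [float(rng.integers(1, 6))] * size_
                        for block, size_ in _GRID_BLOCKS
                    },
                    verification_items={
                        "grid_check_a": (2.0, float(_pick(rng, [1, 3, 4, 5])))
                    },
                    text_responses={prompt: "" for prompt in _TEXT_PROMPTS},
                    completion_status=CompletionStatus.complete,
                )
            )
            j += 1
    return records


def _generate_evolved_wave(
    scenario: CohortScenario, seed: int, wi: int, wave: SpamWave
) -> list[SubmissionRecord]:
    sigs = set(scenario.evolved_signatures)
    wrng = _rng(seed, 1, wi)
    if "geo_mismatch" in sigs:
        region_ip, region_zip = _two_regions(wrng)
    else:
        region_ip = region_zip = _pick(wrng, _REGIONS)
    tz = region_utc_offset(region_zip)
    adjacency = "adjacency" in sigs
    odd_hour = "odd_hour" in sigs
    cap = 4 if (adjacency and odd_hour) else 6
    sizes = _chain_sizes(wave.n, cap) if adjacency else None

    records = []
    j = 0
    chains = sizes if adjacency else [1] * wave.n
    for chain_idx, size in enumerate(chains):
        if adjacency:
            base_time = dt.time(0, 1) if odd_hour else dt.time(9, 0)
            cursor = dt.datetime.combine(
                scenario.start_date + dt.timedelta(days=wave.start_day + chain_idx),
                base_time,
                tz,
            )
        for _ in range(size):
            rng = _rng(seed, 1, wi, j)
            lo, hi = scenario.valid_duration_minutes
            duration = dt.timedelta(minutes=float(rng.uniform(lo, hi)))
            if adjacency:
                start = cursor + dt.timedelta(seconds=float(rng.uniform(10, 40)))
                end = start + duration
                cursor = end
            elif odd_hour:
                night = scenario.start_date + dt.timedelta(days=wave.start_day + j // 6)
                end = dt.datetime.combine(night, dt.time(0, 30), tz) + dt.timedelta(
                    minutes=float(rng.uniform(0, 210))
                )
                start = end - duration
            else:
                day = wave.start_day + j // 6
                start = dt.datetime.combine(
                    scenario.start_date + dt.timedelta(days=day),
                    dt.time(8 + int(rng.integers(12)), int(rng.integers(60))),
                    tz,
                )
                end = start + duration
            age_years = int(round(_draw_age(rng, scenario)))
            age_dx, psa, gleason, status = _valid_clinical(rng, scenario, age_years)
            grids, verify, texts = _valid_style(rng)
            disclosure = bool(rng.random() < 0.85)
            rehab, discrimination = _valid_social(rng, disclosure)
            if "email_convention" in sigs:
                email = f"{_letters(rng, 4)}{_digits(rng, 2)}@{_EVOLVED_HOST}"
            else:
                email = _personal_email(rng)
            records.append(
                SubmissionRecord(
                    submission_id=f"E{wi:02d}{j:04d}",
                    channel_id=wave.channel_id,
                    start_timestamp=start,
                    end_timestamp=end,
                    ip_address=_region_ip(region_ip, j, 128, 120),
                    email_address=email,
                    zip_code=_region_zip(rng, region_zip),
                    birth_date=_birth_date(rng, end.year, age_years),
                    age_years=age_years,
                    age_at_diagnosis=min(age_dx, age_years),
                    psa_at_diagnosis=psa,
                    gleason_total=gleason,
                    treatment_history=_pick(rng, _VALID_TREATMENTS),
                    disclosure_to_provider=disclosure,
                    rehab_recommendations=rehab,
                    discrimination_attributes=discrimination,
                    cancer_status=status,
                    grid_responses=grids,
                    verification_items=verify,
                    text_responses=texts,
                    completion_status=CompletionStatus.complete,
                )
            )
            j += 1
    return records


def generate_cohort(
    scenario: CohortScenario, seed: Optional[int] = None
) -> tuple[list[SubmissionRecord], dict[str, str]]:
    """Generate the full cohort with ground-truth labels.

    Returns ``(records, labels)`` where labels maps submission_id to one of
    ``valid``, ``naive`` or ``evolved``. Valid records come first, then the
    waves in scenario order; a fixed seed yields byte-identical output.
    """
    seed = scenario.seed if seed is None else seed
    if seed < 0:
        raise ValueError("seed must be non-negative")
    records = _generate_valid(scenario, seed)
    labels = {r.submission_id: "valid" for r in records}
    for wi, wave in enumerate(scenario.waves):
        if wave.profile == "naive":
            wave_records = _generate_naive_wave(scenario, seed, wi, wave)
        else:
            wave_records = _generate_evolved_wave(scenario, seed, wi, wave)
        records.extend(wave_records)
        labels.update({r.submission_id: wave.profile for r in wave_records})
    return records, labels


def make_dual_link_scenario(
    base: CohortScenario, diversion_day: int, seed: Optional[int] = None
) -> tuple[list[SubmissionRecord], list[SubmissionRecord], dict[str, str]]:
    """Dual-link diversion: route newly recruited valid respondents elsewhere.

    From ``diversion_day`` onward, valid records move to the restricted
    channel (``base.diverted_channel``); spam stays on its original
    channel. Returns (original-channel records, restricted-channel records,
    labels).
    """
    scenario = base.model_copy(update={"diversion_day": diversion_day})
    records, labels = generate_cohort(scenario, seed)
    channel_b = [r for r in records if r.channel_id == scenario.diverted_channel]
    channel_a = [r for r in records if r.channel_id != scenario.diverted_channel]
    return channel_a, channel_b, labels
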