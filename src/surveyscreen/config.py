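"""Rule configuration: every threshold and switch of the screening protocol.

A :class:`RuleConfig` is one versioned era of the protocol. A protocol
history is a list of configs with non-overlapping effective windows; a
retrospective pass re-applies a single final config uniformly.

Defaults encode the study protocol this package operationalizes: surveys
under 30 minutes on a 45-60 minute instrument are speeding; PSA above 20
ng/mL and Gleason totals above 6 at diagnosis are statistically unlikely;
prostate-cancer diagnosis before age 40 is rarer than 1 in 10,000; and no
single indicator may invalidate a submission ("three strikes and you're
out", so ``strike_threshold_k >= 2`` is enforced).
"""
from __future__ import annotations

import datetime as dt
import json
import math
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from pydantic import ValidationError

from .exceptions import ConfigurationError

DEFAULT_FORBIDDEN_TRANSITIONS: frozenset[tuple[str, str]] = frozenset(
    {
        # definitive local therapy followed by mere observation
        ("prostatectomy", "watchful_waiting"),
        ("prostatectomy", "active_surveillance"),
        # "diet" as a treatment following definitive therapy
        ("prostatectomy", "diet"),
        ("radiation", "diet"),
        ("chemotherapy", "diet"),
        ("hormone_therapy", "diet"),
    }
)

DEFAULT_PROVIDER_COMPAT: dict[str, frozenset[str]] = {
    "prostatectomy": frozenset({"urologist", "surgeon"}),
    "radiation": frozenset({"radiation_oncologist"}),
    "chemotherapy": frozenset({"oncologist"}),
    "hormone_therapy": frozenset({"oncologist", "urologist"}),
}

DEFAULT_DISCLOSURE_REQUIRED_REHAB = frozenset({"dilator", "dildo", "butt_plug"})
DEFAULT_PERIPHERAL_DISCRIMINATION = frozenset({"weight", "height", "appearance"})
DEFAULT_CORE_DISCRIMINATION = frozenset({"race", "sexual_orientation"})


class RuleConfig(BaseModel):
    """Thresholds and switches for one era of the screening protocol."""

    model_config = ConfigDict(extra="forbid")

    config_id: str = "default"
    effective_start: Optional[dt.date] = None
    effective_end: Optional[dt.date] = None  # half-open: [start, end)

    # speeding
    duration_min_minutes: float = 30.0
    relative_speed_enabled: bool = False
    relative_speed_fraction: float = 1.0 / 3.0

    # clinical plausibility
    age_dx_min: int = 40
    psa_max: float = 20.0
    gleason_max: int = 6
    forbidden_transitions: set[tuple[str, str]] = Field(
        default_factory=lambda: set(DEFAULT_FORBIDDEN_TRANSITIONS)
    )
    provider_compat: dict[str, set[str]] = Field(
        default_factory=lambda: {k: set(v) for k, v in DEFAULT_PROVIDER_COMPAT.items()}
    )
    disclosure_required_rehab: set[str] = Field(
        default_factory=lambda: set(DEFAULT_DISCLOSURE_REQUIRED_REHAB)
    )
    peripheral_discrimination: set[str] = Field(
        default_factory=lambda: set(DEFAULT_PERIPHERAL_DISCRIMINATION)
    )
    core_discrimination: set[str] = Field(
        default_factory=lambda: set(DEFAULT_CORE_DISCRIMINATION)
    )

    # response style
    grid_min_items: int = 5
    differentiation_threshold: float = 0.2
    nonresponse_threshold: float = 0.2
    gibberish_vowel_fraction: float = 0.5

    # dataset-level dedup signals
    email_cluster_min: int = Field(default=3, ge=2)
    adjacency_gap_seconds: float = 60.0
    odd_hour_start: dt.time = dt.time(0, 0)
    odd_hour_end: dt.time = dt.time(5, 0)  # half-open window [start, end)
    shared_anomaly_min: int = Field(default=3, ge=2)
    shared_anomaly_fields: list[str] = Field(default_factory=lambda: ["birth_date"])
    ip_prefix_grouping: bool = False  # optional /24 near-duplicate grouping

    # adjudication and drift
    strike_threshold_k: int = 3
    drift_window_days: int = Field(default=7, ge=1)
    drift_delta: float = 0.3

    # rule switches and CSV field mapping
    disabled_rules: set[str] = Field(default_factory=set)
    field_mapping: dict[str, str] = Field(default_factory=dict)

    @field_validator("strike_threshold_k")
    @classmethod
    def _k_at_least_two(cls, v: int) -> int:
        if v < 2:
            raise ValueError(
                "strike_threshold_k must be >= 2: no single indicator is "
                "sufficient to call a submission invalid"
            )
        return v

    @model_validator(mode="after")
    def _finite_thresholds(self) -> "RuleConfig":
        for name in (
            "duration_min_minutes",
            "relative_speed_fraction",
            "psa_max",
            "differentiation_threshold",
            "nonresponse_threshold",
            "gibberish_vowel_fraction",
            "adjacency_gap_seconds",
            "drift_delta",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if (
            self.effective_start is not None
            and self.effective_end is not None
            and self.effective_end <= self.effective_start
        ):
            raise ValueError("effective_end must be after effective_start")
        return self

    def covers(self, day: dt.date) -> bool:
        """True when ``day`` falls in this config's half-open effective window."""
        if self.effective_start is not None and day < self.effective_start:
            return False
        if self.effective_end is not None and day >= self.effective_end:
            return False
        return True

    def rule_enabled(self, rule_id: str) -> bool:
        return rule_id not in self.disabled_rules


def load_rule_config(path: Union[str, Path, None]) -> RuleConfig:
    """Load a JSON or YAML rule configuration; absent keys get defaults.

    ``path=None`` or an empty file yields the full default configuration.
    Unknown keys and ``strike_threshold_k < 2`` raise
    :class:`ConfigurationError`.
    """
    if path is None:
        return RuleConfig()
    p = Path(path)
    try:
        text = p.read_text(encoding="utf-8")
    except OSError as exc:
        raise ConfigurationError(f"cannot read config file {p}: {exc}") from exc
    try:
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"config file {p} is not valid JSON/YAML: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {p} must contain a mapping at top level")
    return rule_config_from_dict(data)


def rule_config_from_dict(data: dict) -> RuleConfig:
    """Validate a config mapping, translating errors into readable messages."""
    try:
        return RuleConfig(**data)
    except ValidationError as exc:
        unknown = [
            str(e["loc"][0]) for e in exc.errors() if e["type"] == "extra_forbidden"
        ]
        if unknown:
            allowed = ", ".join(sorted(RuleConfig.model_fields))
            raise ConfigurationError(
                f"unknown config key(s): {', '.join(unknown)}; allowed keys: {allowed}"
            ) from exc
        msgs = "; ".join(
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration: {msgs}") from exc


def dump_rule_config(config: RuleConfig) -> dict:
    """JSON-compatible dict such that loading it reproduces ``config``."""
    data = config.model_dump(mode="json")
    # deterministic ordering for set-typed fields
    for key in (
        "forbidden_transitions",
        "disclosure_required_rehab",
        "peripheral_discrimination",
        "core_discrimination",
        "disabled_rules",
    ):
        data[key] = sorted(data[key])
    data["provider_compat"] = {k: sorted(v) for k, v in sorted(data["provider_compat"].items())}
    return data


def save_rule_config(config: RuleConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(dump_rule_config(config), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
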