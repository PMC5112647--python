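"""Run configuration: YAML schema, validation and defaults.

An empty (or absent) configuration file reproduces the base case: a
07:30-16:00 OR day, five scheduled procedures on each of 21 working
days, 10.7% other-reason cancellations, a 14-minute per-procedure
saving for verified sugammadex patients, a 60% unverified RNMB risk
under neostigmine reduced 93% by sugammadex, and 24.5%/44.2% excess
complication risks.  Unknown keys are rejected with an error naming the
field.  Clock times may be given as "HH:MM" (24 h) or "h:MM AM/PM".
"""

from __future__ import annotations

import re
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .compare import DEFAULT_SAVINGS_GRID, DEFAULT_SCENARIOS
from .day import CANCEL_POLICIES, DurationModel, ORPolicy
from .outcomes import ComplicationRisks, ReversalArm
from .variates import ConfigurationError, DistributionSpec

__all__ = ["RunConfig", "load_config", "parse_clock"]

ANALYSES = ("base", "sensitivity", "deep_block", "all")

_CLOCK_RE = re.compile(r"^\s*(\d{1,2}):(\d{2})\s*(AM|PM)?\s*$", re.IGNORECASE)


def parse_clock(value: int | str) -> int:
    """Clock time -> minutes since midnight ("7:30 AM" -> 450)."""
    if isinstance(value, int):
        if not (0 <= value < 24 * 60):
            raise ConfigurationError(f"clock minute must be in [0, 1440), got {value}")
        return value
    m = _CLOCK_RE.match(str(value))
    if not m:
        raise ConfigurationError(f"cannot parse clock time {value!r}; expected 'HH:MM [AM/PM]'")
    hh, mm, ampm = int(m.group(1)), int(m.group(2)), m.group(3)
    if mm >= 60 or hh > 23 or (ampm and not 1 <= hh <= 12):
        raise ConfigurationError(f"clock time {value!r} out of range")
    if ampm:
        hh = hh % 12 + (12 if ampm.upper() == "PM" else 0)
    return 60 * hh + mm


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DistributionConfig(_Model):
    """Either {kind, params} or an Arena-dialect string {arena: "..."}"""

    kind: str | None = None
    params: list[float] | None = None
    arena: str | None = None

    def to_spec(self, default: DistributionSpec) -> DistributionSpec:
        if self.arena is not None:
            if self.kind is not None or self.params is not None:
                raise ConfigurationError(
                    "give either 'arena' or 'kind'/'params' for a distribution, not both"
                )
            return DistributionSpec.from_arena(self.arena)
        if self.kind is None and self.params is None:
            return default
        if self.kind is None or self.params is None:
            raise ConfigurationError("distribution needs both 'kind' and 'params'")
        return DistributionSpec(self.kind, tuple(self.params))


class DistributionsConfig(_Model):
    procedure: DistributionConfig = DistributionConfig()
    turnover: DistributionConfig = DistributionConfig()
    first_patient_delay: DistributionConfig = DistributionConfig()
    cleanup: DistributionConfig = DistributionConfig()

    def to_model(self) -> DurationModel:
        d = DurationModel()
        return DurationModel(
            procedure=self.procedure.to_spec(d.procedure),
            turnover=self.turnover.to_spec(d.turnover),
            first_patient_delay=self.first_patient_delay.to_spec(d.first_patient_delay),
            cleanup=self.cleanup.to_spec(d.cleanup),
        )


class PolicyConfig(_Model):
    day_start: int | str = "07:30"
    day_end: int | str = "16:00"
    procedures_per_day: int = Field(5, ge=1)
    working_days: int = Field(21, ge=1)
    cancel_policy: str = "no_start_after_end"
    move_up_on_cancel: bool = False
    p_other_cancel: float = Field(0.107, ge=0.0, le=1.0)
    p_emergency: float = Field(0.0, ge=0.0, le=1.0)
    p_semi_emergency: float = Field(0.0, ge=0.0, le=1.0)
    overtime_increment_min: float = Field(30.0, gt=0.0)
    overtime_staff: int = Field(5, ge=1)

    def to_policy(self) -> ORPolicy:
        if self.cancel_policy not in CANCEL_POLICIES:
            raise ConfigurationError(
                f"cancel_policy must be one of {CANCEL_POLICIES}, got {self.cancel_policy!r}"
            )
        return ORPolicy(
            day_start=parse_clock(self.day_start),
            day_end=parse_clock(self.day_end),
            procedures_per_day=self.procedures_per_day,
            working_days=self.working_days,
            cancel_policy=self.cancel_policy,
            move_up_on_cancel=self.move_up_on_cancel,
            p_other_cancel=self.p_other_cancel,
            p_emergency=self.p_emergency,
            p_semi_emergency=self.p_semi_emergency,
            overtime_increment=self.overtime_increment_min,
            overtime_staff=self.overtime_staff,
        )


class ArmConfig(_Model):
    name: str
    delta_verified: float = 0.0
    delta_unverified: float = 0.0
    rnmb_risk_unverified: float = Field(ge=0.0, le=1.0)

    def to_arm(self) -> ReversalArm:
        return ReversalArm(
            self.name, self.delta_verified, self.delta_unverified, self.rnmb_risk_unverified
        )


class ArmsConfig(_Model):
    # comparator default: 0.60 * (1 - 0.93) = 0.042 unverified RNMB risk
    reference: ArmConfig = ArmConfig(name="neostigmine", rnmb_risk_unverified=0.60)
    comparator: ArmConfig = ArmConfig(
        name="sugammadex", delta_verified=-14.0, rnmb_risk_unverified=0.042
    )


class RisksConfig(_Model):
    hypoxemia_excess: float = Field(0.245, ge=0.0, le=1.0)
    airway_obstruction_excess: float = Field(0.442, ge=0.0, le=1.0)

    def to_risks(self) -> ComplicationRisks:
        return ComplicationRisks(self.hypoxemia_excess, self.airway_obstruction_excess)


class DeepBlockConfig(_Model):
    procedures_per_day: int = Field(3, ge=1)
    procedure_mean_min: float = Field(145.0, gt=0.0)
    savings_grid_min: list[float] = Field(default_factory=lambda: list(DEFAULT_SAVINGS_GRID))


class RunConfig(_Model):
    """Validated top-level run configuration."""

    policy: PolicyConfig = PolicyConfig()
    distributions: DistributionsConfig = DistributionsConfig()
    arms: ArmsConfig = ArmsConfig()
    risks: RisksConfig = RisksConfig()
    scenarios: list[float] = Field(default_factory=lambda: list(DEFAULT_SCENARIOS))
    deep_block: DeepBlockConfig = DeepBlockConfig()
    n_replications: int = Field(50, ge=1)
    master_seed: int = Field(2016, ge=0)
    analysis: str = "base"
    output_dir: str = "results"

    def model_post_init(self, __context) -> None:
        if self.analysis not in ANALYSES:
            raise ConfigurationError(
                f"analysis must be one of {ANALYSES}, got {self.analysis!r}"
            )
        for p in self.scenarios:
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"scenarios entries must be in [0, 1], got {p}")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML configuration; ``None`` or an empty file
    yields the base-case defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(
                f"configuration root must be a mapping, got {type(raw).__name__}"
            )
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:  # re-raise with the package's error type
        raise ConfigurationError(str(exc)) from exc
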