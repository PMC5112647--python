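"""One operating-room day: sequential procedural flow on a single room.

The day opens at 07:30 with a short delay before the first patient is
admitted, then runs the scheduled slots in order.  Consecutive
activities are separated by a turnover (room cleaning/setup).  Each
scheduled slot may be

* bumped by an emergency case inserted immediately before it,
* cancelled for reasons unrelated to OR time (patient no-show,
  unavailability, ...) — an exogenous event, resolved first,
* cancelled for lack of OR time under the hospital's cancellation
  policy, evaluated at the slot's proposed start, or
* performed, with the reversal arm's per-procedure time delta applied
  according to the patient's verification status.

After the last slot a semi-emergency case may be appended, the room is
cleaned for the next day, and paid staff overtime is settled in 30-min
blocks for the eligible staff.

Timeline conventions (calibrated against the published monthly tallies;
see docs/methods.md for the rationale):

* Clock minutes are measured from the day start; the regular day is
  ``day_end - day_start`` minutes long (510 by default).
* A slot cancelled for lack of time consumes no clock time.
* A slot cancelled for other reasons blocks the room for its effective
  duration when the next procedure is not moved up (the default); with
  ``move_up_on_cancel`` the slot is skipped entirely.
* Cleanup counts toward overtime (staff stay through cleanup).
* A day is "complete" when no procedure was cancelled for lack of OR
  time and the room closed (cleanup included) by the regular day end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .outcomes import ComplicationRisks, ReversalArm
from .variates import ConfigurationError, DistributionSpec, RandomStreams

__all__ = [
    "PERFORMED",
    "CANCELLED_TIME",
    "CANCELLED_OTHER",
    "CANCEL_POLICIES",
    "ORPolicy",
    "DurationModel",
    "ProcedureOutcome",
    "DayOutcome",
    "DayDraws",
    "draw_day",
    "simulate_day",
    "simulate_day_from_draws",
    "should_cancel_for_time",
    "paid_overtime_hours",
]

PERFORMED = "performed"
CANCELLED_TIME = "cancelled_time"
CANCELLED_OTHER = "cancelled_other"

CANCEL_POLICIES = (
    "no_start_after_end",
    "cancel_if_lt_half_completable",
    "never_cancel",
)


@dataclass(frozen=True)
class ORPolicy:
    """Hospital scheduling and staffing rules for one OR.

    ``day_start``/``day_end`` are clock minutes since midnight
    (07:30 = 450, 16:00 = 960).  ``overtime_staff`` is the headcount
    eligible for overtime pay (3 RNs + 1 respiratory therapist + 1
    nurse aide by default); each is paid in ``overtime_increment``-
    minute blocks, rounded up.
    """

    day_start: int = 450
    day_end: int = 960
    procedures_per_day: int = 5
    working_days: int = 21
    cancel_policy: str = "no_start_after_end"
    move_up_on_cancel: bool = False
    p_other_cancel: float = 0.107
    p_emergency: float = 0.0
    p_semi_emergency: float = 0.0
    overtime_increment: float = 30.0
    overtime_staff: int = 5

    def __post_init__(self) -> None:
        if self.day_end <= self.day_start:
            raise ConfigurationError(
                f"day_end ({self.day_end}) must be after day_start ({self.day_start})"
            )
        for name in ("procedures_per_day", "working_days", "overtime_staff"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("p_other_cancel", "p_emergency", "p_semi_emergency"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.overtime_increment <= 0:
            raise ConfigurationError(
                f"overtime_increment must be > 0, got {self.overtime_increment}"
            )
        if self.cancel_policy not in CANCEL_POLICIES:
            raise ConfigurationError(
                f"cancel_policy must be one of {CANCEL_POLICIES}, got {self.cancel_policy!r}"
            )

    @property
    def regular_day_length(self) -> float:
        """Regular OR day in minutes (510 for 07:30-16:00)."""
        return float(self.day_end - self.day_start)


@dataclass(frozen=True)
class DurationModel:
    """The four stochastic durations driving the OR day (minutes)."""

    procedure: DistributionSpec = DistributionSpec("lognormal_mean_sd", (72.9, 29.2))
    turnover: DistributionSpec = DistributionSpec("shifted_exponential", (10.0, 25.6))
    first_patient_delay: DistributionSpec = DistributionSpec(
        "discrete_cdf", (0.5, 5.0, 1.0, 15.0)
    )
    cleanup: DistributionSpec = DistributionSpec("triangular", (7.5, 15.0, 22.5))


@dataclass(frozen=True)
class ProcedureOutcome:
    slot_index: int
    is_emergency: bool
    status: str
    start_minute: float | None
    end_minute: float | None
    drawn_duration: float
    verified: bool = False
    rnmb: bool = False
    hypoxemia: bool = False
    airway_obstruction: bool = False


@dataclass(frozen=True)
class DayOutcome:
    procedures: tuple[ProcedureOutcome, ...]
    last_procedure_end: float
    day_close: float
    overtime_hours_paid: float
    completed_within_day: bool

    def count(self, status: str, *, emergencies: bool | None = None) -> int:
        return sum(
            1
            for p in self.procedures
            if p.status == status
            and (emergencies is None or p.is_emergency == emergencies)
        )


@dataclass(frozen=True)
class DayDraws:
    """All random draws for one (replication, day), fixed before either
    arm is simulated so both arms see identical randomness.

    Patient-level uniform arrays are indexed: scheduled slot ``i`` at
    ``i``, the emergency bumping slot ``i`` at ``n + i``, and the
    semi-emergency at ``2n``.
    """

    first_delay: float
    durations: np.ndarray
    turnovers: np.ndarray
    emergency_turnovers: np.ndarray
    emergency_durations: np.ndarray
    semi_turnover: float
    semi_duration: float
    cleanup: float
    u_other_cancel: np.ndarray
    u_emergency: np.ndarray
    u_semi: float
    u_verified: np.ndarray
    u_rnmb: np.ndarray
    u_hypoxemia: np.ndarray
    u_airway: np.ndarray


def draw_day(
    streams: RandomStreams,
    model: DurationModel,
    policy: ORPolicy,
    replication: int,
    day: int,
) -> DayDraws:
    """Generate one day's worth of draws from purpose-keyed substreams."""
    n = policy.procedures_per_day
    r = lambda purpose: streams.rng(purpose, replication, day)
    npat = 2 * n + 1
    return DayDraws(
        first_delay=model.first_patient_delay.sample(r("first_patient_delay")),
        durations=model.procedure.sample(r("procedure_duration"), n),
        turnovers=model.turnover.sample(r("turnover"), n),
        emergency_turnovers=model.turnover.sample(r("emergency_turnover"), n),
        emergency_durations=model.procedure.sample(r("emergency_duration"), n),
        semi_turnover=model.turnover.sample(r("semi_emergency_turnover")),
        semi_duration=model.procedure.sample(r("semi_emergency_duration")),
        cleanup=model.cleanup.sample(r("cleanup")),
        u_other_cancel=r("other_cancel").random(n),
        u_emergency=r("emergency").random(n),
        u_semi=float(r("semi_emergency").random()),
        u_verified=r("verification").random(npat),
        u_rnmb=r("rnmb").random(npat),
        u_hypoxemia=r("hypoxemia").random(npat),
        u_airway=r("airway").random(npat),
    )


def should_cancel_for_time(
    policy: ORPolicy,
    proposed_start: float,
    drawn_duration: float,
    regular_day_length: float,
) -> bool:
    """Apply the hospital's time-cancellation policy to one slot.

    ``no_start_after_end``: cancel iff the slot would start at or after
    the regular day end.  ``cancel_if_lt_half_completable``: cancel iff
    less than half of the drawn duration fits in the remaining regular
    day.  ``never_cancel``: never.
    """
    if policy.cancel_policy == "never_cancel":
        return False
    if policy.cancel_policy == "no_start_after_end":
        return proposed_start >= regular_day_length
    return (regular_day_length - proposed_start) / drawn_duration < 0.5


def paid_overtime_hours(
    day_close: float,
    regular_day_length: float,
    increment: float,
    staff: int,
) -> float:
    """Paid staff overtime for one day, in hours.

    The overrun past the regular day end is rounded up to whole
    ``increment``-minute blocks and paid to every eligible staff member.
    """
    overrun = max(0.0, day_close - regular_day_length)
    blocks = ceil(round(overrun / increment, 9))
    return blocks * (increment / 60.0) * staff


def simulate_day_from_draws(
    policy: ORPolicy,
    arm: ReversalArm,
    risks: ComplicationRisks,
    p_verified: float,
    draws: DayDraws,
) -> DayOutcome:
    """Deterministically replay one day from pre-generated draws.

    This is the core the paired-comparison engine calls with the same
    ``draws`` for both arms; only ``arm`` differs between the calls.
    """
    n = policy.procedures_per_day
    L = policy.regular_day_length
    t = draws.first_delay
    need_turnover = False
    procs: list[ProcedureOutcome] = []
    any_time_cancel = False

    def perform(slot: int, emergency: bool, drawn: float, start: float, pidx: int) -> float:
        verified = draws.u_verified[pidx] < p_verified
        rnmb = (not verified) and draws.u_rnmb[pidx] < arm.rnmb_risk_unverified
        hyp = rnmb and draws.u_hypoxemia[pidx] < risks.hypoxemia_excess
        air = rnmb and draws.u_airway[pidx] < risks.airway_obstruction_excess
        eff = max(1.0, drawn + arm.delta(verified))
        procs.append(
            ProcedureOutcome(slot, emergency, PERFORMED, start, start + eff, drawn,
                             verified, rnmb, hyp, air)
        )
        return start + eff

    for i in range(n):
        if draws.u_emergency[i] < policy.p_emergency:
            # emergency bumps the scheduled slot; never cancelled
            start = t + (draws.emergency_turnovers[i] if need_turnover else 0.0)
            t = perform(i, True, float(draws.emergency_durations[i]), start, n + i)
            need_turnover = True

        proposed = t + (draws.turnovers[i] if need_turnover else 0.0)
        drawn = float(draws.durations[i])
        # other-reason cancellations (no-shows etc.) are exogenous and
        # resolved before the clock is consulted
        if draws.u_other_cancel[i] < policy.p_other_cancel:
            procs.append(ProcedureOutcome(i, False, CANCELLED_OTHER, None, None, drawn))
            if not policy.move_up_on_cancel:
                # slot still blocks the room for its effective duration
                verified = draws.u_verified[i] < p_verified
                t = proposed + max(1.0, drawn + arm.delta(verified))
                need_turnover = True
            continue
        if should_cancel_for_time(policy, proposed, drawn, L):
            any_time_cancel = True
            procs.append(ProcedureOutcome(i, False, CANCELLED_TIME, None, None, drawn))
            continue
        t = perform(i, False, drawn, proposed, i)
        need_turnover = True

    if draws.u_semi < policy.p_semi_emergency:
        start = t + (draws.semi_turnover if need_turnover else 0.0)
        t = perform(n, True, draws.semi_duration, start, 2 * n)

    last_end = t
    day_close = last_end + draws.cleanup
    overtime = paid_overtime_hours(
        day_close, L, policy.overtime_increment, policy.overtime_staff
    )
    completed = (not any_time_cancel) and day_close <= L
    return DayOutcome(tuple(procs), last_end, day_close, overtime, completed)


def simulate_day(
    policy: ORPolicy,
    arm: ReversalArm,
    p_verified: float,
    streams: RandomStreams,
    day_index: int,
    *,
    replication: int = 0,
    model: DurationModel | None = None,
    risks: ComplicationRisks | None = None,
) -> DayOutcome:
    """Simulate one OR day (draws generated internally)."""
    if not (0.0 <= p_verified <= 1.0):
        raise ConfigurationError(f"p_verified must be in [0, 1], got {p_verified}")
    draws = draw_day(streams, model or DurationModel(), policy, replication, day_index)
    return simulate_day_from_draws(policy, arm, risks or ComplicationRisks(), p_verified, draws)
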