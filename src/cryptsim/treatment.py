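"""Dose schedules, drug-activity timing and clinical-practicality rules.

A dose schedule for one drug is a triple ``(duration, interval, intensity)``
in simulation steps (1 step ~ 4 hours): the drug is active for ``duration``
consecutive steps starting every ``interval`` steps, at the given intensity
(a *lethality* factor for cytotoxic, 5-FU-like drugs; an apoptotic-intensity
factor, a.k.a. PTreatment/CptDieMax, for sulindac-like drugs).  The interval
is measured from the beginning of one dose to the beginning of the next.
A combination schedule pairs one cytotoxic and one apoptotic schedule,
started simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import FrozenSet, Union

__all__ = [
    "CYTOTOXIC",
    "APOPTOTIC",
    "DoseSchedule",
    "CombinationSchedule",
    "PracticalityPolicy",
    "ScheduleError",
    "is_dose_active",
    "steps_to_days",
    "accumulated_dose",
    "is_practical",
]

CYTOTOXIC = "cytotoxic"
APOPTOTIC = "apoptotic"

#: Hours of human time represented by one simulation step.
HOURS_PER_STEP = 4


class ScheduleError(ValueError):
    """Raised for an invalid dose schedule."""


@dataclass(frozen=True)
class DoseSchedule:
    """One drug's intermittent dose schedule.

    ``interval <= duration`` (continuous dosing) is representable so that
    full enumeration grids can be constructed, but such schedules are
    rejected at execution time; see :meth:`executable`.
    """

    drug_kind: str
    duration: int
    interval: int
    intensity: float

    def __post_init__(self) -> None:
        if self.drug_kind not in (CYTOTOXIC, APOPTOTIC):
            raise ScheduleError(f"unknown drug kind {self.drug_kind!r}")
        if self.duration < 1:
            raise ScheduleError("duration must be >= 1 step")
        if self.interval < 2 or self.interval % 2 != 0:
            raise ScheduleError("interval must be an even number of steps >= 2")
        if not self.intensity > 0:
            raise ScheduleError("intensity must be positive")

    @property
    def executable(self) -> bool:
        """Executed schedules require the interval to exceed the duration."""
        return self.interval > self.duration

    @property
    def duty_fraction(self) -> float:
        """Fraction of steps with the dose active over one period."""
        return min(self.duration, self.interval) / self.interval


@dataclass(frozen=True)
class CombinationSchedule:
    """A cytotoxic and an apoptotic schedule initiated simultaneously."""

    cytotoxic: DoseSchedule
    apoptotic: DoseSchedule
    start_step: int = 0

    def __post_init__(self) -> None:
        if self.cytotoxic.drug_kind != CYTOTOXIC:
            raise ScheduleError("cytotoxic slot must hold a cytotoxic schedule")
        if self.apoptotic.drug_kind != APOPTOTIC:
            raise ScheduleError("apoptotic slot must hold an apoptotic schedule")
        if self.start_step < 0:
            raise ScheduleError("start_step must be >= 0")


Schedule = Union[DoseSchedule, CombinationSchedule]


def is_dose_active(schedule: DoseSchedule, step: int, therapy_start: int = 0) -> bool:
    """Whether the dose is being administered at the given step.

    The interval runs from the beginning of one dose to the beginning of the
    next, so the dose is active on steps ``t`` with
    ``(t - therapy_start) mod interval < duration`` once therapy has begun.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    if step < therapy_start:
        return False
    return (step - therapy_start) % schedule.interval < schedule.duration


def steps_to_days(steps: float) -> float:
    """Convert simulation steps to days (1 step = 4 hours), rounded to 2 dp.

    Rounding is decimal half-up so that printed values like 71.01 steps map
    to 11.84 days exactly.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    days = Decimal(str(steps)) * HOURS_PER_STEP / 24
    return float(days.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def accumulated_dose(
    lethality: float, time_to_cure_steps: float, interval: int
) -> float:
    """Accumulated cytotoxic exposure: ``lethality x (time to cure / interval)``.

    A surrogate for cumulative dose and side-effect burden.  When replicates
    are aggregated, compute this per replicate and then average.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if time_to_cure_steps < 0:
        raise ValueError("time_to_cure_steps must be >= 0")
    return lethality * time_to_cure_steps / interval


@dataclass(frozen=True)
class PracticalityPolicy:
    """Which schedules can actually be administered in an infusion clinic.

    The default allows infusions of at most 2 steps (8 hours, one clinic
    day) and intervals that are whole-week multiples (42 steps = 7 days), so
    dosing stays in sync with the 7-day week.
    """

    max_duration_steps: int = 2
    allowed_intervals: FrozenSet[int] = frozenset({42, 84})

    def __post_init__(self) -> None:
        if self.max_duration_steps < 1:
            raise ScheduleError("max_duration_steps must be >= 1")
        if not self.allowed_intervals:
            raise ScheduleError("allowed_intervals must be non-empty")
        if any(i % 2 != 0 for i in self.allowed_intervals):
            raise ScheduleError("allowed intervals must be even step counts")


def is_practical(schedule: Schedule, policy: PracticalityPolicy | None = None) -> bool:
    """Whether every drug in the schedule fits the clinic policy."""
    policy = policy or PracticalityPolicy()
    if isinstance(schedule, CombinationSchedule):
        parts = (schedule.cytotoxic, schedule.apoptotic)
    else:
        parts = (schedule,)
    return all(
        p.duration <= policy.max_duration_steps
        and p.interval in policy.allowed_intervals
        for p in parts
    )
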