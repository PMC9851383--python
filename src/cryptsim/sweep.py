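"""Dose-schedule grid enumeration, execution and multi-objective filtering.

The single-drug sweep space is the Cartesian product of duration (1..48
steps), interval (even, 2..96 steps) and intensity (0.25..20.00 in 0.25
steps): 48 x 48 x 80 = 184,320 schedules.  Schedules with interval <=
duration are enumerable but filtered at execution time.  A combination
sweep crosses two such grids (~3.4e10 schedules), which is why exhaustive
simulation is intractable and the active-learning surrogate exists.

Curative filtering keeps schedules that cured 100% of replicates with no
toxicity; optimal selection applies the clinical-practicality policy and
ranks lexicographically by (crypt size preserved, accumulated dose,
time to cure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .crypt import CryptGeometry, GradientParams
from .treatment import (
    APOPTOTIC,
    CYTOTOXIC,
    CombinationSchedule,
    DoseSchedule,
    PracticalityPolicy,
    Schedule,
    is_practical,
)
from .trials import (
    ReplicateSummary,
    TrialProtocol,
    classify_toxic,
    run_replicates,
    summarize_replicates,
)

__all__ = [
    "GridSpec",
    "SweepResult",
    "enumerate_grid",
    "enumerate_combination_grid",
    "run_sweep",
    "filter_curative",
    "select_optimal",
    "filter_central",
]

logger = logging.getLogger(__name__)


def _frange(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + k * step, 10) for k in range(n))


@dataclass(frozen=True)
class GridSpec:
    """Enumerable ranges of (duration, interval, intensity) for one drug."""

    drug_kind: str = CYTOTOXIC
    durations: tuple[int, ...] = tuple(range(1, 49))
    intervals: tuple[int, ...] = tuple(range(2, 97, 2))
    intensities: tuple[float, ...] = field(
        default_factory=lambda: _frange(0.25, 20.0, 0.25)
    )
    enforce_interval_gt_duration: bool = False

    def __post_init__(self) -> None:
        if not self.durations or not self.intervals or not self.intensities:
            raise ValueError("grid ranges must be non-empty")
        steps = np.diff(np.asarray(self.intensities, dtype=float))
        if steps.size and not np.allclose(steps, steps[0]):
            raise ValueError("intensity grid must be uniform")

    @property
    def size(self) -> int:
        """Closed-form grid size before the interval > duration filter."""
        return len(self.durations) * len(self.intervals) * len(self.intensities)

    @classmethod
    def default_cytotoxic(cls) -> "GridSpec":
        return cls(drug_kind=CYTOTOXIC)

    @classmethod
    def default_apoptotic(cls) -> "GridSpec":
        return cls(drug_kind=APOPTOTIC)


def enumerate_grid(spec: GridSpec) -> list[DoseSchedule]:
    """Materialize the grid in lexicographic (duration, interval, intensity)
    order.

    The interval > duration constraint is applied here only when the grid
    requests it; by default it is an execution-time filter so that the full
    product (e.g. the 184,320 default single-drug schedules) is enumerable.
    """
    out = []
    for d in spec.durations:
        for i in spec.intervals:
            if spec.enforce_interval_gt_duration and i <= d:
                continue
            for x in spec.intensities:
                out.append(
                    DoseSchedule(
                        drug_kind=spec.drug_kind, duration=d, interval=i, intensity=x
                    )
                )
    return out


def enumerate_combination_grid(
    cyto: GridSpec,
    apo: GridSpec,
    *,
    sample: int | None = None,
    seed: int | None = None,
) -> Iterator[CombinationSchedule]:
    """Lazily stream the product of two grids, or a uniform random sample.

    With ``sample`` given, yields exactly that many distinct combinations
    drawn uniformly (seeded) from the full product space — the seed set of
    the active-learning loop.  The full product is never materialized.
    """
    cyto_list = enumerate_grid(cyto)
    apo_list = enumerate_grid(apo)
    n_total = len(cyto_list) * len(apo_list)
    if sample is None:
        for c in cyto_list:
            for a in apo_list:
                yield CombinationSchedule(cytotoxic=c, apoptotic=a)
        return
    if sample > n_total:
        raise ValueError(
            f"cannot sample {sample} distinct combinations from a space of {n_total}"
        )
    rng = np.random.default_rng(seed)
    if n_total <= 10 * sample:
        flat = rng.choice(n_total, size=sample, replace=False)
    else:
        # rejection sampling keeps memory bounded on huge spaces
        chosen: set[int] = set()
        while len(chosen) < sample:
            draw = rng.integers(0, n_total, size=sample - len(chosen))
            chosen.update(int(v) for v in draw)
        flat = np.fromiter(chosen, dtype=np.int64, count=sample)
        rng.shuffle(flat)
    n_apo = len(apo_list)
    for idx in flat:
        yield CombinationSchedule(
            cytotoxic=cyto_list[int(idx) // n_apo],
            apoptotic=apo_list[int(idx) % n_apo],
        )


@dataclass(frozen=True)
class SweepResult:
    """One schedule's replicate summary plus its filter classifications."""

    schedule: Schedule
    summary: ReplicateSummary
    toxic: bool
    practical: bool


def _executable(schedule: Schedule) -> bool:
    if isinstance(schedule, CombinationSchedule):
        return schedule.cytotoxic.executable and schedule.apoptotic.executable
    return schedule.executable


def run_sweep(
    schedules: Iterable[Schedule],
    protocol: TrialProtocol,
    geometry: CryptGeometry | None = None,
    gradients: GradientParams | None = None,
    *,
    master_seed: int = 0,
    untreated_mean_size: float,
    policy: PracticalityPolicy | None = None,
    progress: Callable[[int, Schedule], None] | None = None,
) -> list[SweepResult]:
    """Execute replicate trials for every executable schedule.

    Schedules with interval <= duration are skipped (logged).  The same
    master seed is used for every schedule, so replicate pre-therapy
    trajectories are shared across schedules (common random numbers) and
    cross-schedule comparisons are paired.
    """
    geometry = geometry or CryptGeometry()
    policy = policy or PracticalityPolicy()
    results = []
    for k, sched in enumerate(schedules):
        if not _executable(sched):
            logger.debug("skipping non-executable schedule %s", sched)
            continue
        if progress is not None:
            progress(k, sched)
        outcomes = run_replicates(
            sched, protocol, geometry, gradients, master_seed=master_seed
        )
        try:
            summary = summarize_replicates(outcomes, untreated_mean_size)
        except ValueError:
            logger.warning(
                "schedule %s: no evaluable replicates (mutant clone never "
                "reached the therapy trigger); skipping",
                sched,
            )
            continue
        toxic = any(
            classify_toxic(o, geometry.min_viable_cells)
            for o in outcomes
            if o.evaluable
        )
        results.append(
            SweepResult(
                schedule=sched,
                summary=summary,
                toxic=toxic,
                practical=is_practical(sched, policy),
            )
        )
    return results


def filter_curative(results: Sequence[SweepResult]) -> list[SweepResult]:
    """Keep schedules that cured every replicate while retaining crypt
    function (no toxicity, no extinguished replicate).  Idempotent and
    order-preserving."""
    return [
        r
        for r in results
        if r.summary.percent_cure == 100.0
        and not r.toxic
        and not r.summary.any_extinguished
    ]


def select_optimal(
    curative: Sequence[SweepResult],
    policy: PracticalityPolicy | None = None,
) -> list[SweepResult]:
    """Rank clinically practical curative schedules.

    Lexicographic: highest crypt size (least perturbation), then lowest
    mean accumulated cytotoxic dose, then lowest mean time to cure.  An
    empty result (everything impractical) is returned with a diagnostic
    log message rather than an error.
    """
    policy = policy or PracticalityPolicy()
    practical = [r for r in curative if is_practical(r.schedule, policy)]
    if not practical:
        logger.warning(
            "no curative schedule passed the practicality policy (%d candidates)",
            len(curative),
        )
        return []

    def key(r: SweepResult):
        s = r.summary
        return (
            -s.crypt_size_percent_untreated,
            s.mean_accumulated_dose if s.mean_accumulated_dose is not None else 0.0,
            s.mean_time_to_cure_steps
            if s.mean_time_to_cure_steps is not None
            else float("inf"),
        )

    return sorted(practical, key=key)


def _schedule_coords(schedule: Schedule) -> tuple:
    if isinstance(schedule, CombinationSchedule):
        return _schedule_coords(schedule.cytotoxic) + _schedule_coords(
            schedule.apoptotic
        )
    return (schedule.duration, schedule.interval, round(schedule.intensity, 10))


def filter_central(
    curative: Sequence[SweepResult],
    all_results: Sequence[SweepResult],
    *,
    duration_step: int = 1,
    interval_step: int = 2,
    intensity_step: float = 0.25,
) -> list[SweepResult]:
    """Optional robustness post-filter: drop curative schedules that sit
    within one grid step of a toxic (or non-curative) explored neighbour.

    Schedules at the curative/toxic boundary are the ones most sensitive to
    adding stochastic replicates; centrally located schedules are robust.
    """
    curative_coords = {_schedule_coords(r.schedule) for r in curative}
    steps = (duration_step, interval_step, intensity_step)

    def neighbours(coords: tuple) -> Iterator[tuple]:
        for axis in range(len(coords)):
            step = steps[axis % 3]
            for sign in (-1, 1):
                out = list(coords)
                out[axis] = round(out[axis] + sign * step, 10)
                yield tuple(out)

    explored = {_schedule_coords(r.schedule) for r in all_results}
    kept = []
    for r in curative:
        coords = _schedule_coords(r.schedule)
        boundary = any(
            n in explored and n not in curative_coords for n in neighbours(coords)
        )
        if not boundary:
            kept.append(r)
    return kept
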