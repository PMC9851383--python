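"""Simulated clinical trials on single crypts.

Protocol: initialize a healthy crypt, let it reach homeostasis, mutate
proliferating cells to a cancer phenotype at a fixed step, let the mutant
clone grow untreated until it reaches a trigger fraction of the crypt, then
start therapy (both drugs simultaneously for combinations) and run until
cure (no cancer-lineage cells left), crypt extinguishment, or a step cap.
Each dose schedule is evaluated over independent seeded stochastic
replicates and the replicate outcomes are aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .crypt import (
    CryptGeometry,
    GradientParams,
    census,
    init_crypt,
    introduce_mutants,
    step_crypt,
)
from .treatment import (
    APOPTOTIC,
    CYTOTOXIC,
    CombinationSchedule,
    DoseSchedule,
    Schedule,
    ScheduleError,
    accumulated_dose,
    is_dose_active,
    steps_to_days,
)

__all__ = [
    "TrialProtocol",
    "TrialOutcome",
    "ReplicateSummary",
    "run_trial",
    "run_replicates",
    "replicate_seeds",
    "summarize_replicates",
    "classify_toxic",
    "estimate_untreated_mean_size",
]


@dataclass(frozen=True)
class TrialProtocol:
    """Timing and replication rules of the simulated clinical trial."""

    mutation_step: int = 200
    therapy_trigger_fraction: float = 0.5
    n_replicates: int = 50
    max_steps: int = 2000
    phenotype_label: str = "cancer"
    n_mutants: int = 1
    mutant_position: str = "lower_third"

    def __post_init__(self) -> None:
        if not 0.0 < self.therapy_trigger_fraction <= 1.0:
            raise ValueError("therapy_trigger_fraction must be in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.max_steps <= self.mutation_step:
            raise ValueError("max_steps must exceed mutation_step")
        if self.mutation_step < 0:
            raise ValueError("mutation_step must be >= 0")
        if self.n_mutants < 1:
            raise ValueError("n_mutants must be >= 1")

    @classmethod
    def desk(cls, phenotype_label: str = "cancer") -> "TrialProtocol":
        """Desk-scale protocol used with the reduced crypt geometry.

        20 replicates, and 16 proliferating cells at the crypt bottom are
        converted at the mutation step: single-cell seeding almost always
        drifts out before the 50% therapy trigger is reached in a small
        crypt, so a clonal patch is seeded instead.
        """
        return cls(
            n_replicates=20,
            phenotype_label=phenotype_label,
            n_mutants=16,
            mutant_position="bottom",
        )


@dataclass(frozen=True)
class TrialOutcome:
    """Result of one replicate.

    ``evaluable`` is False when the mutant clone never reached the therapy
    trigger (lost to drift or ran out of time), in which case the therapy
    fields are meaningless.  ``cured`` and ``extinguished`` are mutually
    exclusive; ``time_to_cure_steps`` is present iff cured.
    """

    cured: bool
    extinguished: bool
    evaluable: bool
    time_to_cure_steps: float | None
    mean_treated_crypt_size: float
    min_treated_crypt_size: float
    accumulated_dose: float
    apoptotic_used: bool
    therapy_start_step: int | None
    seed: int

    def __post_init__(self) -> None:
        if self.cured and self.extinguished:
            raise ValueError("cured and extinguished are mutually exclusive")
        if self.cured != (self.time_to_cure_steps is not None):
            raise ValueError("time_to_cure_steps present iff cured")


@dataclass(frozen=True)
class ReplicateSummary:
    """Aggregate over the replicates of one dose schedule."""

    n_replicates: int
    n_evaluable: int
    percent_cure: float
    mean_time_to_cure_steps: float | None
    mean_time_to_cure_days: float | None
    crypt_size_percent_untreated: float
    mean_accumulated_dose: float | None
    any_extinguished: bool
    min_crypt_size: float


def _split_schedule(
    schedule: Schedule,
) -> tuple[DoseSchedule | None, DoseSchedule | None]:
    if isinstance(schedule, CombinationSchedule):
        return schedule.cytotoxic, schedule.apoptotic
    if schedule.drug_kind == CYTOTOXIC:
        return schedule, None
    return None, schedule


def run_trial(
    schedule: Schedule | None,
    protocol: TrialProtocol,
    geometry: CryptGeometry | None = None,
    gradients: GradientParams | None = None,
    seed: int = 0,
) -> TrialOutcome:
    """Run one simulated clinical trial replicate; deterministic per seed.

    ``schedule`` may be a single-drug schedule, a combination, or None for
    an untreated control arm (therapy phase runs with inactive drugs).
    """
    geometry = geometry or CryptGeometry()
    gradients = gradients or GradientParams()
    cyto, apo = _split_schedule(schedule) if schedule is not None else (None, None)
    for part in (cyto, apo):
        if part is not None and not part.executable:
            raise ScheduleError(
                f"schedule {part} has interval <= duration and cannot be executed"
            )

    state = init_crypt(geometry, gradients, seed)
    while state.step_index < protocol.mutation_step:
        step_crypt(state)
    introduce_mutants(
        state,
        protocol.phenotype_label,
        n_cells=protocol.n_mutants,
        position=protocol.mutant_position,
    )

    def _not_evaluable() -> TrialOutcome:
        return TrialOutcome(
            cured=False,
            extinguished=False,
            evaluable=False,
            time_to_cure_steps=None,
            mean_treated_crypt_size=float("nan"),
            min_treated_crypt_size=float("nan"),
            accumulated_dose=0.0,
            apoptotic_used=apo is not None,
            therapy_start_step=None,
            seed=seed,
        )

    # free-growth phase until the mutant clone reaches the trigger fraction
    while state.cancer_fraction() < protocol.therapy_trigger_fraction:
        if state.cancer_cells() == 0 or state.step_index >= protocol.max_steps:
            return _not_evaluable()
        step_crypt(state)

    therapy_start = state.step_index
    sizes: list[int] = []
    cured = False
    extinguished = False
    time_to_cure: float | None = None

    while state.step_index < protocol.max_steps:
        t = state.step_index
        lethality = (
            cyto.intensity
            if cyto is not None and is_dose_active(cyto, t, therapy_start)
            else 1.0
        )
        apoptotic = (
            apo.intensity
            if apo is not None and is_dose_active(apo, t, therapy_start)
            else 1.0
        )
        step_crypt(state, lethality, apoptotic)
        total = state.total_cells()
        sizes.append(total)
        if total == 0:
            extinguished = True
            break
        if state.cancer_cells() == 0:
            cured = True
            time_to_cure = float(state.step_index - therapy_start)
            break

    treated_steps = time_to_cure if cured else float(state.step_index - therapy_start)
    acc = (
        accumulated_dose(cyto.intensity, treated_steps, cyto.interval)
        if cyto is not None
        else 0.0
    )
    return TrialOutcome(
        cured=cured,
        extinguished=extinguished,
        evaluable=True,
        time_to_cure_steps=time_to_cure,
        mean_treated_crypt_size=float(np.mean(sizes)) if sizes else float("nan"),
        min_treated_crypt_size=float(min(sizes)) if sizes else float("nan"),
        accumulated_dose=acc,
        apoptotic_used=apo is not None,
        therapy_start_step=therapy_start,
        seed=seed,
    )


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n independent replicate seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] & 0x7FFFFFFF) for child in ss.spawn(n)]


def run_replicates(
    schedule: Schedule | None,
    protocol: TrialProtocol,
    geometry: CryptGeometry | None = None,
    gradients: GradientParams | None = None,
    master_seed: int = 0,
) -> list[TrialOutcome]:
    """Run the protocol's stochastic replicates with independent seeds."""
    seeds = replicate_seeds(master_seed, protocol.n_replicates)
    return [
        run_trial(schedule, protocol, geometry, gradients, seed=s) for s in seeds
    ]


def summarize_replicates(
    outcomes: Sequence[TrialOutcome], untreated_mean_size: float
) -> ReplicateSummary:
    """Aggregate replicate outcomes the way trial tables report them.

    Percent cure is computed over evaluable replicates; mean time to cure and
    mean accumulated dose are averaged over cured replicates (dose per
    replicate first, then averaged); crypt size is the treated-phase mean
    expressed as a percentage of the untreated mean crypt size.
    """
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    evaluable = [o for o in outcomes if o.evaluable]
    if not evaluable:
        raise ValueError("no evaluable replicates (trigger never reached)")
    cured = [o for o in evaluable if o.cured]
    percent_cure = 100.0 * len(cured) / len(evaluable)
    if cured:
        mean_t = float(np.mean([o.time_to_cure_steps for o in cured]))
        mean_days = steps_to_days(mean_t)
        mean_dose = float(np.mean([o.accumulated_dose for o in cured]))
    else:
        mean_t = mean_days = mean_dose = None
    sizes = [o.mean_treated_crypt_size for o in evaluable]
    return ReplicateSummary(
        n_replicates=len(outcomes),
        n_evaluable=len(evaluable),
        percent_cure=percent_cure,
        mean_time_to_cure_steps=mean_t,
        mean_time_to_cure_days=mean_days,
        crypt_size_percent_untreated=100.0 * float(np.mean(sizes))
        / untreated_mean_size,
        mean_accumulated_dose=mean_dose,
        any_extinguished=any(o.extinguished for o in evaluable),
        min_crypt_size=float(np.min([o.min_treated_crypt_size for o in evaluable])),
    )


def classify_toxic(outcome: TrialOutcome, min_viable_cells: int = 1399) -> bool:
    """Host-toxicity rule for one replicate.

    Toxic iff the crypt was extinguished, or apoptotic dosing drove the
    crypt below the minimum viable size observed in biopsies.
    """
    if outcome.extinguished:
        return True
    if outcome.apoptotic_used and outcome.evaluable:
        return outcome.min_treated_crypt_size < min_viable_cells
    return False


def estimate_untreated_mean_size(
    geometry: CryptGeometry | None = None,
    gradients: GradientParams | None = None,
    *,
    steps: int = 500,
    burn_in: int = 200,
    seed: int = 0,
) -> float:
    """Mean total cell count of an untreated crypt after burn-in."""
    geometry = geometry or CryptGeometry()
    gradients = gradients or GradientParams()
    state = init_crypt(geometry, gradients, seed)
    totals = []
    for t in range(steps):
        step_crypt(state)
        if t >= burn_in:
            totals.append(state.total_cells())
    return float(np.mean(totals))
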