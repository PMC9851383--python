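"""Configuration, schedule tables, results files, manifests and reports.

Schedule tables are CSV/TSV with columns ``cyto_duration, cyto_interval,
cyto_lethality, apo_duration, apo_interval, apo_intensity`` (either drug's
triple may be absent for single-drug tables).  Results files are tidy CSV,
one row per schedule, that round-trip losslessly through the readers here.
All files are UTF-8 with "." decimals, independent of locale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .crypt import (
    CryptGeometry,
    GradientParams,
    census,
    init_crypt,
    introduce_mutants,
    step_crypt,
)
from .treatment import (
    CombinationSchedule,
    DoseSchedule,
    PracticalityPolicy,
    Schedule,
    ScheduleError,
    is_dose_active,
)
from .trials import TrialProtocol
from .sweep import SweepResult, filter_curative, select_optimal

__all__ = [
    "RunConfig",
    "read_schedule_table",
    "write_results",
    "write_manifest",
    "funnel_counts",
    "run_timeline",
    "report",
]

logger = logging.getLogger(__name__)

_CYTO_COLS = ["cyto_duration", "cyto_interval", "cyto_lethality"]
_APO_COLS = ["apo_duration", "apo_interval", "apo_intensity"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit.

    The master seed deterministically derives every stream seed used by
    the run; the config hash plus the master seed is the run's identity.
    """

    geometry: CryptGeometry = field(default_factory=CryptGeometry)
    gradients: GradientParams = field(default_factory=GradientParams)
    protocol: TrialProtocol = field(default_factory=TrialProtocol)
    policy: PracticalityPolicy = field(default_factory=PracticalityPolicy)
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, klass in (
            ("geometry", CryptGeometry),
            ("gradients", GradientParams),
            ("protocol", TrialProtocol),
        ):
            if key in raw:
                kwargs[key] = klass(**raw[key])
        if "policy" in raw:
            pol = dict(raw["policy"])
            if "allowed_intervals" in pol:
                pol["allowed_intervals"] = frozenset(pol["allowed_intervals"])
            kwargs["policy"] = PracticalityPolicy(**pol)
        if "master_seed" in raw:
            kwargs["master_seed"] = int(raw["master_seed"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["policy"]["allowed_intervals"] = sorted(
            self.policy.allowed_intervals
        )
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _schedule_from_row(row: pd.Series, row_number: int) -> Schedule:
    has_cyto = all(c in row.index and pd.notna(row[c]) for c in _CYTO_COLS)
    has_apo = all(c in row.index and pd.notna(row[c]) for c in _APO_COLS)
    if not has_cyto and not has_apo:
        raise ScheduleError(f"row {row_number}: no complete drug triple")
    try:
        cyto = (
            DoseSchedule(
                "cytotoxic",
                int(row["cyto_duration"]),
                int(row["cyto_interval"]),
                float(row["cyto_lethality"]),
            )
            if has_cyto
            else None
        )
        apo = (
            DoseSchedule(
                "apoptotic",
                int(row["apo_duration"]),
                int(row["apo_interval"]),
                float(row["apo_intensity"]),
            )
            if has_apo
            else None
        )
        for part in (cyto, apo):
            if part is not None and not part.executable:
                raise ScheduleError("interval must be greater than duration")
    except (ScheduleError, ValueError) as exc:
        raise ScheduleError(f"row {row_number}: {exc}") from exc
    if cyto is not None and apo is not None:
        return CombinationSchedule(cytotoxic=cyto, apoptotic=apo)
    return cyto if cyto is not None else apo


def read_schedule_table(path: str | Path) -> list[Schedule]:
    """Parse a schedule table (CSV, or TSV by sniffing); order preserved.

    Unknown columns produce a warning; a malformed row raises a
    :class:`ScheduleError` naming the 1-based data row.
    """
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        warnings.warn(f"{path} is empty or undelimited; no schedules read")
        return []
    known = set(_CYTO_COLS) | set(_APO_COLS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}")
    if df.empty:
        warnings.warn(f"{path} has a header but no rows")
        return []
    return [
        _schedule_from_row(row, i + 1) for i, (_, row) in enumerate(df.iterrows())
    ]


def _schedule_to_row(schedule: Schedule) -> dict:
    row: dict = {c: np.nan for c in _CYTO_COLS + _APO_COLS}
    parts = (
        (schedule.cytotoxic, schedule.apoptotic)
        if isinstance(schedule, CombinationSchedule)
        else (schedule,)
    )
    for p in parts:
        if p.drug_kind == "cytotoxic":
            row.update(
                cyto_duration=p.duration,
                cyto_interval=p.interval,
                cyto_lethality=p.intensity,
            )
        else:
            row.update(
                apo_duration=p.duration,
                apo_interval=p.interval,
                apo_intensity=p.intensity,
            )
    return row


_SUMMARY_COLS = [
    "n_replicates",
    "n_evaluable",
    "percent_cure",
    "mean_time_to_cure_steps",
    "mean_time_to_cure_days",
    "crypt_size_percent_untreated",
    "mean_accumulated_dose",
    "any_extinguished",
    "min_crypt_size",
]


def write_results(
    results: Sequence[SweepResult], path: str | Path, *, sep: str = ","
) -> Path:
    """Write sweep results as tidy CSV (schedule columns + summary columns);
    stable column order; an empty result list produces a header-only file."""
    rows = []
    for r in results:
        row = _schedule_to_row(r.schedule)
        for col in _SUMMARY_COLS:
            row[col] = getattr(r.summary, col)
        row["toxic"] = r.toxic
        row["practical"] = r.practical
        rows.append(row)
    columns = _CYTO_COLS + _APO_COLS + _SUMMARY_COLS + ["toxic", "practical"]
    df = pd.DataFrame(rows, columns=columns)
    path = Path(path)
    df.to_csv(path, index=False, sep=sep)
    return path


def write_manifest(
    config: RunConfig, path: str | Path, *, extra: dict | None = None
) -> Path:
    """JSON run manifest: config, its hash, and the master seed."""
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def funnel_counts(
    results: Sequence[SweepResult],
    *,
    n_enumerated: int | None = None,
    n_predicted_nontoxic: int | None = None,
    policy: PracticalityPolicy | None = None,
) -> dict[str, int]:
    """Counts at each stage of the schedule-selection funnel.

    enumerated -> predicted nontoxic -> executed -> curative -> practical
    -> optimal.  Stages upstream of execution may be supplied by the
    caller (grid size, surrogate output); counts are non-increasing.
    """
    executed = len(results)
    curative = filter_curative(results)
    ranked = select_optimal(curative, policy) if curative else []
    counts = {
        "enumerated": n_enumerated if n_enumerated is not None else executed,
        "predicted_nontoxic": n_predicted_nontoxic
        if n_predicted_nontoxic is not None
        else executed,
        "executed": executed,
        "curative": len(curative),
        "practical": len(ranked),
        "optimal": 1 if ranked else 0,
    }
    return counts


def run_timeline(
    schedule: Schedule | None,
    protocol: TrialProtocol,
    geometry: CryptGeometry | None = None,
    gradients: GradientParams | None = None,
    seed: int = 0,
    *,
    max_steps: int | None = None,
) -> pd.DataFrame:
    """Per-step timeline of one replicate: total cells, cancer cells and
    dose-active flags, from initialization through therapy.

    This is the trial runner re-executed with full state recording; use it
    to visualise how a schedule drives cancer cells to zero while the crypt
    recovers between doses.
    """
    from .trials import _split_schedule  # shared semantics with run_trial

    geometry = geometry or CryptGeometry()
    gradients = gradients or GradientParams()
    cap = max_steps or protocol.max_steps
    cyto, apo = _split_schedule(schedule) if schedule is not None else (None, None)

    state = init_crypt(geometry, gradients, seed)
    records = []
    therapy_start: int | None = None

    def record(lethality_active: bool, apoptotic_active: bool) -> None:
        c = census(state)
        records.append(
            {
                "step": state.step_index,
                "total_cells": c.total,
                "cancer_cells": c.phenotype_total("cancer")
                + c.phenotype_total("resistant"),
                "cancer_fraction": c.cancer_fraction,
                "cyto_active": lethality_active,
                "apo_active": apoptotic_active,
                "phase": "therapy" if therapy_start is not None else "growth",
            }
        )

    record(False, False)
    while state.step_index < cap:
        if state.step_index == protocol.mutation_step:
            introduce_mutants(
                state,
                protocol.phenotype_label,
                n_cells=protocol.n_mutants,
                position=protocol.mutant_position,
            )
        if (
            therapy_start is None
            and state.step_index > protocol.mutation_step
            and state.cancer_fraction() >= protocol.therapy_trigger_fraction
        ):
            therapy_start = state.step_index
        t = state.step_index
        cyto_on = (
            therapy_start is not None
            and cyto is not None
            and is_dose_active(cyto, t, therapy_start)
        )
        apo_on = (
            therapy_start is not None
            and apo is not None
            and is_dose_active(apo, t, therapy_start)
        )
        step_crypt(
            state,
            cyto.intensity if cyto_on else 1.0,
            apo.intensity if apo_on else 1.0,
        )
        record(cyto_on, apo_on)
        if state.total_cells() == 0:
            break
        if therapy_start is not None and state.cancer_cells() == 0:
            break
    return pd.DataFrame.from_records(records)


def report(
    results: Sequence[SweepResult],
    untreated_mean_size: float,
    *,
    timeline: pd.DataFrame | None = None,
    policy: PracticalityPolicy | None = None,
    n_enumerated: int | None = None,
    n_predicted_nontoxic: int | None = None,
) -> str:
    """Human-readable summary: the selection funnel, the ranked practical
    schedules, and (optionally) a timeline digest for one chosen schedule."""
    counts = funnel_counts(
        results,
        n_enumerated=n_enumerated,
        n_predicted_nontoxic=n_predicted_nontoxic,
        policy=policy,
    )
    lines = ["Schedule selection funnel:"]
    for stage, n in counts.items():
        lines.append(f"  {stage:>20s}: {n}")
    ranked = select_optimal(filter_curative(results), policy)
    if ranked:
        lines.append("")
        lines.append("Ranked practical curative schedules:")
        for rank, r in enumerate(ranked, 1):
            s = r.summary
            lines.append(
                f"  #{rank} {_schedule_to_row(r.schedule)} "
                f"cure={s.percent_cure:.0f}% "
                f"time={s.mean_time_to_cure_steps} steps "
                f"size={s.crypt_size_percent_untreated:.1f}% "
                f"dose={s.mean_accumulated_dose}"
            )
    if timeline is not None and not timeline.empty:
        therapy = timeline[timeline["phase"] == "therapy"]
        lines.append("")
        lines.append("Timeline digest (therapy phase):")
        if therapy.empty:
            lines.append("  therapy never triggered")
        else:
            lines.append(f"  therapy start step: {int(therapy['step'].iloc[0])}")
            lines.append(
                f"  final cancer cells: {int(timeline['cancer_cells'].iloc[-1])}"
            )
            lines.append(
                f"  min total cells: {int(therapy['total_cells'].min())} "
                f"({100 * therapy['total_cells'].min() / untreated_mean_size:.1f}% "
                "of untreated)"
            )
    return "\n".join(lines)
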