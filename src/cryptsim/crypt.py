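"""Agent-based model of cell dynamics in a human colon crypt.

The crypt is a cylindrical lattice of cells (``circumference`` columns x
``height`` rows).  Row 0 is the crypt bottom; the top row faces the lumen.
Three compartments are defined by normalized height ``h`` in [0, 1]:

* **quiescent stem niche** (``h < niche_fraction``): cells neither divide nor
  die while the crypt is at homeostatic size; they "awake" and divide when
  the total cell count drops below a release fraction of the homeostatic
  target, and slowly replace each other by neutral drift.
* **proliferating zone** (middle): division probability decreases linearly
  with height, death probability increases linearly with height.
* **differentiated zone** (top ``differentiated_fraction``): cells no longer
  divide; they die and are shed at the lumen.

One timestep corresponds to roughly 4 hours of human time.  Each tick
applies, in order: niche neutral replacement, death draws, division draws
(daughters are inserted just above or below the parent in the same or an
adjacent column), downward compaction of each column, and removal of cells
pushed past the top row.  Division flux exceeds death flux, so the crypt
runs as a "full conveyor": the lattice stays pinned near capacity and
surplus cells are shed at the lumen.

Phenotypes multiply the positional probabilities: drug-sensitive cancer
cells divide 1.16x and die 1.10x as fast as normal cells at the same
position; relatively drug-resistant cancer cells divide 1.08x and die
1.05x as fast.  Mutant cells respond poorly to the upward migration cue
(their daughters are biased toward the crypt bottom), which is what lets a
clone anchor and fill the crypt as an adenoma, but they cannot displace
the stem niche itself.

Drug effects are multiplicative factors on the positional death
probability.  The cytotoxic *lethality* factor applies to dividing cells
(the proliferating zone, plus the niche while awake), weighted by each
phenotype's division propensity because the drug kills cells in S phase;
resistant cells spend part of their time in a slow-cycling,
drug-invulnerable state and so experience only a fraction of the nominal
exposure.  The apoptotic *intensity* factor applies to the differentiated
top zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "EMPTY",
    "NORMAL",
    "CANCER",
    "RESISTANT",
    "PHENOTYPES",
    "CellPhenotype",
    "Cell",
    "CryptGeometry",
    "GradientParams",
    "CryptState",
    "CryptConfigError",
    "StepStats",
    "CryptCensus",
    "init_crypt",
    "divide_probability",
    "die_probability",
    "step_crypt",
    "introduce_mutants",
    "census",
    "calibrate_gradients",
    "CalibrationResult",
    "estimate_division_ratio",
]

# phenotype codes stored in the lattice
EMPTY, NORMAL, CANCER, RESISTANT = 0, 1, 2, 3

_DIVIDE_MULT = np.array([0.0, 1.0, 1.16, 1.08])
_DIE_MULT = np.array([0.0, 1.0, 1.10, 1.05])

QUIESCENT_STEM = "quiescent_stem"
PROLIFERATING = "proliferating"
DIFFERENTIATED = "differentiated"


class CryptConfigError(ValueError):
    """Raised for invalid crypt geometry or model configuration."""


@dataclass(frozen=True)
class CellPhenotype:
    """Multipliers a phenotype applies to the positional divide/die rates."""

    label: str
    divide_multiplier: float
    die_multiplier: float

    def __post_init__(self) -> None:
        if self.divide_multiplier <= 0 or self.die_multiplier <= 0:
            raise CryptConfigError("phenotype multipliers must be positive")


#: Registry of the three phenotypes used throughout the model.
PHENOTYPES: Mapping[str, CellPhenotype] = {
    "normal": CellPhenotype("normal", 1.0, 1.0),
    "cancer": CellPhenotype("cancer", 1.16, 1.10),
    "resistant": CellPhenotype("resistant", 1.08, 1.05),
}

_LABEL_TO_CODE = {"normal": NORMAL, "cancer": CANCER, "resistant": RESISTANT}
_CODE_TO_LABEL = {v: k for k, v in _LABEL_TO_CODE.items()}


@dataclass(frozen=True)
class CryptGeometry:
    """Lattice dimensions and reference cell counts for one crypt.

    Parameters
    ----------
    circumference : int
        Cells per ring (columns of the cylindrical lattice).
    height : int
        Rings from crypt bottom to lumen (rows).
    homeostatic_target : int
        Mean total cell count of an untreated crypt.
    min_viable_cells : int
        Reference floor used for toxicity classification; a crypt driven
        below this size by apoptotic dosing is considered damaged (1,399
        cells is the lowest count measured in human biopsy specimens).
    """

    circumference: int = 25
    height: int = 72
    homeostatic_target: int = 1750
    min_viable_cells: int = 1399

    def __post_init__(self) -> None:
        if self.circumference < 1:
            raise CryptConfigError("circumference must be >= 1")
        if self.height < 3:
            raise CryptConfigError(
                "height must be >= 3 so that niche, proliferative and "
                "differentiated zones are all representable"
            )
        if self.homeostatic_target < 1:
            raise CryptConfigError("homeostatic_target must be positive")
        if self.min_viable_cells > self.homeostatic_target:
            raise CryptConfigError("min_viable_cells must be <= homeostatic_target")
        if self.capacity < self.homeostatic_target:
            raise CryptConfigError(
                f"lattice capacity {self.capacity} is below the homeostatic "
                f"target {self.homeostatic_target}"
            )

    @property
    def capacity(self) -> int:
        return self.circumference * self.height

    @classmethod
    def reduced(cls) -> "CryptGeometry":
        """Small desk-scale geometry with the same zone proportions.

        The viability floor keeps the full model's ~80%-of-target ratio.
        """
        return cls(
            circumference=20,
            height=30,
            homeostatic_target=585,
            min_viable_cells=468,
        )


@dataclass(frozen=True)
class GradientParams:
    """Positional divide/die gradients and niche behaviour.

    The divide gradient falls linearly from ``divide_max`` at the crypt
    bottom to ``divide_min`` at the top; the die gradient rises linearly
    from ``die_min`` at the bottom to ``die_max`` at the top.  Default
    values were calibrated so an untreated default-geometry crypt
    equilibrates near its homeostatic target of 1,750 cells while keeping
    cell residence times on the scale of days.
    """

    divide_max: float = 0.25
    divide_min: float = 0.0
    die_max: float = 0.06
    die_min: float = 0.005
    niche_fraction: float = 0.1
    differentiated_fraction: float = 1.0 / 3.0
    release_fraction: float = 0.9
    niche_replace_prob: float = 0.02
    mutant_descent_bias: float = 0.7
    resistant_exposure: float = 0.75

    def __post_init__(self) -> None:
        for name in ("divide_max", "divide_min", "die_max", "die_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CryptConfigError(f"{name} must be a probability in [0, 1]")
        if self.divide_max < self.divide_min:
            raise CryptConfigError("divide_max must be >= divide_min")
        if self.die_max < self.die_min:
            raise CryptConfigError("die_max must be >= die_min")
        if not 0.0 < self.niche_fraction < 1.0:
            raise CryptConfigError("niche_fraction must be in (0, 1)")
        if not 0.0 < self.differentiated_fraction < 1.0:
            raise CryptConfigError("differentiated_fraction must be in (0, 1)")
        if self.niche_fraction + self.differentiated_fraction >= 1.0:
            raise CryptConfigError("niche and differentiated zones overlap")
        if not 0.0 < self.release_fraction <= 1.0:
            raise CryptConfigError("release_fraction must be in (0, 1]")
        if not 0.0 <= self.niche_replace_prob <= 1.0:
            raise CryptConfigError("niche_replace_prob must be in [0, 1]")
        if not 0.0 <= self.mutant_descent_bias <= 1.0:
            raise CryptConfigError("mutant_descent_bias must be in [0, 1]")
        if not 0.0 < self.resistant_exposure <= 1.0:
            raise CryptConfigError("resistant_exposure must be in (0, 1]")

    def divide_base(self, height_norm) -> np.ndarray | float:
        """Positional divide probability before phenotype/compartment rules."""
        return self.divide_max + (self.divide_min - self.divide_max) * height_norm

    def die_base(self, height_norm) -> np.ndarray | float:
        """Positional die probability before phenotype/compartment rules."""
        return self.die_min + (self.die_max - self.die_min) * height_norm

    def compartment(self, height_norm: float) -> str:
        if height_norm < self.niche_fraction:
            return QUIESCENT_STEM
        if height_norm >= 1.0 - self.differentiated_fraction:
            return DIFFERENTIATED
        return PROLIFERATING


@dataclass(frozen=True)
class Cell:
    """Read-only view of one lattice cell, for the scalar probability API."""

    position: tuple[int, int]  # (ring/row index, angular/column index)
    height_norm: float
    compartment: str
    phenotype: CellPhenotype
    divided_this_step: bool = False


@dataclass
class StepStats:
    """Bookkeeping for one tick; total(t+1) = total(t) + births - deaths - removals."""

    births: int = 0
    deaths: int = 0
    removals: int = 0


@dataclass
class CryptState:
    """Full mutable state of one crypt.

    ``grid`` holds phenotype codes (0 = empty) with row 0 at the crypt
    bottom; ``lineage`` holds a clone identifier per cell (0 = empty), used
    for neutral-drift / monoclonal-conversion analyses.  ``step_crypt``
    advances the state in place; use :meth:`copy` to snapshot.
    """

    geometry: CryptGeometry
    gradients: GradientParams
    grid: np.ndarray
    lineage: np.ndarray
    step_index: int
    rng: np.random.Generator
    last_stats: StepStats = field(default_factory=StepStats)

    # ---- derived geometry (cached row masks) -------------------------------
    @property
    def height_norm(self) -> np.ndarray:
        H = self.geometry.height
        return np.arange(H) / (H - 1)

    def _row_masks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = self.height_norm
        niche = h < self.gradients.niche_fraction
        top = h >= 1.0 - self.gradients.differentiated_fraction
        return niche, ~niche & ~top, top

    # ---- counts ------------------------------------------------------------
    def total_cells(self) -> int:
        return int(np.count_nonzero(self.grid))

    def cancer_cells(self) -> int:
        """Cells of either cancer lineage (sensitive or resistant)."""
        return int(np.count_nonzero((self.grid == CANCER) | (self.grid == RESISTANT)))

    def cancer_fraction(self) -> float:
        total = self.total_cells()
        return self.cancer_cells() / total if total else 0.0

    def awake(self) -> bool:
        """True when crypt depletion has released the quiescent niche."""
        threshold = self.gradients.release_fraction * self.geometry.homeostatic_target
        return self.total_cells() < threshold

    # ---- cell views --------------------------------------------------------
    def cell_at(self, row: int, col: int) -> Cell:
        code = int(self.grid[row, col])
        if code == EMPTY:
            raise IndexError(f"no cell at ({row}, {col})")
        h = row / (self.geometry.height - 1)
        return Cell(
            position=(row, col),
            height_norm=h,
            compartment=self.gradients.compartment(h),
            phenotype=PHENOTYPES[_CODE_TO_LABEL[code]],
        )

    def iter_cells(self) -> Iterator[Cell]:
        for row, col in zip(*np.nonzero(self.grid)):
            yield self.cell_at(int(row), int(col))

    def copy(self) -> "CryptState":
        return CryptState(
            geometry=self.geometry,
            gradients=self.gradients,
            grid=self.grid.copy(),
            lineage=self.lineage.copy(),
            step_index=self.step_index,
            rng=_clone_rng(self.rng),
            last_stats=replace(self.last_stats),
        )


def _clone_rng(rng: np.random.Generator) -> np.random.Generator:
    clone = np.random.default_rng(0)
    clone.bit_generator.state = rng.bit_generator.state
    return clone


def init_crypt(
    geometry: CryptGeometry,
    gradients: GradientParams,
    seed: int | np.random.SeedSequence,
) -> CryptState:
    """Populate a crypt to its homeostatic target with normal cells.

    Cells fill each column contiguously from the bottom; compartments follow
    from height.  Every initial cell gets a distinct lineage identifier.
    Deterministic for a fixed seed.
    """
    H, C = geometry.height, geometry.circumference
    rng = np.random.default_rng(seed)
    grid = np.zeros((H, C), dtype=np.int8)
    lineage = np.zeros((H, C), dtype=np.int32)

    target = geometry.homeostatic_target
    full_rows, remainder = divmod(target, C)
    grid[:full_rows, :] = NORMAL
    if remainder:
        cols = rng.choice(C, size=remainder, replace=False)
        grid[full_rows, cols] = NORMAL
    occ_rows, occ_cols = np.nonzero(grid)
    lineage[occ_rows, occ_cols] = np.arange(1, occ_rows.size + 1, dtype=np.int32)

    return CryptState(
        geometry=geometry,
        gradients=gradients,
        grid=grid,
        lineage=lineage,
        step_index=0,
        rng=rng,
    )


def divide_probability(
    cell: Cell,
    gradients: GradientParams,
    crypt: CryptState | None = None,
    *,
    awake: bool | None = None,
) -> float:
    """Per-step division probability of one cell.

    ``clamp(positional_base(h) * phenotype.divide_multiplier, 0, 1)`` with
    two compartment rules: differentiated cells never divide, and quiescent
    stem cells divide only while the niche is released (crypt below the
    release fraction of its homeostatic target).
    """
    if awake is None:
        awake = crypt.awake() if crypt is not None else False
    if cell.compartment == DIFFERENTIATED:
        return 0.0
    if cell.compartment == QUIESCENT_STEM and not awake:
        return 0.0
    base = gradients.divide_base(cell.height_norm)
    return float(np.clip(base * cell.phenotype.divide_multiplier, 0.0, 1.0))


def die_probability(
    cell: Cell,
    gradients: GradientParams,
    lethality: float = 1.0,
    apoptotic_intensity: float = 1.0,
    *,
    awake: bool = False,
) -> float:
    """Per-step death probability of one cell under (possibly active) drugs.

    ``clamp(positional_die(h) * phenotype.die_multiplier * L_eff * A_eff, 0, 1)``
    where the cytotoxic lethality factor applies to dividing cells (the
    proliferating compartment, plus released stem cells) and the apoptotic
    factor applies to the differentiated top zone.  An inactive dose is
    encoded as factor 1.  Quiescent (non-released) stem cells do not die.
    """
    if lethality < 0 or apoptotic_intensity < 0:
        raise ValueError("drug intensity factors must be non-negative")
    if cell.compartment == QUIESCENT_STEM and not awake:
        return 0.0
    p = gradients.die_base(cell.height_norm) * cell.phenotype.die_multiplier
    if cell.compartment == PROLIFERATING or (
        cell.compartment == QUIESCENT_STEM and awake
    ):
        if lethality != 1.0:
            exposure = cell.phenotype.divide_multiplier
            if cell.phenotype.label == "resistant":
                exposure *= gradients.resistant_exposure
            p *= lethality * exposure
    if cell.compartment == DIFFERENTIATED:
        p *= apoptotic_intensity
    return float(np.clip(p, 0.0, 1.0))


def _niche_replacement(state: CryptState, niche_rows: np.ndarray) -> None:
    """Neutral drift in the stem niche: occasional symmetric divisions that
    replace a lattice-neighbour stem cell."""
    g = state.gradients
    if g.niche_replace_prob <= 0:
        return
    H, C = state.grid.shape
    niche_mask = niche_rows[:, None] & (state.grid != EMPTY)
    rows, cols = np.nonzero(niche_mask)
    if rows.size == 0:
        return
    events = state.rng.random(rows.size) < g.niche_replace_prob
    n_niche_rows = int(niche_rows.sum())
    for r, c in zip(rows[events], cols[events]):
        neighbours = [(r, (c - 1) % C), (r, (c + 1) % C)]
        if r > 0:
            neighbours.append((r - 1, c))
        if r + 1 < n_niche_rows:
            neighbours.append((r + 1, c))
        nr, nc = neighbours[state.rng.integers(len(neighbours))]
        if state.grid[nr, nc] != EMPTY:
            state.grid[nr, nc] = state.grid[r, c]
            state.lineage[nr, nc] = state.lineage[r, c]


def step_crypt(
    state: CryptState,
    lethality: float = 1.0,
    apoptotic_intensity: float = 1.0,
) -> CryptState:
    """Advance the crypt by one ~4-hour tick (in place).

    Order within the tick: niche neutral replacement, death draws, division
    draws, downward compaction of each column with daughters inserted just
    above or below their parents, then removal of cells pushed past the top
    row.  Returns the same (mutated) state object.
    """
    if lethality < 0 or apoptotic_intensity < 0:
        raise ValueError("drug intensity factors must be non-negative")

    geom, g = state.geometry, state.gradients
    grid, lineage, rng = state.grid, state.lineage, state.rng
    H, C = grid.shape
    h_col = state.height_norm[:, None]
    niche_rows, prolif_rows, top_rows = state._row_masks()

    awake = state.awake()

    _niche_replacement(state, niche_rows)

    # --- deaths -------------------------------------------------------------
    p_die = g.die_base(h_col) * _DIE_MULT[grid]
    lethal_zone = prolif_rows[:, None] | (niche_rows[:, None] & awake)
    if lethality != 1.0:
        # a cytotoxic drug kills cells in S phase, so exposure scales with
        # the cell's division propensity (its divide multiplier); resistant
        # cells additionally spend part of their time in a slow-cycling,
        # drug-invulnerable state, reducing their effective exposure
        exposure = _DIVIDE_MULT.copy()
        exposure[RESISTANT] *= g.resistant_exposure
        p_die = np.where(lethal_zone, p_die * lethality * exposure[grid], p_die)
    if apoptotic_intensity != 1.0:
        p_die = np.where(top_rows[:, None], p_die * apoptotic_intensity, p_die)
    if not awake:
        p_die = np.where(niche_rows[:, None], 0.0, p_die)
    np.clip(p_die, 0.0, 1.0, out=p_die)
    occupied = grid != EMPTY
    dead = occupied & (rng.random(grid.shape) < p_die)
    n_deaths = int(dead.sum())
    grid[dead] = EMPTY
    lineage[dead] = 0

    # --- divisions (survivors only) ------------------------------------------
    p_div = g.divide_base(h_col) * _DIVIDE_MULT[grid]
    p_div = np.where(top_rows[:, None], 0.0, p_div)
    if not awake:
        p_div = np.where(niche_rows[:, None], 0.0, p_div)
    np.clip(p_div, 0.0, 1.0, out=p_div)
    parents = (grid != EMPTY) & (rng.random(grid.shape) < p_div)
    pr, pc = np.nonzero(parents)
    n_births = pr.size

    # --- compaction + insertion + top removal --------------------------------
    sr, sc = np.nonzero(grid != EMPTY)
    daughter_cols = (pc + rng.integers(-1, 2, size=n_births)) % C
    cols = np.concatenate([sc, daughter_cols])
    # daughters sort just above or just below their parent; normal daughters
    # go either way with equal probability, mutant daughters are biased
    # downward (cancer cells respond poorly to the upward migration cue).
    # lexsort is stable so ties keep survivor-then-daughter order and fixed
    # column order
    parent_codes = grid[pr, pc]
    p_down = np.where(parent_codes == NORMAL, 0.5, g.mutant_descent_bias)
    vertical = np.where(rng.random(n_births) < p_down, -0.5, 0.5)
    keys = np.concatenate([sr.astype(np.float64), pr + vertical])
    # mutants never displace the stem niche: clamp their sort keys so they
    # cannot settle below the niche rows
    n_niche_rows = int(niche_rows.sum())
    phen_all = np.concatenate([grid[sr, sc], parent_codes])
    keys = np.where(phen_all != NORMAL, np.maximum(keys, n_niche_rows - 0.5), keys)
    phen = np.concatenate([grid[sr, sc], grid[pr, pc]])
    lin = np.concatenate([lineage[sr, sc], lineage[pr, pc]])

    order = np.lexsort((keys, cols))
    cols_s = cols[order]
    counts = np.bincount(cols_s, minlength=C)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    new_rows = np.arange(cols_s.size) - np.repeat(starts, counts)
    keep = new_rows < H
    n_removed = int((~keep).sum())

    grid[:] = EMPTY
    lineage[:] = 0
    grid[new_rows[keep], cols_s[keep]] = phen[order][keep]
    lineage[new_rows[keep], cols_s[keep]] = lin[order][keep]

    state.step_index += 1
    state.last_stats = StepStats(births=n_births, deaths=n_deaths, removals=n_removed)
    return state


def introduce_mutants(
    state: CryptState,
    phenotype_label: str,
    n_cells: int = 1,
    position: str = "lower_third",
) -> CryptState:
    """Convert proliferating cells to a cancer phenotype (in place).

    ``position`` selects the seeding region along the crypt axis: ``bottom``
    (just above the niche), ``lower_third`` or ``top_third``.  Mutant cells
    share a single new lineage identifier.  If no eligible cell exists the
    crypt is returned unchanged with a warning.
    """
    if phenotype_label not in ("cancer", "resistant"):
        raise ValueError(f"unknown mutant phenotype {phenotype_label!r}")
    g = state.gradients
    h = state.height_norm
    if position == "bottom":
        region = (h >= g.niche_fraction) & (h < g.niche_fraction + 0.05)
    elif position == "lower_third":
        region = (h >= g.niche_fraction) & (h < 1.0 / 3.0)
    elif position == "top_third":
        region = h >= 2.0 / 3.0
    else:
        raise ValueError(f"unknown seeding position {position!r}")

    _, prolif_rows, _ = state._row_masks()
    eligible = region[:, None] & prolif_rows[:, None] & (state.grid != EMPTY)
    if not eligible.any():
        # fall back to any occupied cell in the region (e.g. top third)
        eligible = region[:, None] & (state.grid != EMPTY)
    rows, cols = np.nonzero(eligible)
    if rows.size == 0:
        warnings.warn("no eligible cells for mutation; crypt unchanged")
        return state
    n = min(n_cells, rows.size)
    pick = state.rng.choice(rows.size, size=n, replace=False)
    code = _LABEL_TO_CODE[phenotype_label]
    mutant_lineage = int(state.lineage.max()) + 1
    state.grid[rows[pick], cols[pick]] = code
    state.lineage[rows[pick], cols[pick]] = mutant_lineage
    return state


@dataclass(frozen=True)
class CryptCensus:
    """Counts per (compartment, phenotype) plus summary fractions."""

    counts: Mapping[tuple[str, str], int]
    total: int
    cancer_fraction: float

    def compartment_total(self, compartment: str) -> int:
        return sum(v for (c, _), v in self.counts.items() if c == compartment)

    def phenotype_total(self, label: str) -> int:
        return sum(v for (_, p), v in self.counts.items() if p == label)


def census(state: CryptState) -> CryptCensus:
    """Count cells per compartment x phenotype; counts sum to the total."""
    niche_rows, prolif_rows, top_rows = state._row_masks()
    comp_masks = {
        QUIESCENT_STEM: niche_rows[:, None],
        PROLIFERATING: prolif_rows[:, None],
        DIFFERENTIATED: top_rows[:, None],
    }
    counts: dict[tuple[str, str], int] = {}
    for comp, mask in comp_masks.items():
        for label, code in _LABEL_TO_CODE.items():
            counts[(comp, label)] = int(np.count_nonzero(mask & (state.grid == code)))
    total = sum(counts.values())
    cancer = sum(
        v for (_, p), v in counts.items() if p in ("cancer", "resistant")
    )
    return CryptCensus(
        counts=counts,
        total=total,
        cancer_fraction=cancer / total if total else 0.0,
    )


@dataclass(frozen=True)
class CalibrationResult:
    params: GradientParams
    error: float


def _compartment_stats(
    geometry: CryptGeometry,
    params: GradientParams,
    *,
    steps: int,
    burn_in: int,
    seed,
) -> dict[str, tuple[float, float]]:
    state = init_crypt(geometry, params, seed)
    series: dict[str, list[int]] = {
        QUIESCENT_STEM: [],
        PROLIFERATING: [],
        DIFFERENTIATED: [],
    }
    for t in range(steps):
        step_crypt(state)
        if t >= burn_in:
            c = census(state)
            for comp in series:
                series[comp].append(c.compartment_total(comp))
    return {
        comp: (float(np.mean(v)), float(np.var(v))) for comp, v in series.items()
    }


def calibrate_gradients(
    targets: Mapping[str, tuple[float, float]],
    search_budget: int,
    seed: int,
    *,
    geometry: CryptGeometry | None = None,
    initial: GradientParams | None = None,
    sim_steps: int = 300,
    burn_in: int = 100,
    variance_weight: float = 0.1,
) -> CalibrationResult:
    """Fit divide/die gradient amplitudes to target cell-type statistics.

    ``targets`` maps each compartment to the (mean, variance) of its cell
    count in the reference data.  A seeded random search over
    ``(divide_max, die_max)`` minimizes a weighted squared relative error of
    the simulated long-run means and variances against the targets; the
    means dominate the objective because short-run variances are noisy.
    With ``search_budget`` 0 the initial guess and its error are returned.
    """
    geometry = geometry or CryptGeometry()
    initial = initial or GradientParams()
    if search_budget < 0:
        raise ValueError("search_budget must be >= 0")
    for comp, (mean, var) in targets.items():
        if mean <= 0 or var < 0:
            raise ValueError(f"invalid target for {comp!r}")
    if sum(m for m, _ in targets.values()) > geometry.capacity:
        raise CryptConfigError("target cell counts exceed lattice capacity")

    rng = np.random.default_rng(seed)

    def objective(params: GradientParams, eval_seed) -> float:
        stats = _compartment_stats(
            geometry, params, steps=sim_steps, burn_in=burn_in, seed=eval_seed
        )
        err = 0.0
        for comp, (t_mean, t_var) in targets.items():
            s_mean, s_var = stats[comp]
            err += ((s_mean - t_mean) / t_mean) ** 2
            err += variance_weight * ((s_var - t_var) / max(t_var, 1.0)) ** 2
        return err

    ss = np.random.SeedSequence(seed)
    eval_seeds = ss.spawn(search_budget + 1)
    best = CalibrationResult(initial, objective(initial, eval_seeds[0]))
    for k in range(search_budget):
        candidate = replace(
            initial,
            divide_max=float(rng.uniform(0.05, 0.6)),
            die_max=float(rng.uniform(0.05, 0.6)),
        )
        err = objective(candidate, eval_seeds[k + 1])
        if err < best.error:
            best = CalibrationResult(candidate, err)
    return best


def estimate_division_ratio(
    label_a: str,
    label_b: str,
    *,
    height_norm: float = 0.4,
    n_draws: int = 2_000_000,
    seed: int = 0,
    gradients: GradientParams | None = None,
) -> float:
    """Monte-Carlo estimate of the division-frequency ratio of two phenotypes.

    Places one cell of each phenotype at the same mid-crypt height and draws
    paired division events from independent seeded streams, returning the
    ratio of empirical division frequencies (a / b).
    """
    gradients = gradients or GradientParams()
    ss = np.random.SeedSequence(seed)
    rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(2))
    comp = gradients.compartment(height_norm)
    cells = {}
    for label in (label_a, label_b):
        cells[label] = Cell(
            position=(0, 0),
            height_norm=height_norm,
            compartment=comp,
            phenotype=PHENOTYPES[label],
        )
    p_a = divide_probability(cells[label_a], gradients)
    p_b = divide_probability(cells[label_b], gradients)
    freq_a = float(np.mean(rng_a.random(n_draws) < p_a))
    freq_b = float(np.mean(rng_b.random(n_draws) < p_b))
    if freq_b == 0:
        raise ZeroDivisionError("reference phenotype never divided")
    return freq_a / freq_b
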