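"""Surrogate-assisted exploration of the combination-schedule space.

Simulating 50 replicates per schedule over the full cross product of two
dose grids is computationally intractable, but a neural-network classifier
can predict toxicity for thousands of schedules per second.  The loop:

1. label a seeded random sample of schedules by simulation (the oracle),
2. train a probabilistic toxicity classifier on all labels so far,
3. predict over the full enumerated space,
4. label the batch of schedules whose predicted probability of toxicity is
   closest to 0.5 (uncertainty sampling),
5. repeat until held-out sensitivity and specificity both exceed the
   stopping thresholds.

The predicted-nontoxic subset is then executed by real simulation, so
surrogate false positives are self-correcting downstream; false negatives
merely remain unexplored.

The classifier contract is any calibrated probabilistic binary classifier;
the default is a small feed-forward network (two hidden layers) behind a
standardization step, with a logistic-regression fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler

from .treatment import CombinationSchedule, Schedule

__all__ = [
    "LabeledSchedule",
    "ALConfig",
    "ALState",
    "ALResult",
    "schedule_features",
    "train_surrogate",
    "select_uncertain",
    "evaluate_sens_spec",
    "run_active_learning",
    "toy_schedule_space",
    "toy_toxicity_oracle",
]


@dataclass(frozen=True)
class LabeledSchedule:
    """A 6-vector schedule feature row with its simulated toxicity label."""

    features: tuple[float, ...]
    toxic: bool


def schedule_features(schedule: Schedule) -> np.ndarray:
    """Map a schedule to the surrogate's 6-feature vector:
    (cyto duration, interval, intensity, apo duration, interval, intensity).
    Single-drug schedules put zeros in the missing slots."""
    if isinstance(schedule, CombinationSchedule):
        c, a = schedule.cytotoxic, schedule.apoptotic
        return np.array(
            [c.duration, c.interval, c.intensity, a.duration, a.interval, a.intensity],
            dtype=float,
        )
    z = [0.0, 0.0, 0.0]
    row = [schedule.duration, schedule.interval, schedule.intensity]
    if schedule.drug_kind == "cytotoxic":
        return np.array(row + z)
    return np.array(z + row)


def _dosing_features(X: np.ndarray) -> np.ndarray:
    """Append per-drug duty cycles and dose pressures to the raw 6-vector.

    Intermittent dosing is naturally parametrized by the duty cycle
    (duration / interval) and the time-averaged intensity
    (intensity x duty); toxicity boundaries run roughly along these
    quantities, which a network struggles to synthesize from raw
    duration/interval/intensity columns alone.
    """
    X = np.asarray(X, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        duty1 = np.where(X[:, 1] > 0, X[:, 0] / X[:, 1], 0.0)
        duty2 = np.where(X[:, 4] > 0, X[:, 3] / X[:, 4], 0.0)
    pressure1 = X[:, 2] * duty1
    pressure2 = X[:, 5] * duty2
    return np.column_stack([X, duty1, duty2, pressure1, pressure2])


def train_surrogate(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    *,
    model: str = "mlp",
) -> Pipeline:
    """Fit the probabilistic toxicity classifier; deterministic per seed.

    The pipeline appends duty-cycle/dose-pressure features, standardizes
    to zero mean / unit variance, then fits the classifier.  Raises if
    only one class is present (nothing to separate).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both toxicity classes")
    if model == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=(32, 16),
            activation="relu",
            max_iter=2000,
            random_state=seed,
        )
    elif model == "logistic":
        clf = LogisticRegression(max_iter=1000, random_state=seed)
    else:
        raise ValueError(f"unknown surrogate model {model!r}")
    pipe = Pipeline([
        ("dosing", FunctionTransformer(_dosing_features)),
        ("scale", StandardScaler()),
        ("clf", clf),
    ])
    pipe.fit(X, y)
    return pipe


def select_uncertain(
    model: Pipeline, pool: np.ndarray, batch: int
) -> np.ndarray:
    """Indices of the ``batch`` pool rows with predicted P(toxic) closest
    to 0.5; ties broken by enumeration order (stable sort)."""
    pool = np.asarray(pool, dtype=float)
    if pool.shape[0] == 0:
        raise ValueError("pool is empty")
    if batch > pool.shape[0]:
        raise ValueError("batch exceeds pool size")
    proba = model.predict_proba(pool)[:, 1]
    order = np.argsort(np.abs(proba - 0.5), kind="stable")
    return order[:batch]


def evaluate_sens_spec(
    model: Pipeline, X: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Sensitivity and specificity (in %) on a labeled evaluation set.

    Sensitivity = 100*TP/(TP+FN) on the toxic class; specificity =
    100*TN/(TN+FP) on the nontoxic class.  Both classes must be present.
    """
    y = np.asarray(y).astype(bool)
    if y.all() or not y.any():
        raise ValueError("evaluation set must contain both classes")
    pred = model.predict(np.asarray(X, dtype=float)).astype(bool)
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    return 100.0 * tp / (tp + fn), 100.0 * tn / (tn + fp)


@dataclass(frozen=True)
class ALConfig:
    """Loop hyper-parameters.

    Defaults mirror the full-scale exploration protocol (100,000 seed
    labels, batches of 10,000, stop when sensitivity and specificity both
    exceed 99%); scale them down together with the schedule space.
    """

    seed_size: int = 100_000
    batch_size: int = 10_000
    stop_sensitivity: float = 99.0
    stop_specificity: float = 99.0
    eval_size: int = 500
    max_iterations: int = 50
    model: str = "mlp"


@dataclass
class ALState:
    """Per-iteration snapshot of the loop."""

    iteration: int
    n_labeled: int
    sensitivity: float
    specificity: float


@dataclass
class ALResult:
    model: Pipeline
    nontoxic_indices: np.ndarray
    history: list[ALState] = field(default_factory=list)
    converged: bool = False
    n_labeled: int = 0


def run_active_learning(
    space: np.ndarray,
    oracle: Callable[[np.ndarray], np.ndarray],
    config: ALConfig,
    seed: int = 0,
) -> ALResult:
    """Run the uncertainty-sampling loop over an enumerated schedule space.

    ``space`` is the (n, 6) feature matrix of every candidate schedule;
    ``oracle`` labels feature rows as toxic (simulation at full scale, a
    cheap deterministic stand-in in tests).  A fixed held-out evaluation
    set is drawn uniformly from the space and labeled once at the start:
    uncertainty sampling concentrates the training labels on the
    toxic/nontoxic boundary, so evaluating on a split of the training
    labels would score the classifier only on the hardest points and the
    stopping criterion would describe boundary accuracy rather than
    accuracy over the schedule space.  Each iteration trains on all
    training labels so far, evaluates on the held-out set, and stops when
    sensitivity and specificity both exceed their thresholds; otherwise it
    labels the most uncertain unlabeled batch and retrains.  The training
    set grows by exactly ``batch_size`` per iteration (no point is labeled
    twice).

    Returns the final model, the indices predicted nontoxic (for downstream
    execution by real simulation), the per-iteration history, and a
    ``converged`` flag (False when the iteration cap was hit).
    """
    space = np.asarray(space, dtype=float)
    n = space.shape[0]
    if config.seed_size + config.eval_size > n:
        raise ValueError("seed_size + eval_size exceeds the schedule space")
    rng = np.random.default_rng(seed)

    draw = rng.choice(n, size=config.seed_size + config.eval_size, replace=False)
    eval_idx, labeled_idx = draw[: config.eval_size], draw[config.eval_size :]
    y_eval = np.asarray(oracle(space[eval_idx]), dtype=bool)
    labels = np.asarray(oracle(space[labeled_idx]), dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("oracle returned a single class on the seed sample")
    if y_eval.all() or not y_eval.any():
        raise ValueError("oracle returned a single class on the evaluation sample")

    unlabeled = np.ones(n, dtype=bool)
    unlabeled[labeled_idx] = False
    unlabeled[eval_idx] = False

    history: list[ALState] = []
    model = None
    converged = False
    for it in range(config.max_iterations):
        fit_seed = int(rng.integers(0, 2**31 - 1))
        model = train_surrogate(
            space[labeled_idx], labels, seed=fit_seed, model=config.model
        )
        sens, spec = evaluate_sens_spec(model, space[eval_idx], y_eval)
        history.append(
            ALState(
                iteration=it,
                n_labeled=int(labeled_idx.size),
                sensitivity=sens,
                specificity=spec,
            )
        )
        if sens > config.stop_sensitivity and spec > config.stop_specificity:
            converged = True
            break
        pool_idx = np.nonzero(unlabeled)[0]
        if pool_idx.size == 0:
            break
        batch = min(config.batch_size, pool_idx.size)
        pick = select_uncertain(model, space[pool_idx], batch)
        new_idx = pool_idx[pick]
        new_labels = np.asarray(oracle(space[new_idx]), dtype=bool)
        labeled_idx = np.concatenate([labeled_idx, new_idx])
        labels = np.concatenate([labels, new_labels])
        unlabeled[new_idx] = False

    proba = model.predict_proba(space)[:, 1]
    nontoxic = np.nonzero(proba < 0.5)[0]
    return ALResult(
        model=model,
        nontoxic_indices=nontoxic,
        history=history,
        converged=converged,
        n_labeled=int(labeled_idx.size),
    )


def toy_schedule_space(n: int = 10_000, seed: int = 0) -> np.ndarray:
    """A fully enumerable stand-in combination-schedule space for
    desk-scale runs of the loop (synthetic; no simulation behind it).

    Rows are (cyto duration, interval, intensity, apo duration, interval,
    intensity) drawn on the sweep's grids with interval > duration.
    """
    rng = np.random.default_rng(seed)
    durations = rng.integers(1, 13, size=(n, 2)).astype(float)
    intervals = 2.0 * rng.integers(7, 49, size=(n, 2))
    intensities = 0.25 * rng.integers(1, 81, size=(n, 2))
    return np.column_stack(
        [
            durations[:, 0],
            intervals[:, 0],
            intensities[:, 0],
            durations[:, 1],
            intervals[:, 1],
            intensities[:, 1],
        ]
    )


def toy_toxicity_oracle(features: np.ndarray, threshold: float = 2.0) -> np.ndarray:
    """Deterministic smooth toxic/nontoxic boundary for loop testing
    (synthetic stand-in for the simulation oracle).

    A schedule is toxic when its total drug pressure — intensity times duty
    cycle, summed over both drugs — exceeds the threshold; this mimics the
    real geometry of the toxic region (high dose, long duration, short
    interval) while being instant to evaluate.
    """
    f = np.atleast_2d(np.asarray(features, dtype=float))
    pressure = f[:, 2] * f[:, 0] / f[:, 1] + f[:, 5] * f[:, 3] / f[:, 4]
    return pressure > threshold
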