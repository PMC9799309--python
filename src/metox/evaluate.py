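"""Evaluation of oxidation-prone predictions against observed oxidation.

Two observation granularities are supported:

* residue-resolved data — each methionine carries a measured oxidation
  level; the ≥ 5% rule turns levels into binary labels and a standard
  confusion matrix follows;
* segment-level event counts — only the number of oxidation events per
  molecule is known (not which residue), so observed and predicted
  counts are matched per molecule: TP = min(observed, predicted), the
  excess on either side becoming FN or FP.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP). Uncertainties come
from bootstrap resampling of the per-methionine outcomes (or of the
per-molecule count tuples) with replacement; replicates whose ratio is
undefined are dropped and counted, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "BootstrapResult",
    "EvaluationResult",
    "DEFAULT_SEED",
    "label_from_oxidation",
    "confusion_from_labels",
    "confusion_from_event_counts",
    "event_outcome_units",
    "sens_spec",
    "bootstrap_errors",
    "semiquant_metrics",
    "evaluate_labels",
    "format_confusion",
]

DEFAULT_SEED = 20221229


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fn + other.fn,
            self.fp + other.fp,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class BootstrapResult:
    sens_mean: float
    spec_mean: float
    sens_err: float
    spec_err: float
    n_reps: int
    seed: int
    n_dropped_sens: int = 0
    n_dropped_spec: int = 0


@dataclass
class EvaluationResult:
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    sens_err: float
    spec_err: float
    n_bootstrap: int
    seed: int
    sens_boot_mean: float = math.nan
    spec_boot_mean: float = math.nan


def label_from_oxidation(ox_percent: float, min_level: float = 5.0) -> int:
    """Binary observed-oxidation label: 1 iff the measured oxidation level
    reaches the established minimum (≥ 5% by default)."""
    if ox_percent < 0:
        raise ValueError("oxidation level cannot be negative")
    return int(ox_percent >= min_level)


def confusion_from_labels(
    observed: Sequence[int], predicted: Sequence[int]
) -> ConfusionMatrix:
    """Cellwise confusion counts from paired binary labels."""
    observed = np.asarray(observed, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if observed.shape != predicted.shape:
        raise ValueError(
            f"observed ({observed.shape}) and predicted ({predicted.shape}) "
            "label vectors differ in length"
        )
    tp = int(np.sum((observed == 1) & (predicted == 1)))
    fn = int(np.sum((observed == 1) & (predicted == 0)))
    fp = int(np.sum((observed == 0) & (predicted == 1)))
    tn = int(np.sum((observed == 0) & (predicted == 0)))
    return ConfusionMatrix(tp, fn, fp, tn)


def confusion_from_event_counts(
    per_molecule: Iterable[Tuple[int, int, int]]
) -> ConfusionMatrix:
    """Confusion counts from per-molecule (n_met, observed, predicted)
    event-count tuples.

    Residue identity of the observed events is unknown, so counts are
    matched within each molecule: TP = min(observed, predicted), the
    remainder split into FN/FP, and the untouched methionines are TN.
    """
    total = ConfusionMatrix(0, 0, 0, 0)
    for n_met, observed, predicted in per_molecule:
        if not (0 <= observed <= n_met and 0 <= predicted <= n_met):
            raise ValueError(
                f"event counts (obs={observed}, pred={predicted}) exceed the "
                f"{n_met} methionines of the molecule"
            )
        tp = min(observed, predicted)
        fn = observed - tp
        fp = predicted - tp
        tn = n_met - observed - fp
        total = total + ConfusionMatrix(tp, fn, fp, tn)
    return total


def event_outcome_units(
    per_molecule: Iterable[Tuple[int, int, int]]
) -> list[Tuple[int, int]]:
    """Expand count-matched confusion cells into per-methionine
    (observed, predicted) outcomes — the resampling units for the
    bootstrap on event-count data."""
    units: list[Tuple[int, int]] = []
    for n_met, observed, predicted in per_molecule:
        cm = confusion_from_event_counts([(n_met, observed, predicted)])
        units.extend([(1, 1)] * cm.tp)
        units.extend([(1, 0)] * cm.fn)
        units.extend([(0, 1)] * cm.fp)
        units.extend([(0, 0)] * cm.tn)
    return units


def sens_spec(confusion: ConfusionMatrix) -> Tuple[float, float]:
    """(sensitivity, specificity); an undefined ratio (empty denominator)
    is reported as NaN, never silently zero."""
    sens = (
        confusion.tp / (confusion.tp + confusion.fn)
        if confusion.tp + confusion.fn > 0
        else math.nan
    )
    spec = (
        confusion.tn / (confusion.tn + confusion.fp)
        if confusion.tn + confusion.fp > 0
        else math.nan
    )
    return sens, spec


def _units_to_confusion(units: np.ndarray) -> ConfusionMatrix:
    if units.shape[1] == 2:
        return confusion_from_labels(units[:, 0], units[:, 1])
    return confusion_from_event_counts([tuple(row) for row in units])


def bootstrap_errors(
    unit_records: Sequence[Tuple[int, ...]],
    n_reps: int = 50,
    seed: int = DEFAULT_SEED,
) -> BootstrapResult:
    """Bootstrap mean and standard deviation of sensitivity/specificity.

    ``unit_records`` are either per-methionine (observed, predicted)
    pairs or per-molecule (n_met, observed, predicted) tuples; the
    record type is the resampling unit. Deterministic under a fixed
    seed; replicates with an undefined ratio are dropped and counted.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    units = np.asarray(unit_records, dtype=int)
    if units.ndim != 2 or units.shape[1] not in (2, 3):
        raise ValueError("unit records must be (obs, pred) or (n_met, obs, pred)")
    rng = np.random.default_rng(seed)
    n = units.shape[0]
    sens_reps: list[float] = []
    spec_reps: list[float] = []
    dropped_sens = dropped_spec = 0
    for _ in range(n_reps):
        sample = units[rng.integers(0, n, n)]
        sens, spec = sens_spec(_units_to_confusion(sample))
        if math.isnan(sens):
            dropped_sens += 1
        else:
            sens_reps.append(sens)
        if math.isnan(spec):
            dropped_spec += 1
        else:
            spec_reps.append(spec)
    if not sens_reps and not spec_reps:
        raise ValueError("all bootstrap replicates had undefined ratios")
    sens_arr = np.asarray(sens_reps)
    spec_arr = np.asarray(spec_reps)
    return BootstrapResult(
        sens_mean=float(sens_arr.mean()) if sens_arr.size else math.nan,
        spec_mean=float(spec_arr.mean()) if spec_arr.size else math.nan,
        sens_err=float(sens_arr.std(ddof=1)) if sens_arr.size > 1 else math.nan,
        spec_err=float(spec_arr.std(ddof=1)) if spec_arr.size > 1 else math.nan,
        n_reps=n_reps,
        seed=seed,
        n_dropped_sens=dropped_sens,
        n_dropped_spec=dropped_spec,
    )


def semiquant_metrics(
    descriptor_values: Sequence[float], ox_percent: Sequence[float]
) -> Tuple[float, float, float]:
    """Semiquantitative agreement between a descriptor and measured
    oxidation levels: R² of the ordinary least-squares fit of oxidation
    on the descriptor, Pearson r and Spearman ρ. Zero variance in
    either input yields NaNs (flagged undefined)."""
    x = np.asarray(descriptor_values, dtype=float)
    y = np.asarray(ox_percent, dtype=float)
    if x.shape != y.shape:
        raise ValueError("descriptor and oxidation vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan, math.nan
    fit = stats.linregress(x, y)
    pearson = stats.pearsonr(x, y).statistic
    spearman = stats.spearmanr(x, y).statistic
    return float(fit.rvalue**2), float(pearson), float(spearman)


def evaluate_labels(
    observed: Sequence[int],
    predicted: Sequence[int],
    n_bootstrap: int = 50,
    seed: int = DEFAULT_SEED,
) -> EvaluationResult:
    """Full residue-resolved evaluation: confusion, point ratios and
    bootstrap uncertainties in one result object."""
    confusion = confusion_from_labels(observed, predicted)
    sens, spec = sens_spec(confusion)
    boot = bootstrap_errors(
        list(zip(observed, predicted)), n_reps=n_bootstrap, seed=seed
    )
    return EvaluationResult(
        confusion=confusion,
        sensitivity=sens,
        specificity=spec,
        sens_err=boot.sens_err,
        spec_err=boot.spec_err,
        n_bootstrap=n_bootstrap,
        seed=seed,
        sens_boot_mean=boot.sens_mean,
        spec_boot_mean=boot.spec_mean,
    )


def format_confusion(confusion: ConfusionMatrix) -> str:
    """Render the confusion matrix with TP FN on the first row and FP TN
    on the second."""
    return (
        f"TP {confusion.tp:>4d}  FN {confusion.fn:>4d}\n"
        f"FP {confusion.fp:>4d}  TN {confusion.tn:>4d}"
    )
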