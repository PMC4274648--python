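"""Diagnostic-accuracy statistics for binary CT classification rules.

Implements the 2x2 machinery used to evaluate the scoring system:
confusion counts, sensitivity / specificity / predictive values / accuracy,
the two-point ROC area of a single binary rule (the trapezoid through
(0,0), (1-specificity, sensitivity), (1,1), i.e. (sens + spec) / 2, equal to
balanced accuracy), the Hanley-McNeil confidence interval for an AUC, HU
cut-off selection, Pearson chi-square comparison of categorical features, and
a univariate logistic fit (IRLS via statsmodels GLM) for cut-off modelling.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats

import statsmodels.api as sm

from .cohort import Cohort, PatientRecord

__all__ = [
    "ConfusionCounts",
    "DiagnosticIndices",
    "confusion_from_cohort",
    "diagnostic_indices",
    "two_point_auc",
    "auc_ci",
    "select_cutoff",
    "chi_square_rx2",
    "LogisticFit",
    "logistic_fit",
    "round_half_up",
    "percent",
]

logger = logging.getLogger(__name__)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the display convention of the report tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """A fraction as a half-up rounded percentage."""
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticIndices:
    """Sensitivity/specificity/PPV/NPV/accuracy bundle (proportions in [0,1]).

    An index whose denominator is zero is NaN and listed in ``undefined``
    rather than raising.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    undefined: frozenset[str]

    def as_percent(self, ndigits: int = 1) -> dict[str, float]:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            out[name] = float("nan") if name in self.undefined else round_half_up(100 * v, ndigits)
        return out


def confusion_from_cohort(
    cohort: Cohort, predictor: Callable[[PatientRecord], bool]
) -> ConfusionCounts:
    """Tally a per-patient binary rule against the histopathology labels."""
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    tp = fp = fn = tn = 0
    for record in cohort:
        predicted = bool(predictor(record))
        if record.dtd_label:
            tp += predicted
            fn += not predicted
        else:
            fp += predicted
            tn += not predicted
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (float("nan"), True)


def diagnostic_indices(counts: ConfusionCounts) -> DiagnosticIndices:
    """Standard indices from a 2x2 confusion table, NaN on zero denominators."""
    if counts.total == 0:
        logger.warning("all-zero confusion counts: every index is undefined")
    undefined = set()
    values = {}
    for name, num, den in (
        ("sensitivity", counts.tp, counts.tp + counts.fn),
        ("specificity", counts.tn, counts.tn + counts.fp),
        ("ppv", counts.tp, counts.tp + counts.fp),
        ("npv", counts.tn, counts.tn + counts.fn),
        ("accuracy", counts.tp + counts.tn, counts.total),
    ):
        values[name], missing = _ratio(num, den)
        if missing:
            undefined.add(name)
    return DiagnosticIndices(undefined=frozenset(undefined), **values)


def two_point_auc(sensitivity: float, specificity: float) -> float:
    """ROC area of a single binary rule.

    The empirical ROC of a binary rule has one interior operating point, so
    the trapezoidal area reduces to (sensitivity + specificity) / 2.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    return (sensitivity + specificity) / 2.0


def auc_ci(auc: float, n_pos: int, n_neg: int, level: float = 0.95) -> tuple[float, float]:
    """Hanley-McNeil standard-error interval for an AUC, clipped to [0, 1]."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both class counts must be positive")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def select_cutoff(
    cohort: Cohort,
    candidates: Sequence[float],
    comparison: str = "le",
) -> tuple[float, dict[float, float]]:
    """Pick the HU cut-off with the largest two-point AUC on a cohort.

    Positivity is ``hu <= c`` (``comparison="le"``) or ``hu < c`` (``"lt"``)
    on the nonenhanced HU.  Ties break toward the larger cutoff (the more
    sensitive rule); the result is invariant to candidate ordering.
    """
    from .scoring import cutoff_predicate

    if len(candidates) == 0:
        raise ValueError("need at least one candidate cutoff")
    aucs: dict[float, float] = {}
    best = None
    for c in sorted(candidates):
        rule = cutoff_predicate(c, comparison)
        counts = confusion_from_cohort(cohort, lambda r: rule(r.profile.attenuation_hu))
        idx = diagnostic_indices(counts)
        auc = two_point_auc(
            0.0 if math.isnan(idx.sensitivity) else idx.sensitivity,
            0.0 if math.isnan(idx.specificity) else idx.specificity,
        )
        aucs[c] = auc
        if best is None or auc >= aucs[best]:
            best = c
    return best, aucs


def chi_square_rx2(table) -> tuple[float, int, float]:
    """Pearson chi-square on an R x 2 count table, no continuity correction.

    All-zero rows (empty categories) are dropped first; at least two rows
    must remain.  Returns (statistic, degrees of freedom, p-value) with
    df = R' - 1 for R' retained rows.
    """
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an R x 2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.all(arr == np.floor(arr)):
        raise ValueError("table entries must be non-negative integers")
    arr = arr[arr.sum(axis=1) > 0].astype(np.int64)
    if arr.shape[0] < 2:
        raise ValueError("need at least two non-empty rows")
    if np.any(arr.sum(axis=0) == 0):
        raise ValueError("a column of the retained table is all zero")
    statistic, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(statistic), int(df), float(p)


class LogisticFit(NamedTuple):
    intercept: float
    slope: float
    converged: bool
    intercept_se: float
    slope_se: float


def logistic_fit(hu_values, labels) -> LogisticFit:
    """Univariate maximum-likelihood logistic regression of label on HU.

    Fit by iteratively reweighted least squares (at most 25 iterations,
    gradient tolerance 1e-8).  Complete separation is reported through
    ``converged=False`` instead of raising.
    """
    x = np.asarray(hu_values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("hu_values and labels must be 1-D of equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    design = sm.add_constant(x)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                maxiter=25, tol=1e-8
            )
        except Exception as exc:  # perfect separation can abort IRLS outright
            logger.warning("logistic fit failed (%s); reporting non-convergence", exc)
            return LogisticFit(float("nan"), float("nan"), False, float("nan"), float("nan"))
    if not getattr(result, "converged", True):
        converged = False
    fitted = np.asarray(result.fittedvalues)
    separated = bool(np.all(np.abs(fitted - y) < 1e-6))
    if separated:
        converged = False
    params = np.asarray(result.params, dtype=float)
    ses = np.asarray(result.bse, dtype=float)
    return LogisticFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        converged=converged,
        intercept_se=float(ses[0]),
        slope_se=float(ses[1]),
    )
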