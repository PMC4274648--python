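"""End-to-end evaluation reports mirroring the study's result tables.

The report of :func:`evaluate_cohort` bundles, for one labelled cohort:

* a per-feature frequency table with chi-square comparison of normal vs DTD
  glands (the frequency-analysis table),
* diagnostic indices of nonenhanced-HU cut-offs 80/90/100 with two-point
  ROC AUCs and Hanley-McNeil intervals (the cut-off table),
* diagnostic indices of every single CT feature category (the per-feature
  table),
* diagnostic indices of the "k or more abnormal features" rule for
  k = 1..5 (the count-threshold table),
* the selected best cut-off (largest two-point AUC) and best count
  threshold (largest accuracy), and a univariate logistic fit of disease
  on nonenhanced HU.

Every report carries the package version, the driving seed and a hash of
the classifier configuration, so a stored report is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict
from typing import Sequence

from . import __version__
from . import diagnostics, scoring
from .cohort import Cohort
from .diagnostics import (
    ConfusionCounts,
    auc_ci,
    confusion_from_cohort,
    diagnostic_indices,
    round_half_up,
    select_cutoff,
    two_point_auc,
)
from .scoring import ClassifierConfig, DEFAULT_CONFIG

__all__ = [
    "evaluate_cohort",
    "frequency_table",
    "cutoff_table",
    "feature_table",
    "threshold_table",
    "concordance_table",
    "render_report_text",
    "config_hash",
]

logger = logging.getLogger(__name__)

_FEATURE_FIELDS = (
    ("attenuation_degree", ("iso", "low", "high")),
    ("attenuation_pattern", ("homogeneous", "inhomogeneous", "heterogeneous")),
    ("size_category", ("normal", "increased", "decreased")),
    ("margin", ("smooth", "lobulated")),
    ("enhancement_pattern", ("homogeneous", "inhomogeneous", "heterogeneous")),
)


def config_hash(config: ClassifierConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _row_from_counts(counts: ConfusionCounts, with_auc: bool = True) -> dict:
    idx = diagnostic_indices(counts)
    row = {
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "tn": counts.tn,
        "indices_percent": idx.as_percent(),
        "fractions": {
            "sensitivity": f"{counts.tp}/{counts.n_pos}",
            "specificity": f"{counts.tn}/{counts.n_neg}",
            "ppv": f"{counts.tp}/{counts.tp + counts.fp}",
            "npv": f"{counts.tn}/{counts.tn + counts.fn}",
            "accuracy": f"{counts.tp + counts.tn}/{counts.total}",
        },
        "undefined": sorted(idx.undefined),
    }
    if with_auc:
        if idx.undefined & {"sensitivity", "specificity"}:
            row["auc"] = float("nan")
            row["auc_ci"] = (float("nan"), float("nan"))
        else:
            auc = two_point_auc(idx.sensitivity, idx.specificity)
            row["auc"] = round_half_up(auc, 4)
            if counts.n_pos > 0 and counts.n_neg > 0:
                lo, hi = auc_ci(auc, counts.n_pos, counts.n_neg)
                row["auc_ci"] = (round_half_up(lo, 4), round_half_up(hi, 4))
    return row


def frequency_table(cohort: Cohort) -> dict:
    """Per-feature category counts by group, with chi-square comparison."""
    table: dict = {}
    for feature, categories in _FEATURE_FIELDS:
        counts = {cat: {"normal": 0, "dtd": 0} for cat in categories}
        for record in cohort:
            group = "dtd" if record.dtd_label else "normal"
            counts[getattr(record.profile, feature)][group] += 1
        rx2 = [[counts[cat]["normal"], counts[cat]["dtd"]] for cat in categories]
        try:
            statistic, df, p = diagnostics.chi_square_rx2(rx2)
            chi = {"statistic": statistic, "df": df, "p": p}
        except ValueError as exc:
            logger.warning("chi-square unavailable for %s: %s", feature, exc)
            chi = None
        table[feature] = {"counts": counts, "chi_square": chi}
    return table


def cutoff_table(
    cohort: Cohort,
    cutoffs: Sequence[float] = (80.0, 90.0, 100.0),
    comparison: str = "le",
) -> dict:
    """Diagnostic indices of nonenhanced-HU cut-off rules."""
    rows = {}
    for cutoff in cutoffs:
        rule = scoring.cutoff_predicate(cutoff, comparison)
        counts = confusion_from_cohort(cohort, lambda r: rule(r.profile.attenuation_hu))
        rows[cutoff] = _row_from_counts(counts)
    return rows


def feature_table(cohort: Cohort) -> dict:
    """Diagnostic indices of every single CT feature category as a rule."""
    rows: dict = {}
    for feature, categories in _FEATURE_FIELDS:
        rows[feature] = {}
        for cat in categories:
            counts = confusion_from_cohort(
                cohort, lambda r, f=feature, c=cat: getattr(r.profile, f) == c
            )
            if counts.tp + counts.fp == 0 and cat in ("high", "heterogeneous", "decreased"):
                continue  # category absent from the cohort: no informative row
            rows[feature][cat] = _row_from_counts(counts, with_auc=False)
    return rows


def threshold_table(
    cohort: Cohort,
    config: ClassifierConfig = DEFAULT_CONFIG,
    ks: Sequence[int] = (1, 2, 3, 4, 5),
) -> dict:
    """Diagnostic indices of the "k or more abnormal features" rule."""
    rows = {}
    for k in ks:
        cfg = ClassifierConfig(
            low_hu_cutoff=config.low_hu_cutoff,
            high_hu_cutoff=config.high_hu_cutoff,
            size_band=config.size_band,
            count_threshold=k,
            comparison=config.comparison,
        )
        counts = confusion_from_cohort(
            cohort,
            lambda r: scoring.classify_dtd(scoring.flag_abnormal(r.profile, cfg), cfg),
        )
        rows[k] = _row_from_counts(counts)
    return rows


def evaluate_cohort(
    cohort: Cohort,
    config: ClassifierConfig = DEFAULT_CONFIG,
    cutoffs: Sequence[float] = (80.0, 90.0, 100.0),
    seed: int | None = None,
) -> dict:
    """Full diagnostic-accuracy report for one labelled cohort."""
    if len(cohort) == 0:
        raise ValueError("cannot evaluate an empty cohort")
    report = {
        "metadata": {
            "version": __version__,
            "seed": seed,
            "config": asdict(config),
            "config_hash": config_hash(config),
            "n_patients": len(cohort),
            "n_dtd": cohort.n_dtd,
            "n_normal": cohort.n_normal,
            "class_sizes": cohort.class_sizes(),
        },
        "frequency": frequency_table(cohort),
        "cutoffs": cutoff_table(cohort, cutoffs, config.comparison),
        "features": feature_table(cohort),
        "thresholds": threshold_table(cohort, config),
    }
    if cohort.n_dtd > 0 and cohort.n_normal > 0:
        best_cutoff, cutoff_aucs = select_cutoff(cohort, cutoffs, config.comparison)
        report["best_cutoff"] = best_cutoff
        report["cutoff_aucs"] = cutoff_aucs
        accuracies = {
            k: row["indices_percent"]["accuracy"] for k, row in report["thresholds"].items()
        }
        report["best_threshold"] = max(accuracies, key=lambda k: (accuracies[k], k))
        hu = [r.profile.attenuation_hu for r in cohort]
        labels = [r.dtd_label for r in cohort]
        fit = diagnostics.logistic_fit(hu, labels)
        report["logistic"] = {
            "intercept": fit.intercept,
            "slope": fit.slope,
            "converged": fit.converged,
            "intercept_se": fit.intercept_se,
            "slope_se": fit.slope_se,
        }
    else:
        logger.warning("cohort has a single class: skipping cut-off selection and fit")
        report["best_cutoff"] = None
        report["best_threshold"] = None
        report["logistic"] = None
    return report


def concordance_table(truth: Cohort, extracted: Cohort) -> dict:
    """Per-feature agreement between two cohorts of the same patients
    (e.g. generating profiles vs profiles measured on their phantoms)."""
    if len(truth) != len(extracted):
        raise ValueError("cohorts must have equal length")
    agreement = {}
    for feature, _ in _FEATURE_FIELDS:
        agree = sum(
            getattr(t.profile, feature) == getattr(e.profile, feature)
            for t, e in zip(truth, extracted)
        )
        agreement[feature] = agree / len(truth) if len(truth) else float("nan")
    agreement["overall"] = (
        sum(agreement[f] for f, _ in _FEATURE_FIELDS) / len(_FEATURE_FIELDS)
    )
    return agreement


# ---------------------------------------------------------------------------
# Text rendering
# ---------------------------------------------------------------------------

_INDEX_ORDER = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


def _fmt_row(row: dict) -> str:
    cells = []
    for name in _INDEX_ORDER:
        frac = row["fractions"][name]
        pct = row["indices_percent"][name]
        cells.append(f"{frac} ({'--' if math.isnan(pct) else pct})")
    auc = row.get("auc")
    if auc is not None and not math.isnan(auc):
        lo, hi = row["auc_ci"]
        cells.append(f"{auc:.4f}")
        cells.append(f"{lo:.4f}-{hi:.4f}")
    return "\t".join(cells)


def render_report_text(report: dict) -> str:
    """Aligned-text report mirroring the column order of the result tables."""
    lines = []
    meta = report["metadata"]
    lines.append(
        f"dtdct {meta['version']}  n={meta['n_patients']} "
        f"(DTD {meta['n_dtd']} / normal {meta['n_normal']})  "
        f"seed={meta['seed']}  config={meta['config_hash']}"
    )
    lines.append("")
    lines.append("Frequency of CT features (normal / DTD, chi-square)")
    for feature, entry in report["frequency"].items():
        chi = entry["chi_square"]
        ptxt = f"p={chi['p']:.4g}" if chi else "p=n/a"
        lines.append(f"  {feature} ({ptxt})")
        for cat, counts in entry["counts"].items():
            lines.append(f"    {cat:<14} {counts['normal']:>4} / {counts['dtd']:>4}")
    lines.append("")
    header = "\t".join(("rule",) + _INDEX_ORDER + ("AUC", "95% CI"))
    lines.append("Cut-off HU value (nonenhanced)")
    lines.append(header)
    for cutoff, row in report["cutoffs"].items():
        lines.append(f"{cutoff:g} or less\t" + _fmt_row(row))
    lines.append("")
    lines.append("Individual CT features")
    for feature, cats in report["features"].items():
        for cat, row in cats.items():
            lines.append(f"{feature}={cat}\t" + _fmt_row(row))
    lines.append("")
    lines.append("Number of abnormal CT features")
    lines.append(header)
    for k, row in report["thresholds"].items():
        lines.append(f"{k} or more\t" + _fmt_row(row))
    lines.append("")
    lines.append(f"best cutoff: {report['best_cutoff']}")
    lines.append(f"best count threshold: {report['best_threshold']}")
    fit = report.get("logistic")
    if fit:
        lines.append(
            f"logistic fit: intercept={fit['intercept']:.4f} "
            f"slope={fit['slope']:.4f} converged={fit['converged']}"
        )
    return "\n".join(lines) + "\n"
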