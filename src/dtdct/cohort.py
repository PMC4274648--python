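"""Synthetic patient cohorts for CT-based diffuse thyroid disease scoring.

Two generators are provided:

* :func:`sample_cohort` draws random cohorts whose per-class Hounsfield-unit
  distributions and categorical feature frequencies match the study
  population (157 normal glands, 52 with diffuse thyroid disease), and
* :func:`reconstruct_fixture_cohort` deterministically rebuilds 209-patient
  cohorts whose abnormal-feature counts reproduce the published
  contingency cells exactly, for use as evaluation fixtures.

The fixture builder solves a small contingency-reconstruction problem: given
the number of patients with >= k abnormal features (k = 1..5) in each
histopathology class, assign concrete features to patients so that per-feature
column totals sit as close as possible (L1) to the published per-feature
marginals.  The assignment is a deterministic greedy pass (largest remaining
demand first) — the classic constructive algorithm for degree-constrained
bipartite realisation — so identical inputs always produce identical fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import scoring
from .scoring import (
    ATTENUATION_DEGREES,
    MARGINS,
    PATTERNS,
    SIZE_CATEGORIES,
)

__all__ = [
    "HISTOPATH_CLASSES",
    "DTD_CLASSES",
    "STUDY_CLASS_SIZES",
    "FeatureProfile",
    "PatientRecord",
    "Cohort",
    "CohortGeneratorParams",
    "ParameterError",
    "CohortCSVError",
    "study_params",
    "sample_cohort",
    "reconstruct_fixture_cohort",
    "audit_fixture",
    "read_cohort_csv",
    "write_cohort_csv",
]

HISTOPATH_CLASSES = ("normal", "hashimoto", "non_hashimoto_lt", "diffuse_hyperplasia")
DTD_CLASSES = ("hashimoto", "non_hashimoto_lt", "diffuse_hyperplasia")

#: Histopathology class sizes of the study population (209 patients).
STUDY_CLASS_SIZES: Mapping[str, int] = {
    "normal": 157,
    "hashimoto": 17,
    "non_hashimoto_lt": 34,
    "diffuse_hyperplasia": 1,
}

#: Per-group mean (SD) parenchymal HU: (nonenhanced, enhanced).
NORMAL_HU = ((114.3, 21.2), (202.5, 29.3))
DTD_HU = ((94.5, 21.3), (187.6, 29.9))

#: Published per-group categorical feature counts (the frequency table).
TABLE_FREQUENCIES: Mapping[str, Mapping[str, Mapping[str, int]]] = {
    "normal": {
        "attenuation_degree": {"iso": 130, "low": 27, "high": 0},
        "attenuation_pattern": {"homogeneous": 142, "inhomogeneous": 14, "heterogeneous": 1},
        "size_category": {"normal": 134, "increased": 22, "decreased": 1},
        "margin": {"smooth": 153, "lobulated": 4},
        "enhancement_pattern": {"homogeneous": 152, "inhomogeneous": 5, "heterogeneous": 0},
    },
    "dtd": {
        "attenuation_degree": {"iso": 18, "low": 34, "high": 0},
        "attenuation_pattern": {"homogeneous": 17, "inhomogeneous": 35, "heterogeneous": 0},
        "size_category": {"normal": 38, "increased": 14, "decreased": 0},
        "margin": {"smooth": 40, "lobulated": 12},
        "enhancement_pattern": {"homogeneous": 22, "inhomogeneous": 30, "heterogeneous": 0},
    },
}

#: Per-group abnormal-feature marginal totals, in scoring feature order.
ABNORMAL_MARGINALS = {
    "normal": (27, 14, 22, 4, 5),
    "dtd": (34, 35, 14, 12, 30),
}

# Distribution of low-attenuation patients over the HU bands of the cut-off
# sweep: (<=80, 80-90, 90-100), from the published cut-off table.
LOW_HU_BAND_COUNTS = {"normal": (8, 11, 8), "dtd": (14, 11, 9)}

# Per-class abnormal-feature count multiplicities (count value -> patients),
# listed from 5 down to 0, for the two fixture modes.
_FIXTURE_COUNTS = {
    "table4": {
        # Fixes the k=1,2,3 confusion cells exactly; counts capped at 3
        # because the published table does not constrain the >=4 split.
        "normal": {3: 7, 2: 20, 1: 57, 0: 73},
        "hashimoto": {3: 17},
        "non_hashimoto_lt": {3: 11, 2: 11, 1: 6, 0: 6},
        "diffuse_hyperplasia": {3: 1},
    },
    "section3": {
        # Narrative class breakdowns for >=1..>=4; the unstated five-feature
        # cases (n=5) are assigned to Hashimoto patients (see methods note).
        "normal": {4: 1, 3: 4, 2: 8, 1: 41, 0: 103},
        "hashimoto": {5: 5, 4: 2, 3: 6, 2: 3, 1: 1},
        "non_hashimoto_lt": {4: 6, 3: 6, 2: 8, 1: 6, 0: 8},
        "diffuse_hyperplasia": {4: 1},
    },
}

_CSV_COLUMNS = [
    "patient_id",
    "histopath_class",
    "hu_nonenhanced",
    "hu_enhanced",
    "attenuation_degree",
    "attenuation_pattern",
    "size_category",
    "margin",
    "enhancement_pattern",
]

_CATEGORY_DOMAINS = {
    "attenuation_degree": ATTENUATION_DEGREES,
    "attenuation_pattern": PATTERNS,
    "size_category": SIZE_CATEGORIES,
    "margin": MARGINS,
    "enhancement_pattern": PATTERNS,
}


class ParameterError(ValueError):
    """Invalid cohort generator parameters."""


class CohortCSVError(ValueError):
    """Malformed cohort CSV content."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureProfile:
    """The CT features of one patient.

    ``enhancement_degree`` is always the difference ``enhanced_hu -
    attenuation_hu``; it is exposed as a derived property so the invariant
    cannot be broken.
    """

    attenuation_hu: float
    enhanced_hu: float
    attenuation_degree: str
    attenuation_pattern: str
    size_category: str
    margin: str
    enhancement_pattern: str

    def __post_init__(self) -> None:
        for name in (
            "attenuation_degree",
            "attenuation_pattern",
            "size_category",
            "margin",
            "enhancement_pattern",
        ):
            value = getattr(self, name)
            domain = _CATEGORY_DOMAINS[name]
            if value not in domain:
                raise ValueError(f"{name} must be one of {domain}, got {value!r}")
        if not (math.isfinite(self.attenuation_hu) and math.isfinite(self.enhanced_hu)):
            raise ValueError("HU values must be finite")

    @property
    def enhancement_degree(self) -> float:
        return self.enhanced_hu - self.attenuation_hu


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    histopath_class: str
    profile: FeatureProfile

    def __post_init__(self) -> None:
        if self.histopath_class not in HISTOPATH_CLASSES:
            raise ValueError(
                f"histopath_class must be one of {HISTOPATH_CLASSES}, got {self.histopath_class!r}"
            )

    @property
    def dtd_label(self) -> bool:
        """True for any non-normal histopathology; never stored separately."""
        return self.histopath_class != "normal"


class Cohort:
    """An ordered collection of :class:`PatientRecord`."""

    def __init__(self, records: Iterable[PatientRecord]):
        self._records: tuple[PatientRecord, ...] = tuple(records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self._records)

    def __getitem__(self, index):
        return self._records[index]

    def __eq__(self, other) -> bool:
        return isinstance(other, Cohort) and self._records == other._records

    def __repr__(self) -> str:
        return f"Cohort(n={len(self)}, dtd={self.n_dtd})"

    @property
    def records(self) -> tuple[PatientRecord, ...]:
        return self._records

    @property
    def n_dtd(self) -> int:
        return sum(r.dtd_label for r in self._records)

    @property
    def n_normal(self) -> int:
        return len(self) - self.n_dtd

    def class_sizes(self) -> dict[str, int]:
        sizes = {c: 0 for c in HISTOPATH_CLASSES}
        for r in self._records:
            sizes[r.histopath_class] += 1
        return sizes

    def abnormal_counts(self, config: scoring.ClassifierConfig = scoring.DEFAULT_CONFIG) -> list[int]:
        return [scoring.flag_abnormal(r.profile, config).count for r in self._records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self._records:
            p = r.profile
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "histopath_class": r.histopath_class,
                    "hu_nonenhanced": p.attenuation_hu,
                    "hu_enhanced": p.enhanced_hu,
                    "attenuation_degree": p.attenuation_degree,
                    "attenuation_pattern": p.attenuation_pattern,
                    "size_category": p.size_category,
                    "margin": p.margin,
                    "enhancement_pattern": p.enhancement_pattern,
                }
            )
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)


# ---------------------------------------------------------------------------
# Random cohort generation
# ---------------------------------------------------------------------------

# Category sampling order per feature, most-DTD-suggestive first, so that a
# positive shared latent pushes every feature toward abnormality together.
_SAMPLING_ORDER = {
    "attenuation_pattern": ("inhomogeneous", "heterogeneous", "homogeneous"),
    "size_category": ("increased", "decreased", "normal"),
    "margin": ("lobulated", "smooth"),
    "enhancement_pattern": ("inhomogeneous", "heterogeneous", "homogeneous"),
}


def _group_of(histopath_class: str) -> str:
    return "normal" if histopath_class == "normal" else "dtd"


def study_params() -> "CohortGeneratorParams":
    """Generator parameters matching the study population."""
    hu_non, hu_enh, probs = {}, {}, {}
    for cls in HISTOPATH_CLASSES:
        group = _group_of(cls)
        (non, enh) = NORMAL_HU if group == "normal" else DTD_HU
        hu_non[cls] = non
        hu_enh[cls] = enh
        freq = TABLE_FREQUENCIES[group]
        total = sum(freq["margin"].values())
        probs[cls] = {
            feat: {cat: freq[feat][cat] / total for cat in _SAMPLING_ORDER[feat]}
            for feat in _SAMPLING_ORDER
        }
    return CohortGeneratorParams(
        class_sizes=dict(STUDY_CLASS_SIZES),
        hu_nonenhanced=hu_non,
        hu_enhanced=hu_enh,
        feature_probs=probs,
    )


@dataclass
class CohortGeneratorParams:
    """Parameters of the random cohort generator.

    ``feature_probs`` holds one probability simplex per sampled categorical
    feature per class (attenuation pattern, size, margin, enhancement
    pattern).  The attenuation *degree* is not sampled: it is derived from
    the untruncated HU draw through the banding rule, which keeps the HU
    distribution and the degree consistent by construction.
    ``correlation`` in [0, 1] couples all features (and low HU) through one
    shared latent Gaussian factor; 0 means independent features.
    """

    class_sizes: Mapping[str, int]
    hu_nonenhanced: Mapping[str, tuple[float, float]]
    hu_enhanced: Mapping[str, tuple[float, float]]
    feature_probs: Mapping[str, Mapping[str, Mapping[str, float]]]
    correlation: float = 0.0

    def validate(self) -> None:
        for cls, n in self.class_sizes.items():
            if cls not in HISTOPATH_CLASSES:
                raise ParameterError(f"unknown histopathology class {cls!r}")
            if n < 0:
                raise ParameterError(f"class size for {cls!r} must be >= 0")
        for table in (self.hu_nonenhanced, self.hu_enhanced):
            for cls, (_, sd) in table.items():
                if sd <= 0:
                    raise ParameterError(f"HU SD for {cls!r} must be positive")
        for cls, feats in self.feature_probs.items():
            for feat, simplex in feats.items():
                if feat not in _SAMPLING_ORDER:
                    raise ParameterError(f"unknown feature {feat!r}")
                if set(simplex) != set(_SAMPLING_ORDER[feat]):
                    raise ParameterError(f"wrong categories for {feat!r} in class {cls!r}")
                if any(p < 0 for p in simplex.values()):
                    raise ParameterError(f"negative probability for {feat!r} in class {cls!r}")
                if abs(sum(simplex.values()) - 1.0) > 1e-9:
                    raise ParameterError(f"probabilities for {feat!r} in class {cls!r} must sum to 1")
        if not 0.0 <= self.correlation <= 1.0:
            raise ParameterError("correlation must lie in [0, 1]")


def sample_cohort(params: CohortGeneratorParams, seed: int) -> Cohort:
    """Draw a random cohort with the configured class structure.

    HU values are sampled untruncated from per-class normal distributions;
    the attenuation degree follows from the banding rule.  Categorical
    features are drawn from the per-class simplices, independently when
    ``params.correlation`` is 0 and through a shared latent factor otherwise.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    rho = params.correlation
    records: list[PatientRecord] = []
    for cls in HISTOPATH_CLASSES:
        n = int(params.class_sizes.get(cls, 0))
        if n == 0:
            continue
        shared = rng.standard_normal(n)

        def latent() -> np.ndarray:
            eps = rng.standard_normal(n)
            return math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * eps

        mu_n, sd_n = params.hu_nonenhanced[cls]
        mu_e, sd_e = params.hu_enhanced[cls]
        # A positive latent lowers HU: low attenuation is the abnormal pole.
        hu_non = mu_n - sd_n * latent()
        hu_enh = mu_e - sd_e * latent()
        cats: dict[str, list[str]] = {}
        for feat in _SAMPLING_ORDER:
            u = stats.norm.sf(latent())  # large latent -> small u -> abnormal
            order = _SAMPLING_ORDER[feat]
            simplex = params.feature_probs[cls][feat]
            edges = np.cumsum([simplex[c] for c in order])
            idx = np.searchsorted(edges, u, side="left")
            idx = np.minimum(idx, len(order) - 1)
            cats[feat] = [order[i] for i in idx]
        for i in range(n):
            profile = FeatureProfile(
                attenuation_hu=float(hu_non[i]),
                enhanced_hu=float(hu_enh[i]),
                attenuation_degree=scoring.classify_attenuation_degree(float(hu_non[i])),
                attenuation_pattern=cats["attenuation_pattern"][i],
                size_category=cats["size_category"][i],
                margin=cats["margin"][i],
                enhancement_pattern=cats["enhancement_pattern"][i],
            )
            records.append(PatientRecord(f"{cls}-{i:05d}", cls, profile))
    return Cohort(records)


# ---------------------------------------------------------------------------
# Fixture reconstruction
# ---------------------------------------------------------------------------


def _expand_counts(multiplicities: Mapping[int, int]) -> list[int]:
    out: list[int] = []
    for value in sorted(multiplicities, reverse=True):
        out.extend([value] * multiplicities[value])
    return out


def _greedy_assign(counts: Sequence[int], targets: Sequence[int]) -> list[tuple[int, ...]]:
    """Assign ``counts[i]`` distinct features to each patient.

    Patients are processed in descending count order; each takes the features
    with the largest remaining demand (ties by feature order).  When demand is
    exhausted the excess goes to the *last* features in reporting order, which
    protects the attenuation marginals that anchor the published cut-off and
    per-feature tables.
    """
    n_feat = len(targets)
    demand = list(targets)
    order = sorted(range(len(counts)), key=lambda i: -counts[i])
    assignment: list[tuple[int, ...]] = [()] * len(counts)
    for i in order:
        c = counts[i]
        if c == 0:
            continue
        positive = sorted(
            (f for f in range(n_feat) if demand[f] > 0), key=lambda f: (-demand[f], f)
        )
        chosen = positive[:c]
        if len(chosen) < c:
            overflow = sorted(
                (f for f in range(n_feat) if f not in chosen and demand[f] <= 0),
                key=lambda f: (-demand[f], -f),
            )
            chosen.extend(overflow[: c - len(chosen)])
        for f in chosen:
            demand[f] -= 1
        assignment[i] = tuple(sorted(chosen))
    return assignment


def _band_quotas(m: int, weights: Sequence[int]) -> list[int]:
    total = sum(weights)
    base = [m * w // total for w in weights]
    rem = m - sum(base)
    idx = len(weights) - 1
    while rem > 0:
        base[idx] += 1
        rem -= 1
        idx = (idx - 1) % len(weights)
    return base


_JUST_BELOW_100 = float(np.nextafter(100.0, -np.inf))
_JUST_ABOVE_100 = float(np.nextafter(100.0, np.inf))


def _truncated_hu(rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def reconstruct_fixture_cohort(mode: str, seed: int = 0) -> Cohort:
    """Deterministically rebuild a 209-patient study fixture.

    ``mode="table4"`` reproduces the published confusion cells of the
    count-threshold table exactly for k = 1, 2, 3.  ``mode="section3"``
    reproduces the narrative breakdown of patients per threshold
    (98/50/31/15/5 with the stated class compositions) and pushes per-feature
    abnormal totals as close as possible (L1) to the published marginals;
    the two constraint sets are mutually inconsistent, so only one can hold
    at a time.  ``seed`` drives HU sampling only — the feature assignment is
    fully deterministic.
    """
    if mode not in _FIXTURE_COUNTS:
        raise ValueError(f"mode must be one of {tuple(_FIXTURE_COUNTS)}, got {mode!r}")
    per_class = {cls: _expand_counts(_FIXTURE_COUNTS[mode][cls]) for cls in HISTOPATH_CLASSES}
    for cls in HISTOPATH_CLASSES:
        per_class[cls].extend([0] * (STUDY_CLASS_SIZES[cls] - len(per_class[cls])))
        assert len(per_class[cls]) == STUDY_CLASS_SIZES[cls]

    # Pool patients per comparison group and assign concrete features.
    assignments: dict[str, list[tuple[int, ...]]] = {}
    for group, classes in (("normal", ("normal",)), ("dtd", DTD_CLASSES)):
        counts = [c for cls in classes for c in per_class[cls]]
        assignments[group] = _greedy_assign(counts, ABNORMAL_MARGINALS[group])

    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    offsets = {"normal": 0, "dtd": 0}
    # Special normal-class patients, chosen among the zero-count tail:
    # one heterogeneous attenuation pattern and one decreased gland
    # (section3 mode, matching the frequency table's non-abnormal singletons)
    # and one iso gland at exactly 100.0 HU (both modes: the published
    # cut-off table counts one more normal at "<=100" than at "<100").
    zero_positions = [
        i for i, c in enumerate(per_class["normal"]) if c == 0
    ]
    het_patient = zero_positions[0] if mode == "section3" else None
    decreased_patient = zero_positions[1] if mode == "section3" else None
    tie_patient = zero_positions[2] if mode == "section3" else zero_positions[0]

    # Pre-compute HU band membership for low-attenuation patients per group.
    low_band: dict[tuple[str, int], int] = {}
    for group, classes in (("normal", ("normal",)), ("dtd", DTD_CLASSES)):
        flags = assignments[group]
        low_idx = [i for i, feats in enumerate(flags) if 0 in feats]
        quotas = _band_quotas(len(low_idx), LOW_HU_BAND_COUNTS[group])
        pos = 0
        for band, q in enumerate(quotas):
            for i in low_idx[pos : pos + q]:
                low_band[(group, i)] = band
            pos += q

    band_bounds = [(-np.inf, 80.0), (80.0, 90.0), (90.0, _JUST_BELOW_100)]
    serial = 0
    for cls in HISTOPATH_CLASSES:
        group = _group_of(cls)
        (mu_n, sd_n), (mu_e, sd_e) = NORMAL_HU if group == "normal" else DTD_HU
        for j in range(STUDY_CLASS_SIZES[cls]):
            gi = offsets[group]
            feats = assignments[group][gi]
            is_low = 0 in feats
            if is_low:
                lo, hi = band_bounds[low_band[(group, gi)]]
                hu_non = _truncated_hu(rng, mu_n, sd_n, lo, hi)
                degree = "low"
            elif cls == "normal" and j == tie_patient:
                hu_non = 100.0
                degree = "iso"
            else:
                hu_non = _truncated_hu(rng, mu_n, sd_n, _JUST_ABOVE_100, 180.0)
                degree = "iso"
            hu_enh = float(rng.normal(mu_e, sd_e))
            att_pattern = "inhomogeneous" if 1 in feats else "homogeneous"
            size_cat = "increased" if 2 in feats else "normal"
            margin = "lobulated" if 3 in feats else "smooth"
            enh_pattern = "inhomogeneous" if 4 in feats else "homogeneous"
            if cls == "normal" and j == het_patient:
                att_pattern = "heterogeneous"
            if cls == "normal" and j == decreased_patient:
                size_cat = "decreased"
            profile = FeatureProfile(
                attenuation_hu=hu_non,
                enhanced_hu=hu_enh,
                attenuation_degree=degree,
                attenuation_pattern=att_pattern,
                size_category=size_cat,
                margin=margin,
                enhancement_pattern=enh_pattern,
            )
            serial += 1
            records.append(PatientRecord(f"{mode}-{serial:03d}", cls, profile))
            offsets[group] += 1
    return Cohort(records)


def minimal_section3_residual() -> int:
    """Exhaustive feasibility audit of the narrative fixture constraints.

    Enumerates every feasible allocation of the five unattributed
    five-feature cases over the histopathology classes and returns the
    smallest achievable L1 distance between per-group abnormal instance
    totals and the published marginal totals.  The narrative thresholds fix
    per-class instance totals through the sum-of-thresholds identity
    (sum over k >= 1 of #{count >= k} equals the number of abnormal feature
    instances), so the residual can be audited without building cohorts.
    """
    base = {"hashimoto": 53, "non_hashimoto_lt": 64, "diffuse_hyperplasia": 4, "normal": 73}
    caps = {"hashimoto": 7, "non_hashimoto_lt": 6, "diffuse_hyperplasia": 1, "normal": 1}
    target = {"dtd": sum(ABNORMAL_MARGINALS["dtd"]), "normal": sum(ABNORMAL_MARGINALS["normal"])}
    best = None
    for h5 in range(min(5, caps["hashimoto"]) + 1):
        for n5 in range(min(5 - h5, caps["non_hashimoto_lt"]) + 1):
            for d5 in range(min(5 - h5 - n5, caps["diffuse_hyperplasia"]) + 1):
                m5 = 5 - h5 - n5 - d5
                if m5 < 0 or m5 > caps["normal"]:
                    continue
                dtd_total = base["hashimoto"] + base["non_hashimoto_lt"] + base["diffuse_hyperplasia"] + h5 + n5 + d5
                norm_total = base["normal"] + m5
                residual = abs(dtd_total - target["dtd"]) + abs(norm_total - target["normal"])
                best = residual if best is None else min(best, residual)
    return int(best)


def audit_fixture(
    cohort: Cohort, config: scoring.ClassifierConfig = scoring.DEFAULT_CONFIG
) -> dict:
    """Consistency audit of a cohort against the published marginals.

    Returns the per-threshold patient counts, the per-group achieved
    abnormal-feature column totals, their L1 residual against the published
    marginals, and a brute-force check of the sum-of-thresholds identity.
    Infeasible constraint sets therefore surface as a nonzero reported
    residual, never as a silent failure.
    """
    counts = cohort.abnormal_counts(config)
    threshold_counts = {k: sum(c >= k for c in counts) for k in range(1, 6)}
    identity_holds = sum(threshold_counts.values()) == sum(counts)
    achieved = {"normal": [0] * 5, "dtd": [0] * 5}
    for record in cohort:
        flags = scoring.flag_abnormal(record.profile, config).as_tuple()
        group = _group_of(record.histopath_class)
        for f, on in enumerate(flags):
            achieved[group][f] += int(on)
    residual = {
        group: sum(
            abs(a - t) for a, t in zip(achieved[group], ABNORMAL_MARGINALS[group])
        )
        for group in achieved
    }
    return {
        "threshold_counts": threshold_counts,
        "achieved_marginals": {g: tuple(v) for g, v in achieved.items()},
        "target_marginals": {g: ABNORMAL_MARGINALS[g] for g in achieved},
        "l1_residual": residual,
        "total_l1_residual": sum(residual.values()),
        "sum_of_thresholds_identity": identity_holds,
    }


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort as UTF-8 comma-separated text with a mandatory header."""
    cohort.to_dataframe().to_csv(path, index=False)


def read_cohort_csv(path) -> Cohort:
    """Read a cohort CSV, validating the header and every category.

    Malformed rows raise :class:`CohortCSVError` naming the offending line
    (1-based, counting the header as line 1).  A file holding only the header
    yields an empty cohort.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise CohortCSVError("file is empty: a header line is mandatory") from exc
    if list(frame.columns) != _CSV_COLUMNS:
        raise CohortCSVError(
            f"bad header: expected columns {_CSV_COLUMNS}, got {list(frame.columns)}"
        )
    records = []
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        data = dict(zip(_CSV_COLUMNS, row))
        try:
            if data["histopath_class"] not in HISTOPATH_CLASSES:
                raise ValueError(f"unknown histopath_class {data['histopath_class']!r}")
            profile = FeatureProfile(
                attenuation_hu=float(data["hu_nonenhanced"]),
                enhanced_hu=float(data["hu_enhanced"]),
                attenuation_degree=data["attenuation_degree"],
                attenuation_pattern=data["attenuation_pattern"],
                size_category=data["size_category"],
                margin=data["margin"],
                enhancement_pattern=data["enhancement_pattern"],
            )
            records.append(PatientRecord(data["patient_id"], data["histopath_class"], profile))
        except (ValueError, TypeError) as exc:
            raise CohortCSVError(f"line {pos}: {exc}") from exc
    return Cohort(records)
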