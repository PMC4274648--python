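"""Rule-based CT feature scoring for diffuse thyroid disease (DTD).

Five categorical CT features are read off a patient's feature profile and
counted against a "k or more" rule:

* low parenchymal attenuation on nonenhanced CT (mean HU < 100),
* inhomogeneous attenuation pattern,
* increased glandular size (average anteroposterior diameter > 2 cm),
* lobulated thyroid margin,
* inhomogeneous enhancement pattern.

A patient is called DTD-positive when at least ``k`` of the five features are
abnormal (default ``k = 3``).  Heterogeneous patterns and decreased size are
recorded but never counted as abnormal, and the degree of parenchymal
enhancement (enhanced minus nonenhanced HU) contributes no flag: no usable
enhancement cut-off separates DTD from normal glands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

__all__ = [
    "ATTENUATION_DEGREES",
    "PATTERNS",
    "SIZE_CATEGORIES",
    "MARGINS",
    "ABNORMAL_FEATURES",
    "ClassifierConfig",
    "DEFAULT_CONFIG",
    "AbnormalFlags",
    "classify_attenuation_degree",
    "classify_size_category",
    "flag_abnormal",
    "classify_dtd",
    "enhancement_degree",
    "cutoff_predicate",
]

ATTENUATION_DEGREES = ("iso", "low", "high")
PATTERNS = ("homogeneous", "inhomogeneous", "heterogeneous")
SIZE_CATEGORIES = ("normal", "increased", "decreased")
MARGINS = ("smooth", "lobulated")

#: The five DTD-suggestive features, in reporting order.
ABNORMAL_FEATURES = (
    "low_attenuation",
    "inhomogeneous_attenuation",
    "increased_size",
    "lobulated_margin",
    "inhomogeneous_enhancement",
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the scoring rule.

    Parameters
    ----------
    low_hu_cutoff, high_hu_cutoff:
        Banding of mean nonenhanced HU into low (< ``low_hu_cutoff``),
        iso (``low_hu_cutoff``..``high_hu_cutoff`` inclusive) and high
        (> ``high_hu_cutoff``).  Defaults 100 and 180 HU.
    size_band:
        Inclusive (lower, upper) bounds in cm of a *normal* average AP
        diameter; below is decreased, above is increased.  Default (1, 2).
    count_threshold:
        ``k`` of the "k or more" rule, 1..5.  Default 3.
    comparison:
        Comparison used by HU cut-off *sweeps*: ``"le"`` labels a patient
        positive when HU <= cutoff (the convention of the cut-off tables),
        ``"lt"`` uses a strict inequality (the convention of the attenuation
        banding rule).  The two differ only for patients whose HU ties the
        cutoff exactly.
    """

    low_hu_cutoff: float = 100.0
    high_hu_cutoff: float = 180.0
    size_band: tuple[float, float] = (1.0, 2.0)
    count_threshold: int = 3
    comparison: str = "le"

    def __post_init__(self) -> None:
        if not self.low_hu_cutoff < self.high_hu_cutoff:
            raise ValueError("low_hu_cutoff must be below high_hu_cutoff")
        if not 1 <= self.count_threshold <= 5:
            raise ValueError("count_threshold must be in 1..5")
        if self.comparison not in ("lt", "le"):
            raise ValueError("comparison must be 'lt' or 'le'")
        if not self.size_band[0] < self.size_band[1]:
            raise ValueError("size_band must be an increasing pair")


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class AbnormalFlags:
    """The five abnormality flags of one patient."""

    low_attenuation: bool
    inhomogeneous_attenuation: bool
    increased_size: bool
    lobulated_margin: bool
    inhomogeneous_enhancement: bool

    @property
    def count(self) -> int:
        return sum(
            (
                self.low_attenuation,
                self.inhomogeneous_attenuation,
                self.increased_size,
                self.lobulated_margin,
                self.inhomogeneous_enhancement,
            )
        )

    def as_tuple(self) -> tuple[bool, ...]:
        return (
            self.low_attenuation,
            self.inhomogeneous_attenuation,
            self.increased_size,
            self.lobulated_margin,
            self.inhomogeneous_enhancement,
        )


def classify_attenuation_degree(hu: float, config: ClassifierConfig = DEFAULT_CONFIG) -> str:
    """Band a mean nonenhanced HU value into iso / low / high.

    The banding is inclusive at both cut points: exactly 100 HU is *iso*.
    """
    if not math.isfinite(hu):
        raise ValueError(f"attenuation HU must be finite, got {hu!r}")
    if hu < config.low_hu_cutoff:
        return "low"
    if hu > config.high_hu_cutoff:
        return "high"
    return "iso"


def classify_size_category(ap_diameter_cm: float, config: ClassifierConfig = DEFAULT_CONFIG) -> str:
    """Band an average AP diameter (cm) into normal / increased / decreased."""
    if not math.isfinite(ap_diameter_cm) or ap_diameter_cm <= 0:
        raise ValueError(f"AP diameter must be finite and positive, got {ap_diameter_cm!r}")
    lo, hi = config.size_band
    if ap_diameter_cm > hi:
        return "increased"
    if ap_diameter_cm < lo:
        return "decreased"
    return "normal"


def flag_abnormal(profile, config: ClassifierConfig = DEFAULT_CONFIG) -> AbnormalFlags:
    """Evaluate the five abnormality rules on a feature profile.

    ``profile`` is any object with the fields of
    :class:`dtdct.cohort.FeatureProfile`.  Heterogeneous patterns and
    decreased size raise no flag; the enhancement degree raises no flag.
    """
    return AbnormalFlags(
        low_attenuation=profile.attenuation_degree == "low",
        inhomogeneous_attenuation=profile.attenuation_pattern == "inhomogeneous",
        increased_size=profile.size_category == "increased",
        lobulated_margin=profile.margin == "lobulated",
        inhomogeneous_enhancement=profile.enhancement_pattern == "inhomogeneous",
    )


def classify_dtd(flags: AbnormalFlags, config: ClassifierConfig = DEFAULT_CONFIG) -> bool:
    """DTD-positive iff at least ``config.count_threshold`` flags are set."""
    return flags.count >= config.count_threshold


def enhancement_degree(profile) -> float:
    """Degree of parenchymal enhancement: enhanced minus nonenhanced mean HU."""
    value = profile.enhanced_hu - profile.attenuation_hu
    if not math.isfinite(value):
        raise ValueError("both HU values must be finite")
    return value


def cutoff_predicate(cutoff: float, comparison: str = "le") -> Callable[[float], bool]:
    """Return the positivity rule of one HU cut-off sweep candidate."""
    if comparison == "le":
        return lambda hu: hu <= cutoff
    if comparison == "lt":
        return lambda hu: hu < cutoff
    raise ValueError("comparison must be 'lt' or 'le'")
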