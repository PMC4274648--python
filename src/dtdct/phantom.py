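"""Synthetic neck-CT phantoms with ground-truth thyroid geometry.

A phantom is a pair of 3-D HU rasters (nonenhanced and contrast-enhanced
phase) holding two elliptical-cylinder thyroid lobes flanking an air-filled
trachea on a soft-tissue background, plus a label map of the ground-truth
geometry.  Margin lobulation is a radial sinusoidal perturbation of the lobe
boundary (``r -> r * (1 + A * sin(n * theta))``; the sine phase leaves the
anteroposterior and left-right poles unperturbed so the generating AP
diameter is preserved).  Parenchymal inhomogeneity is a smoothed Gaussian
random field, normalised to unit SD over each lobe, clipped at ±1.1 SD (so a
diffusely mottled gland can never trip the focal-lesion rule) and demeaned
over the default measurement ROI (so the generating mean HU remains the
ground truth the ROI reads out).  Heterogeneous patterns come from explicit
focal lesions (axial cylinders with an HU offset).

The measurement half mirrors the clinical reading: circular-ROI mean HU per
lobe averaged over lobes, anteroposterior diameter on the mid-lobe axial
slice banded at 1 and 2 cm, margin classified by convexity deficiency, and
attenuation/enhancement pattern classified by a focal-deviation rule
(heterogeneous), then a residual-SD rule (inhomogeneous vs homogeneous).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

from . import scoring
from .cohort import FeatureProfile

__all__ = [
    "FocalLesion",
    "PhantomParams",
    "PhantomVolume",
    "RoiSpec",
    "GeometryError",
    "RoiError",
    "generate_phantom",
    "measure_roi_hu",
    "average_lobe_hu",
    "default_rois",
    "extract_size_category",
    "extract_margin",
    "extract_pattern",
    "extract_profile",
    "phantom_params_from_profile",
    "save_phantom",
    "load_phantom",
]

logger = logging.getLogger(__name__)

PHASES = ("nonenhanced", "enhanced")
LABELS = {"background": 0, "left_lobe": 1, "right_lobe": 2, "trachea": 3}

#: Fraction of the lobe's minor semi-axis used as default ROI radius.
DEFAULT_ROI_FRACTION = 0.4

#: AP diameters (cm) used when rebuilding a phantom from a categorical size.
SIZE_TO_AP_CM = {"normal": 1.5, "increased": 2.4, "decreased": 0.8}

#: Inhomogeneity field amplitude (HU) emulating an inhomogeneous pattern.
INHOMOGENEOUS_AMPLITUDE = 40.0

#: Focal lesion emulating a heterogeneous pattern: HU offset and target
#: fraction of the lobe cross-section (kept above the 10% detection rule
#: with margin for ellipse clipping and voxelisation).
LESION_HU_OFFSET = -80.0
LESION_AREA_FRACTION = 0.14

_FIELD_CLIP_SD = 1.1


class GeometryError(ValueError):
    """Phantom geometry is infeasible (overlaps or leaves the grid)."""


class RoiError(ValueError):
    """ROI placement violates its contract."""


@dataclass(frozen=True)
class FocalLesion:
    """Axial cylindrical lesion inside one lobe.

    Offsets are in mm relative to the lobe centre (x: left-right,
    y: anteroposterior); the HU offset is per phase.
    """

    lobe: str
    dx_mm: float
    dy_mm: float
    radius_mm: float
    hu_offset: tuple[float, float]

    def __post_init__(self) -> None:
        if self.lobe not in ("left", "right"):
            raise ValueError("lobe must be 'left' or 'right'")
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")


@dataclass(frozen=True)
class PhantomParams:
    """Generating parameters of one phantom.

    HU pairs are (left lobe, right lobe); inhomogeneity amplitudes are
    (nonenhanced, enhanced) in HU.  ``lobulation_amplitude`` is a fraction of
    the local lobe radius and ``lobulation_count`` the number of boundary
    undulations.  Spacing default 0.5 x 0.5 mm in plane with 3 mm slices.
    """

    ap_diameter_cm: tuple[float, float] = (1.5, 1.5)
    hu_nonenhanced: tuple[float, float] = (114.3, 114.3)
    hu_enhanced: tuple[float, float] = (202.5, 202.5)
    noise_sd: float = 0.0
    inhom_amplitude: tuple[float, float] = (0.0, 0.0)
    inhom_scale_mm: float = 6.0
    lobulation_amplitude: float = 0.0
    lobulation_count: int = 0
    lesions: tuple[FocalLesion, ...] = ()
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 3.0)
    shape: tuple[int, int, int] = (128, 96, 12)
    lr_to_ap_ratio: float = 0.6
    trachea_radius_mm: float = 6.0
    lobe_gap_mm: float = 2.0
    background_hu: tuple[float, float] = (60.0, 90.0)
    trachea_hu: float = -1000.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.ap_diameter_cm):
            raise ValueError("AP diameters must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.inhom_scale_mm <= 0 or self.lr_to_ap_ratio <= 0:
            raise ValueError("spatial scales must be positive")
        if self.lobulation_amplitude < 0 or self.lobulation_count < 0:
            raise ValueError("lobulation parameters must be >= 0")


@dataclass(frozen=True)
class RoiSpec:
    """Circular axial ROI: centre in voxel coordinates, radius in mm."""

    center: tuple[int, int, int]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("ROI radius must be positive")


@dataclass(frozen=True)
class PhantomVolume:
    """HU rasters plus ground-truth masks and the generating parameters."""

    nonenhanced: np.ndarray
    enhanced: np.ndarray
    labels: np.ndarray
    params: PhantomParams
    seed: int

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return self.params.spacing_mm

    def phase(self, name: str) -> np.ndarray:
        if name not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        return self.nonenhanced if name == "nonenhanced" else self.enhanced

    def lobe_mask(self, side: str) -> np.ndarray:
        return self.labels == LABELS[f"{side}_lobe"]

    def mid_slice(self, side: str) -> int:
        zs = np.flatnonzero(self.lobe_mask(side).any(axis=(0, 1)))
        if zs.size == 0:
            raise GeometryError(f"{side} lobe mask is empty")
        return int(zs[len(zs) // 2])


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _lobe_geometry(params: PhantomParams, side: str):
    """Centre (mm, relative to grid centre) and semi-axes (mm) of one lobe."""
    idx = 0 if side == "left" else 1
    b = 10.0 * params.ap_diameter_cm[idx] / 2.0  # AP semi-axis, mm
    a = params.lr_to_ap_ratio * b  # LR semi-axis, mm
    sign = -1.0 if side == "left" else 1.0
    cx = sign * (params.trachea_radius_mm + params.lobe_gap_mm + a)
    # snap the centre onto a voxel centre so pole voxels digitise exactly
    sx = params.spacing_mm[0]
    cx = round(cx / sx) * sx
    return cx, 0.0, a, b


def _lobe_cross_section(params: PhantomParams, side: str) -> np.ndarray:
    nx, ny, _ = params.shape
    sx, sy, _ = params.spacing_mm
    cx, cy, a, b = _lobe_geometry(params, side)
    x = (np.arange(nx) - nx // 2) * sx - cx
    y = (np.arange(ny) - ny // 2) * sy - cy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    r = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_ellipse = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if params.lobulation_amplitude > 0 and params.lobulation_count > 0:
        r_ellipse = r_ellipse * (
            1.0
            + params.lobulation_amplitude
            * np.sin(params.lobulation_count * theta)
        )
    # relative tolerance keeps exact-boundary voxel centres inside
    return r <= r_ellipse * (1.0 + 1e-9)


def _trachea_cross_section(params: PhantomParams) -> np.ndarray:
    nx, ny, _ = params.shape
    sx, sy, _ = params.spacing_mm
    x = (np.arange(nx) - nx // 2) * sx
    y = (np.arange(ny) - ny // 2) * sy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    return np.hypot(xx, yy) <= params.trachea_radius_mm


def _lobe_z_range(params: PhantomParams) -> tuple[int, int]:
    nz = params.shape[2]
    if nz < 3:
        raise GeometryError("need at least 3 slices")
    return 1, nz - 1  # lobes span all but the first and last slice


def _roi_disk(volume_shape, spacing, roi: RoiSpec) -> tuple[np.ndarray, int]:
    """Boolean in-plane disk of one ROI and its slice index."""
    nx, ny, nz = volume_shape
    ix, iy, iz = roi.center
    if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
        raise RoiError(f"ROI centre {roi.center} outside the volume")
    sx, sy, _ = spacing
    x = (np.arange(nx) - ix) * sx
    y = (np.arange(ny) - iy) * sy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    return (np.hypot(xx, yy) <= roi.radius_mm), iz


def generate_phantom(params: PhantomParams, seed: int = 0) -> PhantomVolume:
    """Build one phantom; identical ``params`` and ``seed`` give identical rasters."""
    nx, ny, nz = params.shape
    sx, sy, sz = params.spacing_mm
    z0, z1 = _lobe_z_range(params)
    trachea2d = _trachea_cross_section(params)
    lobes2d = {side: _lobe_cross_section(params, side) for side in ("left", "right")}
    for side, mask in lobes2d.items():
        if not mask.any():
            raise GeometryError(f"{side} lobe does not intersect the grid")
        if (mask & trachea2d).any():
            raise GeometryError(f"{side} lobe overlaps the trachea")
        edge = np.zeros_like(mask)
        edge[[0, -1], :] = True
        edge[:, [0, -1]] = True
        if (mask & edge).any():
            raise GeometryError(f"{side} lobe touches the grid boundary")
    if (lobes2d["left"] & lobes2d["right"]).any():
        raise GeometryError("lobes overlap each other")

    labels = np.zeros(params.shape, dtype=np.uint8)
    labels[trachea2d, :] = LABELS["trachea"]
    for side in ("left", "right"):
        labels[lobes2d[side], z0:z1] = LABELS[f"{side}_lobe"]

    rng = np.random.default_rng(seed)
    volumes = {
        phase: np.full(params.shape, params.background_hu[p], dtype=np.float64)
        for p, phase in enumerate(PHASES)
    }
    for phase in PHASES:
        volumes[phase][labels == LABELS["trachea"]] = params.trachea_hu
    for s, side in enumerate(("left", "right")):
        mask = labels == LABELS[f"{side}_lobe"]
        volumes["nonenhanced"][mask] = params.hu_nonenhanced[s]
        volumes["enhanced"][mask] = params.hu_enhanced[s]

    # Structured inhomogeneity: one spatial field shared by both phases,
    # scaled per phase.  Normalised per lobe, clipped, and demeaned over the
    # default ROI so the ROI reads the generating HU exactly.
    if any(a > 0 for a in params.inhom_amplitude):
        raw = rng.standard_normal(params.shape)
        sigma = [params.inhom_scale_mm / s for s in params.spacing_mm]
        raw = ndimage.gaussian_filter(raw, sigma=sigma)
        rois = _default_rois_from_params(params)
        for side, roi in zip(("left", "right"), rois):
            mask = labels == LABELS[f"{side}_lobe"]
            values = raw[mask]
            sd = values.std()
            if sd == 0:
                continue
            # centre on the lobe median, then clip: the deviation from the
            # median stays below the focal-lesion rule for any amplitude
            # under ~45 HU, so diffuse mottling never reads as heterogeneous
            fieldv = np.clip(
                (values - np.median(values)) / sd, -_FIELD_CLIP_SD, _FIELD_CLIP_SD
            )
            disk, iz = _roi_disk(params.shape, params.spacing_mm, roi)
            roi_mask = np.zeros(params.shape, dtype=bool)
            roi_mask[:, :, iz] = disk
            field3d = np.zeros(params.shape)
            field3d[mask] = fieldv
            inroi = mask & roi_mask
            if inroi.any():
                field3d[mask] -= field3d[inroi].mean()
            for p, phase in enumerate(PHASES):
                if params.inhom_amplitude[p] > 0:
                    volumes[phase][mask] += params.inhom_amplitude[p] * field3d[mask]

    for lesion in params.lesions:
        mask = labels == LABELS[f"{lesion.lobe}_lobe"]
        cx, cy, _, _ = _lobe_geometry(params, lesion.lobe)
        x = (np.arange(nx) - nx // 2) * sx - (cx + lesion.dx_mm)
        y = (np.arange(ny) - ny // 2) * sy - (cy + lesion.dy_mm)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        disk = np.hypot(xx, yy) <= lesion.radius_mm
        lesion3d = np.zeros(params.shape, dtype=bool)
        lesion3d[disk, z0:z1] = True
        lesion3d &= mask
        for p, phase in enumerate(PHASES):
            volumes[phase][lesion3d] += lesion.hu_offset[p]

    if params.noise_sd > 0:
        for phase in PHASES:
            volumes[phase] += rng.normal(0.0, params.noise_sd, params.shape)

    return PhantomVolume(
        nonenhanced=volumes["nonenhanced"],
        enhanced=volumes["enhanced"],
        labels=labels,
        params=params,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------


def _default_rois_from_params(params: PhantomParams) -> tuple[RoiSpec, RoiSpec]:
    nx, ny, nz = params.shape
    sx, sy, _ = params.spacing_mm
    z0, z1 = _lobe_z_range(params)
    iz = (z0 + z1) // 2
    rois = []
    for side in ("left", "right"):
        cx, cy, a, _ = _lobe_geometry(params, side)
        ix = int(round(cx / sx)) + nx // 2
        iy = int(round(cy / sy)) + ny // 2
        rois.append(RoiSpec(center=(ix, iy, iz), radius_mm=DEFAULT_ROI_FRACTION * a))
    return tuple(rois)


def default_rois(volume: PhantomVolume) -> tuple[RoiSpec, RoiSpec]:
    """Default per-lobe ROIs: a disk of radius 40% of the minor semi-axis at
    the lobe centre on the mid-lobe slice, clear of partial-volume edges."""
    return _default_rois_from_params(volume.params)


def measure_roi_hu(volume: PhantomVolume, roi: RoiSpec, phase: str = "nonenhanced") -> float:
    """Arithmetic mean HU over one circular axial ROI.

    The ROI must lie strictly inside a single lobe mask: voxels outside the
    lobe, or touching the lobe boundary, violate the contract and raise
    :class:`RoiError`.
    """
    disk, iz = _roi_disk(volume.labels.shape, volume.spacing_mm, roi)
    if not disk.any():
        raise RoiError("ROI contains no voxels")
    label_slice = volume.labels[:, :, iz]
    covered = np.unique(label_slice[disk])
    if covered.size != 1 or covered[0] not in (LABELS["left_lobe"], LABELS["right_lobe"]):
        raise RoiError("ROI is not contained in a single thyroid lobe")
    lobe = label_slice == covered[0]
    interior = ndimage.binary_erosion(lobe)
    if not np.all(interior[disk]):
        raise RoiError("ROI touches the lobe boundary")
    return float(volume.phase(phase)[:, :, iz][disk].mean())


def average_lobe_hu(
    volume: PhantomVolume,
    left_roi: RoiSpec,
    right_roi: RoiSpec,
    phase: str = "nonenhanced",
) -> float:
    """Mean of the two per-lobe ROI means (the reading-room convention)."""
    return 0.5 * (
        measure_roi_hu(volume, left_roi, phase) + measure_roi_hu(volume, right_roi, phase)
    )


def _mid_slice_mask(volume: PhantomVolume, side: str) -> np.ndarray:
    mask = volume.lobe_mask(side)[:, :, volume.mid_slice(side)]
    if not mask.any():
        raise GeometryError(f"{side} lobe mid-slice mask is empty")
    return mask


def extract_size_category(
    volume: PhantomVolume, config: scoring.ClassifierConfig = scoring.DEFAULT_CONFIG
) -> tuple[str, float]:
    """Average AP diameter over lobes (cm), banded at the configured limits.

    The AP extent is measured on the mid-lobe axial slice along the
    anteroposterior axis, as the distance between extreme voxel centres.
    """
    diameters = []
    for side in ("left", "right"):
        mask = _mid_slice_mask(volume, side)
        ys = np.flatnonzero(mask.any(axis=0))
        extent_mm = (ys[-1] - ys[0]) * volume.spacing_mm[1]
        diameters.append(extent_mm / 10.0)
    ap_cm = float(np.mean(diameters))
    return scoring.classify_size_category(ap_cm, config), ap_cm


def extract_margin(
    volume: PhantomVolume, threshold: float = 0.02
) -> tuple[str, float]:
    """Smooth vs lobulated margin via convexity deficiency.

    Deficiency is 1 - area(mask) / area(convex hull) on the mid-lobe slice;
    the gland is lobulated when either lobe exceeds ``threshold``.
    """
    deficiency = 0.0
    for side in ("left", "right"):
        mask = _mid_slice_mask(volume, side)
        # offset_coordinates=False: a digitised convex shape equals its own
        # hull, so smooth lobes sit at deficiency 0 exactly
        hull = convex_hull_image(mask, offset_coordinates=False)
        deficiency = max(deficiency, 1.0 - mask.sum() / hull.sum())
    category = "lobulated" if deficiency > threshold else "smooth"
    return category, float(deficiency)


def extract_pattern(
    volume: PhantomVolume,
    phase: str = "nonenhanced",
    focal_hu_offset: float = 50.0,
    focal_area_fraction: float = 0.10,
    sd_threshold: float = 15.0,
) -> str:
    """Classify the parenchymal pattern of one phase.

    Heterogeneous: some connected region of at least ``focal_area_fraction``
    of a lobe deviates by at least ``focal_hu_offset`` HU from the lobe
    median.  Otherwise inhomogeneous when the within-lobe SD, after removing
    the configured sensor noise in quadrature, exceeds ``sd_threshold``;
    otherwise homogeneous.
    """
    hu = volume.phase(phase)
    noise_var = volume.params.noise_sd**2
    worst = "homogeneous"
    for side in ("left", "right"):
        mask = volume.lobe_mask(side)
        values = hu[mask]
        median = np.median(values)
        deviant = np.zeros(volume.labels.shape, dtype=bool)
        deviant[mask] = np.abs(hu[mask] - median) >= focal_hu_offset
        if deviant.any():
            labelled, n = ndimage.label(deviant)
            sizes = ndimage.sum_labels(deviant, labelled, index=np.arange(1, n + 1))
            if sizes.size and sizes.max() >= focal_area_fraction * mask.sum():
                return "heterogeneous"
        residual_var = max(float(values.var()) - noise_var, 0.0)
        if math.sqrt(residual_var) > sd_threshold:
            worst = "inhomogeneous"
    return worst


def extract_profile(
    volume: PhantomVolume, config: scoring.ClassifierConfig = scoring.DEFAULT_CONFIG
) -> FeatureProfile:
    """Run the full measurement protocol on one phantom."""
    left_roi, right_roi = default_rois(volume)
    hu_non = average_lobe_hu(volume, left_roi, right_roi, "nonenhanced")
    hu_enh = average_lobe_hu(volume, left_roi, right_roi, "enhanced")
    size_category, _ = extract_size_category(volume, config)
    margin, _ = extract_margin(volume)
    return FeatureProfile(
        attenuation_hu=hu_non,
        enhanced_hu=hu_enh,
        attenuation_degree=scoring.classify_attenuation_degree(hu_non, config),
        attenuation_pattern=extract_pattern(volume, "nonenhanced"),
        size_category=size_category,
        margin=margin,
        enhancement_pattern=extract_pattern(volume, "enhanced"),
    )


def phantom_params_from_profile(
    profile: FeatureProfile,
    noise_sd: float = 0.0,
    **overrides,
) -> PhantomParams:
    """Phantom parameters that realise a tabular feature profile.

    The mapping is the inverse of the measurement protocol: categorical
    sizes map to fixed AP diameters, a lobulated margin to a 6-undulation
    20% boundary perturbation, inhomogeneous patterns to a 40 HU mottling
    field, and heterogeneous patterns to a focal low-density lesion placed
    posteriorly, clear of the measurement ROI.
    """
    ap_cm = SIZE_TO_AP_CM[profile.size_category]
    b = 10.0 * ap_cm / 2.0
    ratio = overrides.get("lr_to_ap_ratio", 0.6)
    a = ratio * b
    lesions: list[FocalLesion] = []
    for p, pattern in enumerate((profile.attenuation_pattern, profile.enhancement_pattern)):
        if pattern == "heterogeneous":
            rc = math.sqrt(LESION_AREA_FRACTION * a * b)
            lo = rc + DEFAULT_ROI_FRACTION * a + 0.3
            hi = b - rc
            if lo > hi:
                raise GeometryError("no room for a focal lesion clear of the ROI")
            offset = (LESION_HU_OFFSET, 0.0) if p == 0 else (0.0, LESION_HU_OFFSET)
            for side in ("left", "right"):
                lesions.append(
                    FocalLesion(
                        lobe=side,
                        dx_mm=0.0,
                        dy_mm=-(lo + hi) / 2.0,
                        radius_mm=rc,
                        hu_offset=offset,
                    )
                )
    return PhantomParams(
        ap_diameter_cm=(ap_cm, ap_cm),
        hu_nonenhanced=(profile.attenuation_hu, profile.attenuation_hu),
        hu_enhanced=(profile.enhanced_hu, profile.enhanced_hu),
        noise_sd=noise_sd,
        inhom_amplitude=(
            INHOMOGENEOUS_AMPLITUDE if profile.attenuation_pattern == "inhomogeneous" else 0.0,
            INHOMOGENEOUS_AMPLITUDE if profile.enhancement_pattern == "inhomogeneous" else 0.0,
        ),
        lobulation_amplitude=0.2 if profile.margin == "lobulated" else 0.0,
        lobulation_count=6 if profile.margin == "lobulated" else 0,
        lesions=tuple(lesions),
        **overrides,
    )


def phantoms_for_cohort(
    cohort, noise_sd: float = 0.0, seed: int = 0, **overrides
) -> list[PhantomVolume]:
    """Generate one phantom per patient of a tabular cohort.

    Per-patient seeds are spawned from ``seed`` so the batch is reproducible
    and patients are independent.
    """
    seeds = np.random.SeedSequence(seed).generate_state(max(len(cohort), 1))
    volumes = []
    for record, s in zip(cohort, seeds):
        params = phantom_params_from_profile(record.profile, noise_sd=noise_sd, **overrides)
        volumes.append(generate_phantom(params, seed=int(s % (2**31))))
    return volumes


def extract_cohort(cohort, volumes, config: scoring.ClassifierConfig = scoring.DEFAULT_CONFIG):
    """Measure a batch of phantoms, keeping ids and histopathology labels."""
    from .cohort import Cohort, PatientRecord

    if len(cohort) != len(volumes):
        raise ValueError("cohort and phantom batch must have equal length")
    records = [
        PatientRecord(r.patient_id, r.histopath_class, extract_profile(v, config))
        for r, v in zip(cohort, volumes)
    ]
    return Cohort(records)


# ---------------------------------------------------------------------------
# NIfTI input/output
# ---------------------------------------------------------------------------


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_phantom(volume: PhantomVolume, directory, stem: str) -> dict[str, str]:
    """Write a phantom as NIfTI (HU as int16, masks as a uint8 label map)
    plus a JSON sidecar holding the generating parameters and seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = _affine(volume.spacing_mm)
    paths = {}
    for phase in PHASES:
        img = nib.Nifti1Image(
            np.round(volume.phase(phase)).astype(np.int16), affine
        )
        path = directory / f"{stem}_{phase}.nii.gz"
        nib.save(img, path)
        paths[phase] = str(path)
    labels_path = directory / f"{stem}_labels.nii.gz"
    nib.save(nib.Nifti1Image(volume.labels, affine), labels_path)
    paths["labels"] = str(labels_path)
    sidecar = directory / f"{stem}_params.json"
    payload = dataclasses.asdict(volume.params)
    payload["lesions"] = [dataclasses.asdict(l) for l in volume.params.lesions]
    sidecar.write_text(json.dumps({"params": payload, "seed": volume.seed}, indent=2))
    paths["params"] = str(sidecar)
    return paths


def load_phantom(directory, stem: str) -> PhantomVolume:
    """Read back a phantom written by :func:`save_phantom`.

    HU rasters are int16 on disk, so sub-HU detail is quantised.
    """
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}_params.json").read_text())
    raw = meta["params"]
    raw["lesions"] = tuple(
        FocalLesion(
            lobe=l["lobe"],
            dx_mm=l["dx_mm"],
            dy_mm=l["dy_mm"],
            radius_mm=l["radius_mm"],
            hu_offset=tuple(l["hu_offset"]),
        )
        for l in raw["lesions"]
    )
    for key in ("ap_diameter_cm", "hu_nonenhanced", "hu_enhanced", "inhom_amplitude",
                "spacing_mm", "shape", "background_hu"):
        raw[key] = tuple(raw[key])
    params = PhantomParams(**raw)
    arrays = {}
    for phase in PHASES:
        arrays[phase] = np.asarray(
            nib.load(directory / f"{stem}_{phase}.nii.gz").dataobj, dtype=np.float64
        )
    labels = np.asarray(nib.load(directory / f"{stem}_labels.nii.gz").dataobj, dtype=np.uint8)
    return PhantomVolume(
        nonenhanced=arrays["nonenhanced"],
        enhanced=arrays["enhanced"],
        labels=labels,
        params=params,
        seed=meta["seed"],
    )
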