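"""Phantom generation and the CT measurement protocol: exact recovery on
noiseless phantoms, statistical behaviour under noise, and IO round trips."""

import math

import numpy as np
import pytest

from dtdct import (
    FeatureProfile,
    FocalLesion,
    PhantomParams,
    RoiSpec,
    average_lobe_hu,
    default_rois,
    extract_margin,
    extract_pattern,
    extract_profile,
    extract_size_category,
    generate_phantom,
    load_phantom,
    measure_roi_hu,
    phantom_params_from_profile,
    save_phantom,
)
from dtdct.phantom import GeometryError, RoiError


@pytest.fixture(scope="module")
def flat_phantom():
    return generate_phantom(PhantomParams(), seed=0)


class TestGeneration:
    def test_constant_lobes_noiseless(self, flat_phantom):
        for side in ("left", "right"):
            mask = flat_phantom.lobe_mask(side)
            assert np.all(flat_phantom.nonenhanced[mask] == 114.3)
            assert np.all(flat_phantom.enhanced[mask] == 202.5)

    def test_trachea_is_air(self, flat_phantom):
        assert np.all(flat_phantom.nonenhanced[flat_phantom.labels == 3] == -1000.0)

    def test_masks_disjoint_and_shapes_match(self, flat_phantom):
        assert flat_phantom.labels.shape == flat_phantom.nonenhanced.shape
        # a label map is disjoint by construction; check lobes don't touch trachea
        left = flat_phantom.lobe_mask("left")
        right = flat_phantom.lobe_mask("right")
        assert not (left & right).any()

    def test_seeded_determinism(self):
        params = PhantomParams(noise_sd=12.0, inhom_amplitude=(25.0, 25.0))
        a = generate_phantom(params, seed=5)
        b = generate_phantom(params, seed=5)
        c = generate_phantom(params, seed=6)
        assert np.array_equal(a.nonenhanced, b.nonenhanced)
        assert np.array_equal(a.enhanced, b.enhanced)
        assert not np.array_equal(a.nonenhanced, c.nonenhanced)

    def test_overlapping_geometry_rejected(self):
        with pytest.raises(GeometryError):
            generate_phantom(PhantomParams(lobe_gap_mm=-8.0), seed=0)

    def test_oversized_lobe_rejected(self):
        with pytest.raises(GeometryError):
            generate_phantom(PhantomParams(ap_diameter_cm=(6.0, 6.0)), seed=0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            PhantomParams(ap_diameter_cm=(0.0, 1.5))
        with pytest.raises(ValueError):
            PhantomParams(noise_sd=-1.0)


class TestRoiMeasurement:
    def test_constant_lobe_mean_exact(self, flat_phantom):
        left, right = default_rois(flat_phantom)
        assert measure_roi_hu(flat_phantom, left) == pytest.approx(114.3)
        assert measure_roi_hu(flat_phantom, right, "enhanced") == pytest.approx(202.5)

    def test_mean_invariant_to_radius_on_constant_lobe(self, flat_phantom):
        left, _ = default_rois(flat_phantom)
        for radius in (0.6, 1.0, 1.5):
            roi = RoiSpec(center=left.center, radius_mm=radius)
            assert measure_roi_hu(flat_phantom, roi) == pytest.approx(114.3)

    def test_noisy_mean_obeys_clt(self):
        """ROI of >= 500 voxels on a noisy lobe: the sample mean sits within
        3 * sd/sqrt(n) of the generating HU."""
        params = PhantomParams(
            ap_diameter_cm=(4.0, 4.0), hu_nonenhanced=(100.0, 100.0),
            noise_sd=10.0, shape=(192, 112, 12),
        )
        volume = generate_phantom(params, seed=4)
        left, _ = default_rois(volume)
        roi = RoiSpec(center=left.center, radius_mm=6.5)
        n_voxels = math.pi * 6.5**2 / 0.25
        assert n_voxels >= 500
        assert abs(measure_roi_hu(volume, roi) - 100.0) < 3 * 10.0 / math.sqrt(n_voxels)

    def test_roi_outside_lobe_rejected(self, flat_phantom):
        centre = RoiSpec(center=(64, 48, 6), radius_mm=2.0)  # inside the trachea
        with pytest.raises(RoiError):
            measure_roi_hu(flat_phantom, centre)

    def test_roi_touching_boundary_rejected(self, flat_phantom):
        left, _ = default_rois(flat_phantom)
        big = RoiSpec(center=left.center, radius_mm=20.0)
        with pytest.raises(RoiError):
            measure_roi_hu(flat_phantom, big)

    def test_average_lobe_hu_midpoint(self):
        params = PhantomParams(hu_nonenhanced=(90.0, 110.0))
        volume = generate_phantom(params, seed=0)
        assert average_lobe_hu(volume, *default_rois(volume)) == pytest.approx(100.0)

    def test_average_lobe_hu_dtd_mean(self):
        params = PhantomParams(hu_nonenhanced=(94.5, 94.5))
        volume = generate_phantom(params, seed=0)
        assert average_lobe_hu(volume, *default_rois(volume)) == pytest.approx(94.5)


class TestSizeExtraction:
    @pytest.mark.parametrize(
        "ap, category", [(1.5, "normal"), (2.4, "increased"), (0.8, "decreased")]
    )
    def test_generated_diameter_recovered(self, ap, category):
        volume = generate_phantom(PhantomParams(ap_diameter_cm=(ap, ap)), seed=0)
        observed_cat, observed_cm = extract_size_category(volume)
        assert observed_cat == category
        assert abs(observed_cm - ap) <= 0.025  # half an in-plane voxel, in cm

    def test_empty_mask_rejected(self, flat_phantom):
        broken = PhantomVolumeNoLobes(flat_phantom)
        with pytest.raises(GeometryError):
            extract_size_category(broken)


class PhantomVolumeNoLobes:
    """A stand-in view of a phantom whose lobe masks are empty."""

    def __init__(self, volume):
        self._volume = volume
        self.labels = np.zeros_like(volume.labels)
        self.params = volume.params
        self.spacing_mm = volume.spacing_mm
        self.nonenhanced = volume.nonenhanced
        self.enhanced = volume.enhanced

    def lobe_mask(self, side):
        return self.labels.astype(bool)

    def mid_slice(self, side):
        return self._volume.mid_slice(side)


class TestMarginExtraction:
    def test_smooth_ellipse_has_zero_deficiency(self, flat_phantom):
        category, deficiency = extract_margin(flat_phantom)
        assert category == "smooth"
        assert deficiency == 0.0

    @pytest.mark.parametrize(
        "undulations, amplitude", [(3, 0.2), (4, 0.15), (6, 0.15), (8, 0.15)]
    )
    def test_strong_lobulation_detected(self, undulations, amplitude):
        """Calibrated decision boundary: at the default 2% deficiency
        threshold, 4+ undulations separate at amplitude 0.15; the shallower
        3-undulation contour needs 0.2."""
        params = PhantomParams(
            lobulation_amplitude=amplitude, lobulation_count=undulations
        )
        category, deficiency = extract_margin(generate_phantom(params, seed=0))
        assert category == "lobulated"
        assert deficiency > 0.02

    def test_degenerate_threshold_always_smooth(self):
        params = PhantomParams(lobulation_amplitude=0.3, lobulation_count=6)
        category, _ = extract_margin(generate_phantom(params, seed=0), threshold=1.0)
        assert category == "smooth"

    def test_deficiency_monotone_in_amplitude(self):
        values = []
        for amp in (0.0, 0.1, 0.15, 0.2, 0.3):
            params = PhantomParams(lobulation_amplitude=amp, lobulation_count=6)
            values.append(extract_margin(generate_phantom(params, seed=0))[1])
        assert values == sorted(values)


class TestPatternExtraction:
    def test_flat_lobe_homogeneous(self, flat_phantom):
        assert extract_pattern(flat_phantom) == "homogeneous"
        assert extract_pattern(flat_phantom, "enhanced") == "homogeneous"

    def test_mottling_field_inhomogeneous(self):
        params = PhantomParams(inhom_amplitude=(40.0, 0.0))
        volume = generate_phantom(params, seed=3)
        assert extract_pattern(volume, "nonenhanced") == "inhomogeneous"
        assert extract_pattern(volume, "enhanced") == "homogeneous"

    def test_classification_monotone_in_amplitude(self):
        """Raising the mottling amplitude never flips inhomogeneous back to
        homogeneous (fixed seed)."""
        ranks = []
        for amp in (0.0, 10.0, 20.0, 40.0, 45.0):
            volume = generate_phantom(PhantomParams(inhom_amplitude=(amp, amp)), seed=3)
            ranks.append(extract_pattern(volume) == "inhomogeneous")
        assert ranks == sorted(ranks)

    def test_sensor_noise_alone_reads_homogeneous(self):
        """Pure voxel noise is removed in quadrature and must not mimic a
        structured inhomogeneity."""
        volume = generate_phantom(PhantomParams(noise_sd=20.0), seed=8)
        assert extract_pattern(volume) == "homogeneous"

    def test_focal_lesion_heterogeneous_by_region_rule(self):
        lesion = [
            FocalLesion(lobe=side, dx_mm=0.0, dy_mm=-4.0, radius_mm=2.2,
                        hu_offset=(-80.0, 0.0))
            for side in ("left", "right")
        ]
        volume = generate_phantom(PhantomParams(lesions=tuple(lesion)), seed=0)
        assert extract_pattern(volume, "nonenhanced") == "heterogeneous"
        # brute-force check of the focal rule on the raster itself
        mask = volume.lobe_mask("left")
        values = volume.nonenhanced[mask]
        deviant = np.abs(values - np.median(values)) >= 50.0
        assert deviant.sum() >= 0.10 * mask.sum()


class TestProfileRecovery:
    ALL_NORMAL = FeatureProfile(114.3, 202.5, "iso", "homogeneous", "normal",
                                "smooth", "homogeneous")
    ALL_ABNORMAL = FeatureProfile(94.5, 187.6, "low", "inhomogeneous", "increased",
                                  "lobulated", "inhomogeneous")

    @pytest.mark.parametrize("profile", [ALL_NORMAL, ALL_ABNORMAL],
                             ids=["all-normal", "all-abnormal"])
    def test_noiseless_exact_recovery(self, profile):
        """Every extracted feature equals its generating ground truth."""
        volume = generate_phantom(phantom_params_from_profile(profile), seed=11)
        recovered = extract_profile(volume)
        assert recovered.attenuation_hu == pytest.approx(profile.attenuation_hu)
        assert recovered.enhanced_hu == pytest.approx(profile.enhanced_hu)
        for feature in ("attenuation_degree", "attenuation_pattern",
                        "size_category", "margin", "enhancement_pattern"):
            assert getattr(recovered, feature) == getattr(profile, feature)

    @pytest.mark.parametrize("size", ["normal", "increased", "decreased"])
    def test_heterogeneous_recovery_across_sizes(self, size):
        profile = FeatureProfile(105.0, 195.0, "iso", "heterogeneous", size,
                                 "smooth", "homogeneous")
        volume = generate_phantom(phantom_params_from_profile(profile), seed=2)
        recovered = extract_profile(volume)
        assert recovered.attenuation_pattern == "heterogeneous"
        assert recovered.size_category == size
        assert recovered.attenuation_hu == pytest.approx(105.0)


def test_nifti_round_trip(tmp_path):
    profile = TestProfileRecovery.ALL_ABNORMAL
    volume = generate_phantom(phantom_params_from_profile(profile, noise_sd=6.0), seed=9)
    save_phantom(volume, tmp_path, "case")
    loaded = load_phantom(tmp_path, "case")
    assert loaded.params == volume.params
    assert loaded.seed == volume.seed
    assert np.array_equal(loaded.labels, volume.labels)
    # HU rasters are int16 on disk: quantised to within half a unit
    assert np.max(np.abs(loaded.nonenhanced - volume.nonenhanced)) <= 0.5
    assert [f.name for f in sorted(tmp_path.iterdir())] == [
        "case_enhanced.nii.gz", "case_labels.nii.gz",
        "case_nonenhanced.nii.gz", "case_params.json",
    ]
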