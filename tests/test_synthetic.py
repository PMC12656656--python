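"""Synthetic image and dataset generator: geometry, noise law, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctdoseiq.errors import DomainError, GeometryError
from ctdoseiq.roi import Roi, measure_brain, measure_roi
from ctdoseiq.synthetic import (
    AcquisitionParams,
    BrainSpec,
    BrainStructure,
    FacilityConfig,
    NoiseModel,
    PhantomSpec,
    TABLE1_SAMPLE_SIZES,
    default_facilities,
    generate_brain_image,
    generate_phantom_image,
    generate_study_dataset,
    records_to_frame,
    simulate_aec_dose,
)

NOISELESS = NoiseModel(amplitude_a=0.0)


def chi2_sd_interval(sigma: float, n: int, conf: float = 0.99) -> tuple[float, float]:
    """Two-sided interval for a sample SD of n iid N(0, sigma^2) draws."""
    alpha = 1 - conf
    lo = sigma * math.sqrt(stats.chi2.ppf(alpha / 2, n - 1) / (n - 1))
    hi = sigma * math.sqrt(stats.chi2.ppf(1 - alpha / 2, n - 1) / (n - 1))
    return lo, hi


class TestPhantomImage:
    def test_noiseless_background_is_exact(self):
        spec = PhantomSpec()
        img = generate_phantom_image(spec, AcquisitionParams(40, seed=0), NOISELESS)
        bg = measure_roi(img, Roi(spec.background_center_mm(), "circle", 10.0))
        assert bg.mean_hu == 60.0
        assert bg.sd_hu == 0.0

    def test_one_percent_rod_is_plus_ten_hu(self):
        # 1% contrast on a 60 HU background with the 1% = 10 HU convention
        spec = PhantomSpec()
        _, diam, x, y = spec.measurement_rod(0.010)
        img = generate_phantom_image(spec, AcquisitionParams(40, seed=0), NOISELESS)
        rod = measure_roi(img, Roi((x, y), "circle", min(10.0, diam)))
        assert rod.mean_hu == 70.0

    def test_empirical_sd_matches_noise_law(self):
        # A=31.62, B=0.5 at 40 mGy predicts sigma = 5.0 HU; the sample SD of
        # a 10,000-pixel rod-free region must land in the 99% chi-square band
        spec = PhantomSpec()
        img = generate_phantom_image(
            spec, AcquisitionParams(40, seed=123), NoiseModel(31.62, 0.5)
        )
        center = measure_roi(img, Roi((0.0, 0.0), "square", side_px=100))
        lo, hi = chi2_sd_interval(5.0, center.n_pixels)
        assert lo < center.sd_hu < hi

    def test_dose_halving_scales_sd_by_sqrt2(self):
        spec = PhantomSpec()
        noise = NoiseModel(31.62, 0.5)
        sds = {}
        for dose in (20.0, 40.0):
            reps = []
            for seed in range(3):
                img = generate_phantom_image(
                    spec, AcquisitionParams(dose, seed=seed), noise
                )
                reps.append(measure_roi(img, Roi((0.0, 0.0), "square", side_px=100)).sd_hu)
            sds[dose] = np.mean(reps)
        assert sds[40.0] / sds[20.0] == pytest.approx(1 / math.sqrt(2), rel=0.03)

    def test_sd_monotone_over_dose_ladder(self):
        spec = PhantomSpec()
        noise = NoiseModel(31.62, 0.5)
        means = []
        for dose in (10.0, 20.0, 40.0, 60.0, 80.0):
            reps = [
                measure_roi(
                    generate_phantom_image(
                        spec, AcquisitionParams(dose, seed=s), noise
                    ),
                    Roi((0.0, 0.0), "square", side_px=100),
                ).sd_hu
                for s in range(3)
            ]
            means.append(np.mean(reps))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_rod_areas_match_analytic_disc_area(self):
        # all rods of one contrast level share one HU value, so compare the
        # rasterised area of each group against the analytic sum of pi*r^2,
        # allowing a one-pixel-wide perimeter band per rod
        spec = PhantomSpec()
        img = generate_phantom_image(spec, AcquisitionParams(40, seed=0), NOISELESS)
        px_area = spec.pixel_spacing_mm**2
        for level in spec.contrast_levels:
            hu = spec.background_hu + spec.contrast_hu(level)
            count = int(np.sum(img.pixels == hu))
            diams = [
                d for l2, d, _, _ in spec.rod_positions() if math.isclose(l2, level)
            ]
            expected = sum(math.pi * (d / 2.0) ** 2 for d in diams)
            band = sum(math.pi * d * spec.pixel_spacing_mm for d in diams)
            assert abs(count * px_area - expected) <= band

    def test_determinism_and_seed_sensitivity(self, small_phantom_spec):
        noise = NoiseModel(31.62, 0.5)
        a = generate_phantom_image(small_phantom_spec, AcquisitionParams(40, seed=9), noise)
        b = generate_phantom_image(small_phantom_spec, AcquisitionParams(40, seed=9), noise)
        c = generate_phantom_image(small_phantom_spec, AcquisitionParams(40, seed=10), noise)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_geometry_and_domain_validation(self):
        with pytest.raises(GeometryError):
            PhantomSpec(matrix_size=128, pixel_spacing_mm=1.0)  # 128 mm FOV < module
        with pytest.raises(DomainError):
            AcquisitionParams(ctdivol=-1.0, seed=0)
        with pytest.raises(DomainError):
            AcquisitionParams(ctdivol=5.0, seed=0)  # below the 10 mGy floor
        AcquisitionParams(ctdivol=5.0, seed=0, min_ctdivol=0.0)  # floor relaxed
        with pytest.raises(DomainError):
            PhantomSpec(rod_diameters_mm=(1.0, 5.0))

    def test_correlated_noise_keeps_target_sd(self):
        spec = PhantomSpec()
        noise = NoiseModel(31.62, 0.5, correlation_fwhm_mm=2.0)
        img = generate_phantom_image(spec, AcquisitionParams(40, seed=3), noise)
        sd = measure_roi(img, Roi((0.0, 0.0), "square", side_px=100)).sd_hu
        assert sd == pytest.approx(5.0, rel=0.10)


class TestBrainImage:
    def test_noiseless_tissue_means_exact(self, small_brain_spec):
        img = generate_brain_image(
            small_brain_spec, AcquisitionParams(25, seed=0), NOISELESS
        )
        gm = [
            measure_roi(img, Roi(c, "square", side_px=10, label="GM")).mean_hu
            for c in small_brain_spec.roi_centers("GM")
        ]
        wm = [
            measure_roi(img, Roi(c, "square", side_px=10, label="WM")).mean_hu
            for c in small_brain_spec.roi_centers("WM")
        ]
        assert gm == [38.0] * len(gm)
        assert wm == [30.0] * len(wm)

    def test_combined_clinical_sd_is_sqrt2_single_roi_sd(self):
        # equal iid noise in GM and WM forces combined SD = sqrt(2) * sigma
        spec = BrainSpec()
        noise = NoiseModel(25.0, 0.5)  # sigma = 5 at 25 mGy
        vals = [
            measure_brain(
                generate_brain_image(spec, AcquisitionParams(25, seed=s), noise), spec
            ).combined_sd
            for s in range(8)
        ]
        assert np.mean(vals) == pytest.approx(math.sqrt(2) * 5.0, rel=0.07)

    def test_parenchymal_rois_never_touch_skull(self, small_brain_spec):
        img = generate_brain_image(
            small_brain_spec, AcquisitionParams(25, seed=0), NOISELESS
        )
        from ctdoseiq.roi import roi_mask

        for label in ("GM", "WM"):
            for center in small_brain_spec.roi_centers(label):
                mask = roi_mask(img, Roi(center, "square", side_px=10))
                assert img.pixels[mask].max() <= 100.0

    def test_tissue_contrast_validation(self):
        with pytest.raises(DomainError):
            BrainSpec(gray_matter_hu=30.0, white_matter_hu=30.0)
        with pytest.raises(DomainError):
            BrainSpec(gray_matter_hu=55.0, gm_plausible_band_hu=(30.0, 40.0))
        with pytest.raises(GeometryError):
            BrainSpec(structures=(
                BrainStructure("GM", (0.0, 0.0), (6.0, 6.0)),
                BrainStructure("GM", (5.0, 0.0), (6.0, 6.0)),
            ))


class TestAec:
    def test_closed_form_inversion(self):
        dose = simulate_aec_dose(NoiseModel(31.62, 0.5), 5.0)
        assert dose == pytest.approx(39.99, abs=0.01)
        # realised noise at the AEC dose equals the target by construction
        assert NoiseModel(31.62, 0.5).sd_at(dose) == pytest.approx(5.0, rel=1e-12)

    def test_unit_dose_identities(self):
        assert simulate_aec_dose(NoiseModel(7.5, 0.3), 7.5) == pytest.approx(1.0)
        assert simulate_aec_dose(NoiseModel(10.0, 0.5), 10.0) == pytest.approx(1.0)

    def test_flat_noise_has_no_aec_solution(self):
        with pytest.raises(DomainError):
            simulate_aec_dose(NoiseModel(8.0, exponent_b=0.0), 5.0)


class TestStudyDataset:
    def test_emulated_study_has_90_exams(self, small_brain_spec):
        facs = default_facilities()
        assert tuple(f.n_exams for f in facs) == TABLE1_SAMPLE_SIZES
        records = generate_study_dataset(facs, seed=11, brain_spec=small_brain_spec)
        assert len(records) == 90
        assert len({r.facility_id for r in records}) == 8

    def test_zero_jitter_doses_are_identical(self, small_brain_spec):
        fac = FacilityConfig(
            facility_id="Z", manufacturer="GE",
            noise_model=NoiseModel(20.0, 0.5), target_sd=4.0,
            n_exams=3, dose_jitter=0.0,
        )
        records = generate_study_dataset([fac], seed=5, brain_spec=small_brain_spec)
        doses = {r.ctdivol_mgy for r in records}
        assert len(doses) == 1
        assert doses.pop() == pytest.approx(simulate_aec_dose(fac.noise_model, 4.0))

    def test_same_seed_gives_identical_tables(self, two_facilities, small_brain_spec):
        a = records_to_frame(
            generate_study_dataset(two_facilities, seed=3, brain_spec=small_brain_spec)
        )
        b = records_to_frame(
            generate_study_dataset(two_facilities, seed=3, brain_spec=small_brain_spec)
        )
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_exclusion_fraction_drops_records(self, two_facilities, small_brain_spec):
        full = generate_study_dataset(two_facilities, seed=3, brain_spec=small_brain_spec)
        dropped = generate_study_dataset(
            two_facilities, seed=3, brain_spec=small_brain_spec,
            exclusion_fraction=0.5,
        )
        assert 0 < len(dropped) < len(full)
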