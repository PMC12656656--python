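import numpy as np
import pytest

from ctdoseiq.image import ImageSlice
from ctdoseiq.synthetic import BrainSpec, FacilityConfig, NoiseModel, PhantomSpec


@pytest.fixture
def small_phantom_spec() -> PhantomSpec:
    """Full 15 cm module on a coarse 192x192 @ 1 mm grid (fast rasterization)."""
    return PhantomSpec(pixel_spacing_mm=1.0, matrix_size=192)


@pytest.fixture
def small_brain_spec() -> BrainSpec:
    return BrainSpec(pixel_spacing_mm=1.0, matrix_size=192)


@pytest.fixture
def two_facilities(small_brain_spec) -> list[FacilityConfig]:
    return [
        FacilityConfig(
            facility_id="X1", manufacturer="Canon", model="test",
            noise_model=NoiseModel(amplitude_a=15.0, exponent_b=0.5),
            target_sd=3.0, n_exams=4, dose_jitter=0.1,
        ),
        FacilityConfig(
            facility_id="Y1", manufacturer="FUJI", model="test",
            noise_model=NoiseModel(amplitude_a=20.0, exponent_b=0.5),
            target_sd=4.0, n_exams=3, dose_jitter=0.1,
        ),
    ]


def brute_force_roi_stats(image: ImageSlice, roi) -> tuple[float, float, int]:
    """Independent ROI oracle: explicit per-pixel loop, no vectorisation.

    Circular membership by centre-of-pixel distance; square by the same
    index window the implementation documents. Mean/sample-SD accumulated
    with plain Python arithmetic.
    """
    rows, cols = image.shape
    s = image.pixel_spacing_mm
    values = []
    if roi.shape == "circle":
        cx, cy = roi.center_mm
        r = roi.diameter_mm / 2.0
        for i in range(rows):
            for j in range(cols):
                x = (j + 0.5) * s - cols * s / 2.0
                y = (i + 0.5) * s - rows * s / 2.0
                if (x - cx) ** 2 + (y - cy) ** 2 <= r**2:
                    values.append(float(image.pixels[i, j]))
    else:
        row_c, col_c = image.mm_to_index(*roi.center_mm)
        half = roi.side_px / 2.0
        r0 = int(round(row_c - half + 0.5))
        c0 = int(round(col_c - half + 0.5))
        for i in range(r0, r0 + roi.side_px):
            for j in range(c0, c0 + roi.side_px):
                values.append(float(image.pixels[i, j]))
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var**0.5, n
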