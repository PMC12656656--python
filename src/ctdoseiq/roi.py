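"""ROI statistics and the noise / contrast-to-noise metrics.

Two measurement protocols are implemented:

* phantom — circular 10 mm ROIs on a low-contrast rod (M) and adjacent
  homogeneous background (B):

      SD  = sqrt(SD_M^2 + SD_B^2)
      CNR = (ROI_M - ROI_B) / SD_B

* clinical — square 10x10-pixel ROIs in gray matter (caudate-like) and
  white matter (internal-capsule-like), averaged over multiple placements
  per tissue before a single noise/CNR computation:

      SD  = sqrt(SD_GM^2 + SD_WM^2)
      CNR = (ROI_GM - ROI_WM) / SD_WM

SD is the sample (n-1) standard deviation throughout. CNR is signed; gray
matter (or the rod) is the minuend. Circular-ROI pixel membership uses
centre-of-pixel inclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AggregationError, RoiPlacementError, UndefinedCnrError
from .image import ImageSlice

__all__ = [
    "Roi",
    "RoiStats",
    "PhantomMeasurement",
    "ClinicalMeasurement",
    "measure_roi",
    "roi_mask",
    "aggregate_roi_stats",
    "phantom_noise",
    "phantom_cnr",
    "clinical_noise",
    "clinical_cnr",
    "measure_phantom",
    "measure_brain",
]


@dataclass(frozen=True)
class Roi:
    """A circular (diameter in mm) or square (side in pixels) region.

    `center_mm` is measured from the image centre. `label` is one of
    M (measurement rod), B (background), GM (gray matter), WM (white matter).
    """

    center_mm: tuple[float, float]
    shape: str = "circle"  # "circle" | "square"
    diameter_mm: float | None = 10.0
    side_px: int | None = None
    label: str = "B"

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "square"):
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        if self.shape == "circle" and (self.diameter_mm is None or self.diameter_mm <= 0):
            raise ValueError("circular ROI needs a positive diameter_mm")
        if self.shape == "square" and (self.side_px is None or self.side_px < 2):
            raise ValueError("square ROI needs side_px >= 2")


@dataclass(frozen=True)
class RoiStats:
    """Mean/SD of HU inside one ROI (or a pooled set of same-tissue ROIs)."""

    mean_hu: float
    sd_hu: float
    n_pixels: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")

    @property
    def se_mean(self) -> float:
        """Standard error of the mean, sd / sqrt(n)."""
        return self.sd_hu / math.sqrt(self.n_pixels)


def roi_mask(image: ImageSlice, roi: Roi) -> np.ndarray:
    """Boolean pixel-membership mask for `roi` on `image`.

    Raises RoiPlacementError if the ROI extends outside the image or
    encloses fewer than 4 pixels.
    """
    rows, cols = image.shape
    if roi.shape == "circle":
        x, y = image.pixel_centers_mm()
        cx, cy = roi.center_mm
        r = roi.diameter_mm / 2.0
        half_w, half_h = cols * image.pixel_spacing_mm / 2, rows * image.pixel_spacing_mm / 2
        if abs(cx) + r > half_w or abs(cy) + r > half_h:
            raise RoiPlacementError(
                f"circular ROI at {roi.center_mm} mm (r={r} mm) leaves the image"
            )
        mask = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
    else:
        row_c, col_c = image.mm_to_index(*roi.center_mm)
        half = roi.side_px / 2.0
        r0 = int(round(row_c - half + 0.5))
        c0 = int(round(col_c - half + 0.5))
        r1, c1 = r0 + roi.side_px, c0 + roi.side_px
        if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
            raise RoiPlacementError(
                f"square ROI at {roi.center_mm} mm ({roi.side_px} px) leaves the image"
            )
        mask = np.zeros((rows, cols), dtype=bool)
        mask[r0:r1, c0:c1] = True
    if mask.sum() < 4:
        raise RoiPlacementError(
            f"ROI at {roi.center_mm} mm encloses {int(mask.sum())} pixels (< 4)"
        )
    return mask


def measure_roi(image: ImageSlice, roi: Roi) -> RoiStats:
    """Mean and sample SD of HU inside the ROI."""
    values = image.pixels[roi_mask(image, roi)]
    return RoiStats(
        mean_hu=float(values.mean()),
        sd_hu=float(values.std(ddof=1)),
        n_pixels=int(values.size),
        label=roi.label,
    )


def aggregate_roi_stats(stats: list[RoiStats]) -> RoiStats:
    """Pool same-tissue ROIs: average the means, combine SDs as the
    root-mean-square (preserving the noise-power interpretation), sum n."""
    if not stats:
        raise AggregationError("cannot aggregate an empty list of ROI stats")
    labels = {s.label for s in stats}
    if len(labels) > 1:
        raise AggregationError(f"mixed tissue labels {sorted(labels)} cannot be pooled")
    mean = float(np.mean([s.mean_hu for s in stats]))
    sd = float(math.sqrt(np.mean([s.sd_hu**2 for s in stats])))
    n = int(sum(s.n_pixels for s in stats))
    return RoiStats(mean_hu=mean, sd_hu=sd, n_pixels=n, label=stats[0].label)


# -- metric formulas ---------------------------------------------------------

def _rss(a: float, b: float) -> float:
    return math.hypot(a, b)


def phantom_noise(m: RoiStats, b: RoiStats) -> float:
    """Combined phantom noise, sqrt(SD_M^2 + SD_B^2)."""
    return _rss(m.sd_hu, b.sd_hu)


def phantom_cnr(m: RoiStats, b: RoiStats) -> float:
    """Signed phantom CNR, (ROI_M - ROI_B) / SD_B."""
    if b.sd_hu == 0:
        raise UndefinedCnrError("background SD is zero; CNR undefined")
    return (m.mean_hu - b.mean_hu) / b.sd_hu


def clinical_noise(gm: RoiStats, wm: RoiStats) -> float:
    """Combined clinical noise, sqrt(SD_GM^2 + SD_WM^2)."""
    return _rss(gm.sd_hu, wm.sd_hu)


def clinical_cnr(gm: RoiStats, wm: RoiStats) -> float:
    """Signed clinical CNR, (ROI_GM - ROI_WM) / SD_WM."""
    if wm.sd_hu == 0:
        raise UndefinedCnrError("white-matter SD is zero; CNR undefined")
    return (gm.mean_hu - wm.mean_hu) / wm.sd_hu


@dataclass(frozen=True)
class PhantomMeasurement:
    """One phantom replicate: the rod/background ROI pair and its metrics."""

    m: RoiStats
    b: RoiStats
    combined_sd: float
    cnr: float
    replicate_index: int = 0


@dataclass(frozen=True)
class ClinicalMeasurement:
    """One examination: pooled GM/WM stats and the derived metrics."""

    gm: RoiStats
    wm: RoiStats
    combined_sd: float
    cnr: float
    mean_ct_hu: float  # average of the GM and WM mean CT values


# -- protocol drivers (ROI placement from known synthetic geometry) ---------

def measure_phantom(
    image: ImageSlice,
    spec,
    contrast_level: float = 0.010,
    roi_diameter_mm: float = 10.0,
    replicate_index: int = 0,
) -> PhantomMeasurement:
    """Phantom protocol: circular ROI on the largest rod of the chosen
    contrast group (M) and on a rod-free background spot (B)."""
    _, rod_diam, rx, ry = spec.measurement_rod(contrast_level)
    d = min(roi_diameter_mm, rod_diam)  # ROI must stay inside the rod
    m = measure_roi(image, Roi((rx, ry), "circle", d, label="M"))
    b = measure_roi(
        image, Roi(spec.background_center_mm(), "circle", roi_diameter_mm, label="B")
    )
    return PhantomMeasurement(
        m=m, b=b, combined_sd=phantom_noise(m, b), cnr=phantom_cnr(m, b),
        replicate_index=replicate_index,
    )


def measure_brain(
    image: ImageSlice,
    spec,
    side_px: int = 10,
) -> ClinicalMeasurement:
    """Clinical protocol: square ROIs at every GM and WM structure centre,
    pooled per tissue, then one noise/CNR computation."""
    gm_stats = [
        measure_roi(image, Roi(c, "square", side_px=side_px, label="GM"))
        for c in spec.roi_centers("GM")
    ]
    wm_stats = [
        measure_roi(image, Roi(c, "square", side_px=side_px, label="WM"))
        for c in spec.roi_centers("WM")
    ]
    gm = aggregate_roi_stats(gm_stats)
    wm = aggregate_roi_stats(wm_stats)
    return ClinicalMeasurement(
        gm=gm,
        wm=wm,
        combined_sd=clinical_noise(gm, wm),
        cnr=clinical_cnr(gm, wm),
        mean_ct_hu=(gm.mean_hu + wm.mean_hu) / 2.0,
    )
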