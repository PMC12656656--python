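"""In-memory CT slice container.

A slice is a 2-D array of Hounsfield units plus the pixel spacing needed to
map ROI coordinates (mm) onto pixels. Coordinates are measured from the
image centre: x increases to the right (columns), y downward (rows), so an
ROI at (0, 0) sits at the centre of the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageSlice:
    """2-D CT image in HU with isotropic pixel spacing.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Hounsfield values, float by default (integer if quantized).
    pixel_spacing_mm : float
        Size of one pixel edge in mm (isotropic).
    meta : dict
        Free-form provenance (dose, seed, facility, ...).
    """

    pixels: np.ndarray
    pixel_spacing_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def extent_mm(self) -> tuple[float, float]:
        """Physical (width, height) of the slice in mm."""
        rows, cols = self.pixels.shape
        return cols * self.pixel_spacing_mm, rows * self.pixel_spacing_mm

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate grids of pixel centres, origin at image centre."""
        rows, cols = self.pixels.shape
        s = self.pixel_spacing_mm
        x = (np.arange(cols) + 0.5) * s - cols * s / 2.0
        y = (np.arange(rows) + 0.5) * s - rows * s / 2.0
        return np.meshgrid(x, y)

    def mm_to_index(self, x_mm: float, y_mm: float) -> tuple[float, float]:
        """Convert centre-origin mm coordinates to fractional (row, col) indices."""
        rows, cols = self.pixels.shape
        s = self.pixel_spacing_mm
        col = x_mm / s + cols / 2.0 - 0.5
        row = y_mm / s + rows / 2.0 - 0.5
        return row, col
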