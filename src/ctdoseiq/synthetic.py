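"""Synthetic CT slice and multi-facility dataset generation.

This module emulates the two measurement arms of a pediatric head CT
dose-optimisation study:

* a Catphan-style low-contrast phantom module — a 15 cm water-equivalent
  disc containing cylindrical rods at 0.3/0.5/1.0 % nominal contrast and
  2-15 mm diameters;
* a basal-ganglia-level brain slice — skull ring, white-matter parenchyma
  (~30 HU) and caudate-like gray-matter structures (30-40 HU);
* scanner noise whose magnitude follows the power law SD(d) = A * d^-B in
  the dose d (CTDIvol, mGy), the B = 1/2 case being the classic
  "noise inversely proportional to sqrt(mAs)" behaviour, with an optional
  dose-independent floor to emulate electronic/reconstruction noise;
* automatic exposure control (AEC): given a target noise SD the scanner
  delivers the dose that realises it, d = (A / target)^(1/B).

Everything is deterministic given the integer seed carried by
:class:`AcquisitionParams` (single master seed, split per image via
``numpy.random.SeedSequence``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DomainError, GeometryError
from .image import ImageSlice
from . import roi as _roi

__all__ = [
    "NoiseModel",
    "AcquisitionParams",
    "PhantomSpec",
    "BrainStructure",
    "BrainSpec",
    "FacilityConfig",
    "MeasurementRecord",
    "generate_phantom_image",
    "generate_brain_image",
    "simulate_aec_dose",
    "generate_study_dataset",
    "records_to_frame",
    "default_facilities",
    "TABLE1_SAMPLE_SIZES",
]


# ---------------------------------------------------------------------------
# noise and acquisition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Dose-dependent image noise: SD(d) = sqrt((A * d^-B)^2 + floor^2).

    amplitude_a : noise SD in HU at unit dose (1 mGy); > 0.
    exponent_b  : dose exponent; 0.5 reproduces the sqrt(mAs) law.
    correlation_fwhm_mm : FWHM of a Gaussian correlation kernel applied to
        the noise field (0 = white noise). The field is renormalised after
        smoothing so the per-pixel SD stays on the power-law curve.
    sd_floor_hu : quadrature-added dose-independent noise floor (HU).
    """

    amplitude_a: float
    exponent_b: float = 0.5
    correlation_fwhm_mm: float = 0.0
    sd_floor_hu: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_a < 0:
            raise DomainError("noise amplitude_a must be >= 0")
        if self.exponent_b < 0:
            raise DomainError("noise exponent_b must be >= 0")
        if self.correlation_fwhm_mm < 0 or self.sd_floor_hu < 0:
            raise DomainError("correlation FWHM and noise floor must be >= 0")

    def sd_at(self, ctdivol: float) -> float:
        """Pixel-noise SD (HU) at dose `ctdivol` (mGy)."""
        if ctdivol <= 0:
            raise DomainError(f"ctdivol must be > 0, got {ctdivol}")
        quantum = self.amplitude_a * ctdivol ** (-self.exponent_b)
        return math.hypot(quantum, self.sd_floor_hu)


def simulate_aec_dose(noise: NoiseModel, target_sd: float) -> float:
    """Dose (mGy) at which the scanner's AEC realises `target_sd` (HU).

    Inverts SD(d) = A * d^-B (quantum term only): d = (A / target)^(1/B).
    With a noise floor, the target refers to the total SD and must exceed
    the floor.
    """
    if target_sd <= 0:
        raise DomainError("target_sd must be > 0")
    quantum_target = target_sd
    if noise.sd_floor_hu > 0:
        if target_sd <= noise.sd_floor_hu:
            raise DomainError(
                f"target_sd {target_sd} not reachable: noise floor is "
                f"{noise.sd_floor_hu} HU"
            )
        quantum_target = math.sqrt(target_sd**2 - noise.sd_floor_hu**2)
    if noise.exponent_b == 0:
        if math.isclose(noise.amplitude_a, quantum_target):
            return 1.0
        raise DomainError(
            "exponent_b = 0: noise is dose-independent, no dose realises "
            f"target_sd {target_sd}"
        )
    return (noise.amplitude_a / quantum_target) ** (1.0 / noise.exponent_b)


@dataclass(frozen=True)
class AcquisitionParams:
    """One scan's acquisition settings.

    ctdivol : delivered dose (mGy); validated against `min_ctdivol`, the
        protocol's lower dose bound (default 10 mGy; relax for experiments).
    tube_current_time : optional mAs, proportional to ctdivol at fixed
        kV/pitch; metadata only.
    target_sd : optional AEC setpoint, restricted to [1, 10] when given.
    seed : integer master seed, required — no silent default.
    """

    ctdivol: float
    seed: int
    tube_current_time: float | None = None
    target_sd: float | None = None
    min_ctdivol: float = 10.0

    def __post_init__(self) -> None:
        if self.ctdivol <= 0:
            raise DomainError(f"ctdivol must be > 0, got {self.ctdivol}")
        if self.ctdivol < self.min_ctdivol:
            raise DomainError(
                f"ctdivol {self.ctdivol} mGy below protocol floor "
                f"{self.min_ctdivol} mGy"
            )
        if self.target_sd is not None and not (1.0 <= self.target_sd <= 10.0):
            raise DomainError("target_sd must lie in [1, 10]")
        if not isinstance(self.seed, (int, np.integer)):
            raise DomainError("seed must be an integer")


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Catphan-CTP515-like low-contrast module.

    Rods are laid out on a ring of radius `rod_ring_radius_mm`; each of the
    three contrast groups occupies a 120 degree sector, diameters increasing
    along the sector. Percent contrast maps to HU through `hu_per_percent`
    (the conventional low-contrast-module scale, 1 % = 10 HU).
    """

    module_diameter_mm: float = 150.0
    background_hu: float = 60.0
    contrast_levels: tuple[float, ...] = (0.003, 0.005, 0.010)
    rod_diameters_mm: tuple[float, ...] = (2.0, 3.0, 5.0, 8.0, 15.0)
    rod_ring_radius_mm: float = 50.0
    hu_per_percent: float = 10.0
    pixel_spacing_mm: float = 0.5
    matrix_size: int = 512
    outside_hu: float = -1000.0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.contrast_levels):
            raise DomainError("contrast levels must be positive")
        if any(not (2.0 <= d <= 15.0) for d in self.rod_diameters_mm):
            raise DomainError("rod diameters must lie in [2, 15] mm")
        fov = self.matrix_size * self.pixel_spacing_mm
        if self.module_diameter_mm > fov:
            raise GeometryError(
                f"module ({self.module_diameter_mm} mm) does not fit the "
                f"{fov:.0f} mm field of view"
            )
        if (
            self.rod_ring_radius_mm + max(self.rod_diameters_mm) / 2.0
            >= self.module_diameter_mm / 2.0
        ):
            raise GeometryError("rod ring extends beyond the module edge")

    def contrast_hu(self, level: float) -> float:
        """HU offset of a rod at fractional contrast `level` (0.01 -> 10 HU)."""
        return level * 100.0 * self.hu_per_percent

    def rod_positions(self) -> list[tuple[float, float, float, float]]:
        """(contrast_level, diameter_mm, x_mm, y_mm) for every rod."""
        out = []
        n = len(self.rod_diameters_mm)
        for g, level in enumerate(self.contrast_levels):
            for i, diam in enumerate(self.rod_diameters_mm):
                ang = math.radians(g * 120.0 + (i + 1) * 120.0 / (n + 1))
                x = self.rod_ring_radius_mm * math.cos(ang)
                y = self.rod_ring_radius_mm * math.sin(ang)
                out.append((level, diam, x, y))
        return out

    def measurement_rod(self, contrast_level: float = 0.010) -> tuple[float, float, float, float]:
        """The largest rod of the given contrast group (the 'M' target)."""
        rods = [r for r in self.rod_positions() if math.isclose(r[0], contrast_level)]
        if not rods:
            raise GeometryError(f"no rod group at contrast {contrast_level}")
        return max(rods, key=lambda r: r[1])

    def background_center_mm(self) -> tuple[float, float]:
        """A rod-free spot on the ring (angle 0 sits between contrast groups)."""
        return (self.rod_ring_radius_mm, 0.0)


def _noise_field(
    shape: tuple[int, int],
    sigma_hu: float,
    noise: NoiseModel,
    pixel_spacing_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if sigma_hu == 0:
        return np.zeros(shape)
    field_ = rng.standard_normal(shape)
    if noise.correlation_fwhm_mm > 0:
        sigma_px = noise.correlation_fwhm_mm / 2.3548 / pixel_spacing_mm
        field_ = ndimage.gaussian_filter(field_, sigma_px, mode="wrap")
        field_ /= field_.std()
    return sigma_hu * field_


def generate_phantom_image(
    spec: PhantomSpec,
    acq: AcquisitionParams,
    noise: NoiseModel,
    quantize: bool = False,
) -> ImageSlice:
    """Rasterise the low-contrast module and add dose-dependent noise.

    Pixel membership in the module/rods uses centre-of-pixel inclusion.
    `quantize=True` rounds to integer HU, as stored-value DICOM would.
    """
    base = _phantom_base(spec)
    rng = np.random.default_rng(np.random.SeedSequence(acq.seed))
    sigma = noise.sd_at(acq.ctdivol)
    img = base + _noise_field(base.shape, sigma, noise, spec.pixel_spacing_mm, rng)
    if quantize:
        img = np.rint(img)
    return ImageSlice(
        img,
        spec.pixel_spacing_mm,
        meta={
            "kind": "phantom",
            "ctdivol_mgy": acq.ctdivol,
            "seed": acq.seed,
            "noise_sd_hu": sigma,
        },
    )


def _phantom_base(spec: PhantomSpec) -> np.ndarray:
    n = spec.matrix_size
    s = spec.pixel_spacing_mm
    coords = (np.arange(n) + 0.5) * s - n * s / 2.0
    x, y = np.meshgrid(coords, coords)
    r2 = x**2 + y**2
    img = np.full((n, n), spec.outside_hu, dtype=float)
    img[r2 <= (spec.module_diameter_mm / 2.0) ** 2] = spec.background_hu
    for level, diam, cx, cy in spec.rod_positions():
        mask = (x - cx) ** 2 + (y - cy) ** 2 <= (diam / 2.0) ** 2
        img[mask] = spec.background_hu + spec.contrast_hu(level)
    return img


# ---------------------------------------------------------------------------
# brain geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BrainStructure:
    """An elliptical parenchymal structure (caudate-like GM, capsule-like WM)."""

    label: str  # "GM" or "WM"
    center_mm: tuple[float, float]
    semi_axes_mm: tuple[float, float]


_DEFAULT_STRUCTURES = (
    BrainStructure("GM", (-14.0, 12.0), (5.0, 12.0)),
    BrainStructure("GM", (14.0, 12.0), (5.0, 12.0)),
    BrainStructure("WM", (-25.0, 6.0), (4.0, 10.0)),
    BrainStructure("WM", (25.0, 6.0), (4.0, 10.0)),
)


@dataclass(frozen=True)
class BrainSpec:
    """Basal-ganglia-level head slice: skull ring around WM parenchyma with
    embedded gray-matter structures.

    `head_axes_mm` are the outer full axes of the head ellipse; the skull
    occupies a ring of `skull_thickness_mm` inside it. Gray matter must be
    brighter than white matter and lie inside `gm_plausible_band_hu`
    (clinical basal-ganglia gray matter sits at 30-40 HU).
    """

    head_axes_mm: tuple[float, float] = (120.0, 150.0)
    skull_thickness_mm: float = 6.0
    skull_hu: float = 1000.0
    white_matter_hu: float = 30.0
    gray_matter_hu: float = 38.0
    structures: tuple[BrainStructure, ...] = _DEFAULT_STRUCTURES
    gm_plausible_band_hu: tuple[float, float] = (30.0, 40.0)
    pixel_spacing_mm: float = 0.5
    matrix_size: int = 512
    outside_hu: float = -1000.0

    def __post_init__(self) -> None:
        if self.gray_matter_hu <= self.white_matter_hu:
            raise DomainError("gray_matter_hu must exceed white_matter_hu")
        lo, hi = self.gm_plausible_band_hu
        if not (lo <= self.gray_matter_hu <= hi):
            raise DomainError(
                f"gray_matter_hu {self.gray_matter_hu} outside plausible band "
                f"[{lo}, {hi}]"
            )
        fov = self.matrix_size * self.pixel_spacing_mm
        if max(self.head_axes_mm) > fov:
            raise GeometryError("head ellipse does not fit the field of view")
        gm = [s for s in self.structures if s.label == "GM"]
        for i, a in enumerate(gm):
            for b in gm[i + 1 :]:
                dx = a.center_mm[0] - b.center_mm[0]
                dy = a.center_mm[1] - b.center_mm[1]
                if math.hypot(dx, dy) < max(a.semi_axes_mm) + max(b.semi_axes_mm):
                    raise GeometryError(
                        f"gray-matter structures at {a.center_mm} and "
                        f"{b.center_mm} overlap"
                    )

    def roi_centers(self, label: str) -> list[tuple[float, float]]:
        """Centres (mm) of the structures carrying the given tissue label."""
        return [s.center_mm for s in self.structures if s.label == label]


def generate_brain_image(
    spec: BrainSpec,
    acq: AcquisitionParams,
    noise: NoiseModel,
    quantize: bool = False,
) -> ImageSlice:
    """Rasterise the head slice and add dose-dependent noise."""
    base = _brain_base(spec)
    rng = np.random.default_rng(np.random.SeedSequence(acq.seed))
    sigma = noise.sd_at(acq.ctdivol)
    img = base + _noise_field(base.shape, sigma, noise, spec.pixel_spacing_mm, rng)
    if quantize:
        img = np.rint(img)
    return ImageSlice(
        img,
        spec.pixel_spacing_mm,
        meta={
            "kind": "brain",
            "ctdivol_mgy": acq.ctdivol,
            "seed": acq.seed,
            "noise_sd_hu": sigma,
        },
    )


def _brain_base(spec: BrainSpec) -> np.ndarray:
    n = spec.matrix_size
    s = spec.pixel_spacing_mm
    coords = (np.arange(n) + 0.5) * s - n * s / 2.0
    x, y = np.meshgrid(coords, coords)
    ax, ay = spec.head_axes_mm[0] / 2.0, spec.head_axes_mm[1] / 2.0
    t = spec.skull_thickness_mm
    img = np.full((n, n), spec.outside_hu, dtype=float)
    outer = (x / ax) ** 2 + (y / ay) ** 2 <= 1.0
    inner = (x / (ax - t)) ** 2 + (y / (ay - t)) ** 2 <= 1.0
    img[outer] = spec.skull_hu
    img[inner] = spec.white_matter_hu
    for st in spec.structures:
        cx, cy = st.center_mm
        sa, sb = st.semi_axes_mm
        mask = ((x - cx) / sa) ** 2 + ((y - cy) / sb) ** 2 <= 1.0
        value = spec.gray_matter_hu if st.label == "GM" else spec.white_matter_hu
        img[mask & inner] = value
    return img


# ---------------------------------------------------------------------------
# multi-facility study dataset
# ---------------------------------------------------------------------------

#: Per-facility examination counts of the emulated eight-site study.
TABLE1_SAMPLE_SIZES = (19, 15, 9, 7, 16, 6, 5, 13)


@dataclass(frozen=True)
class FacilityConfig:
    """One participating site: its scanner noise behaviour and AEC setpoint.

    dose_jitter is the sigma of a lognormal multiplier on the AEC dose,
    standing in for patient-size-driven tube-current modulation spread.
    """

    facility_id: str
    manufacturer: str
    noise_model: NoiseModel
    target_sd: float
    n_exams: int
    model: str = ""
    dose_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.n_exams < 1:
            raise DomainError("n_exams must be >= 1")
        if self.dose_jitter < 0:
            raise DomainError("dose_jitter must be >= 0")


@dataclass
class MeasurementRecord:
    """One examination's dose and derived image-quality measurements."""

    facility_id: str
    manufacturer: str
    model: str
    ctdivol_mgy: float
    target_sd: float
    seed: int
    mean_gm_hu: float = math.nan
    mean_wm_hu: float = math.nan
    sd_gm: float = math.nan
    sd_wm: float = math.nan
    sd_combined: float = math.nan
    cnr: float = math.nan
    mean_ct_hu: float = math.nan


# Fixture calibration: amplitudes chosen so each site's AEC solution lands
# inside realistic pediatric head CTDIvol ranges (~20-45 mGy) given its
# vendor's typical target-SD setpoint; not claims about real scanners.
_DEFAULT_SITES: tuple[tuple[str, str, str, float, float, int], ...] = (
    # id, manufacturer, model, target_sd, mean_dose_mgy, n_exams
    ("A", "Canon", "Aquilion PRIME", 2.5, 23.11, 19),
    ("B", "Canon", "Aquilion Prime SP", 3.0, 37.78, 15),
    ("C", "Canon", "Aquilion Prime SP", 2.5, 30.98, 9),
    ("D", "FUJI", "Supria Grande", 4.0, 26.86, 7),
    ("E", "FUJI", "SCENARIA", 3.8, 42.44, 16),
    ("F", "FUJI", "Supria Optica", 3.8, 30.78, 6),
    ("G", "FUJI", "Supria", 4.0, 35.46, 5),
    ("H", "GE", "Revolution EVO", 2.8, 42.18, 13),
)


def default_facilities(dose_jitter: float = 0.18) -> list[FacilityConfig]:
    """Eight-site fixture with vendor-specific AEC setpoints.

    Each site's noise amplitude is back-solved as A = target_sd * dose^0.5
    so that simulate_aec_dose reproduces its nominal mean dose exactly
    (jitter then scatters individual exams around it).
    """
    out = []
    for fid, manu, model, tsd, dose, n in _DEFAULT_SITES:
        amp = tsd * dose**0.5
        out.append(
            FacilityConfig(
                facility_id=fid,
                manufacturer=manu,
                model=model,
                noise_model=NoiseModel(amplitude_a=amp, exponent_b=0.5),
                target_sd=tsd,
                n_exams=n,
                dose_jitter=dose_jitter,
            )
        )
    return out


def generate_study_dataset(
    facilities: list[FacilityConfig],
    seed: int,
    brain_spec: BrainSpec | None = None,
    with_images: bool = False,
    exclusion_fraction: float = 0.0,
) -> list[MeasurementRecord] | tuple[list[MeasurementRecord], list[ImageSlice]]:
    """Simulate the multi-site clinical arm: one brain slice per examination.

    Per exam, the realised dose scatters lognormally around the facility's
    AEC solution; the slice is generated at that dose and measured with the
    square-ROI gray/white-matter protocol. `exclusion_fraction` randomly
    drops that fraction of exams (motion/metadata loss emulation, applied
    after generation so seeds stay aligned). Fully reproducible given seed.
    """
    if not facilities:
        raise DomainError("at least one facility required")
    if not (0.0 <= exclusion_fraction < 1.0):
        raise DomainError("exclusion_fraction must be in [0, 1)")
    spec = brain_spec if brain_spec is not None else BrainSpec()
    master = np.random.SeedSequence(seed)
    fac_seqs = master.spawn(len(facilities))
    records: list[MeasurementRecord] = []
    images: list[ImageSlice] = []
    for fac, seq in zip(facilities, fac_seqs):
        nominal = simulate_aec_dose(fac.noise_model, fac.target_sd)
        exam_seqs = seq.spawn(fac.n_exams)
        for exam_seq in exam_seqs:
            rng = np.random.default_rng(exam_seq)
            if fac.dose_jitter > 0:
                dose = nominal * math.exp(fac.dose_jitter * rng.standard_normal())
            else:
                dose = nominal
            exam_seed = int(rng.integers(0, 2**31 - 1))
            acq = AcquisitionParams(
                ctdivol=dose, seed=exam_seed, target_sd=fac.target_sd, min_ctdivol=0.0
            )
            img = generate_brain_image(spec, acq, fac.noise_model)
            meas = _roi.measure_brain(img, spec)
            records.append(
                MeasurementRecord(
                    facility_id=fac.facility_id,
                    manufacturer=fac.manufacturer,
                    model=fac.model,
                    ctdivol_mgy=dose,
                    target_sd=fac.target_sd,
                    seed=exam_seed,
                    mean_gm_hu=meas.gm.mean_hu,
                    mean_wm_hu=meas.wm.mean_hu,
                    sd_gm=meas.gm.sd_hu,
                    sd_wm=meas.wm.sd_hu,
                    sd_combined=meas.combined_sd,
                    cnr=meas.cnr,
                    mean_ct_hu=meas.mean_ct_hu,
                )
            )
            if with_images:
                images.append(img)
    if exclusion_fraction > 0:
        drop_rng = np.random.default_rng(master.spawn(1)[0])
        keep = drop_rng.random(len(records)) >= exclusion_fraction
        records = [r for r, k in zip(records, keep) if k]
        if with_images:
            images = [im for im, k in zip(images, keep) if k]
    return (records, images) if with_images else records


def records_to_frame(records: list[MeasurementRecord]):
    """Measurement records as a pandas DataFrame (CSV-ready column order)."""
    import pandas as pd

    cols = [
        "facility_id", "manufacturer", "model", "ctdivol_mgy", "target_sd",
        "seed", "mean_gm_hu", "mean_wm_hu", "sd_gm", "sd_wm", "sd_combined",
        "cnr", "mean_ct_hu",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
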