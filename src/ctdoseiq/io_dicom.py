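"""DICOM entry and exit points.

Reading applies the standard stored-value -> HU rescale (raw * slope +
intercept) and orders slices by InstanceNumber; writing emits secondary-
capture-style 16-bit monochrome slices with PixelSpacing and rescale tags
populated so a written slice round-trips to the identical HU array (HU are
rounded to integers on write, as real scanners store them).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .errors import DicomTagError
from .image import ImageSlice

__all__ = ["read_dicom_slice", "read_dicom_series", "write_dicom_slice"]

_INTERCEPT = -1024.0


def _require(ds: pydicom.Dataset, tag: str):
    if tag not in ds:
        raise DicomTagError(f"required DICOM tag {tag} missing in {getattr(ds, 'filename', '?')}")
    return ds[tag].value


def read_dicom_slice(path: str | os.PathLike) -> ImageSlice:
    """Read one DICOM file into an HU-calibrated ImageSlice."""
    ds = pydicom.dcmread(path)
    spacing = _require(ds, "PixelSpacing")
    slope = float(_require(ds, "RescaleSlope"))
    intercept = float(_require(ds, "RescaleIntercept"))
    hu = ds.pixel_array.astype(float) * slope + intercept
    meta = {
        "source": str(path),
        "instance_number": int(getattr(ds, "InstanceNumber", 0)),
    }
    return ImageSlice(hu, float(spacing[0]), meta=meta)


def read_dicom_series(path: str | os.PathLike) -> list[ImageSlice]:
    """Read every .dcm file under `path`, ordered by InstanceNumber."""
    files = sorted(Path(path).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files under {path}")
    slices = [read_dicom_slice(f) for f in files]
    slices.sort(key=lambda s: s.meta.get("instance_number", 0))
    return slices


def write_dicom_slice(
    image: ImageSlice, path: str | os.PathLike, instance_number: int = 1
) -> None:
    """Write a slice as 16-bit secondary capture with rescale tags.

    HU are rounded to integers and stored as unsigned values offset by
    1024 (RescaleIntercept -1024, RescaleSlope 1); HU must lie within
    [-1024, 64511] to fit 16 bits.
    """
    hu = np.rint(np.asarray(image.pixels, dtype=float))
    stored = hu - _INTERCEPT
    if stored.min() < 0 or stored.max() > 0xFFFF:
        raise ValueError("HU range does not fit 16-bit storage with intercept -1024")
    stored = stored.astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SeriesDescription = str(image.meta.get("kind", "synthetic"))
    ds.InstanceNumber = instance_number
    ds.Rows, ds.Columns = stored.shape
    ds.PixelSpacing = [image.pixel_spacing_mm, image.pixel_spacing_mm]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = 1
    ds.RescaleIntercept = int(_INTERCEPT)
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)
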